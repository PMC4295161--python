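"""Per-agent behavioural rules, exercised on hand-built states."""

import random

import pytest

import spermsim as ss
from spermsim import rules
from spermsim.simulation import SimulationState


def make_state(params, seed=0):
    grid = ss.build_grid(params.geometry)
    grid.set_domains(params.position_domain)
    return SimulationState(grid, random.Random(seed))


def put(state, cell_type, pos, **timers):
    idx = state.grid.index(pos)
    return state.spawn(lineage_id=f"T{state.next_id + 1}", cell_type=cell_type,
                       idx=idx, **timers)


class TestTickTimers:
    @pytest.mark.parametrize("value, expected", [(5, 4), (1, 0), (0, 0)])
    def test_decrement_floors_at_zero(self, params, value, expected):
        state = make_state(params)
        a = put(state, "pachytene", (14, 6), differentiation_timer=value,
                lifespan_timer=200)
        rules.tick_timers(a)
        assert a.differentiation_timer == expected

    def test_n_ticks_reach_max_t_minus_n(self, params):
        state = make_state(params)
        a = put(state, "pachytene", (14, 6), differentiation_timer=7,
                lifespan_timer=3)
        for _ in range(5):
            rules.tick_timers(a)
        assert a.differentiation_timer == 2
        assert a.lifespan_timer == 0


class TestFeedback:
    def test_threshold_semantics(self, params):
        state = make_state(params)
        for k in range(6):
            put(state, "preleptotene", (14 + k, 2),
                differentiation_timer=10, lifespan_timer=50)
        assert rules.feedback_active(state, params)  # 6 >= 5
        params.preleptotene_threshold = 7
        assert not rules.feedback_active(state, params)
        params.preleptotene_threshold = 50
        assert not rules.feedback_active(state, params)  # the VAD setting

    def test_no_preleptotenes_gate_closed(self, params):
        state = make_state(params)
        assert not rules.feedback_active(state, params)


class TestStemDivision:
    def _stem_state(self, params, with_feedback=True):
        state = make_state(params)
        stem = put(state, "stem", (14, 0), division_timer=0)
        if with_feedback:
            for k in range(5):
                put(state, "preleptotene", (10 + k, 2),
                    differentiation_timer=10, lifespan_timer=50)
        state.feedback_now = rules.feedback_active(state, params)
        return state, stem

    def test_asymmetric_division(self, params, rng):
        state, stem = self._stem_state(params)
        daughters = rules.attempt_division(state, stem, params, rng)
        assert len(daughters) == 1
        d = daughters[0]
        assert d.cell_type == "diff_spg"
        assert d.mitosis_round == 0
        assert d.lineage_id.startswith(stem.lineage_id + ".")
        assert state.counts["stem"] == 1  # self-renewal: stem count unchanged
        assert stem.division_timer == params.division_time["stem"]

    def test_blocked_without_feedback(self, params, rng):
        state, stem = self._stem_state(params, with_feedback=False)
        assert rules.attempt_division(state, stem, params, rng) == []
        assert stem.division_timer == 0  # latched; retried next hour

    def test_blocked_without_space(self, params, rng):
        state, stem = self._stem_state(params)
        # saturate every placeable neighbour of the stem
        g = state.grid
        for j in g.neighbor_idx[stem.idx]:
            if g.can_place_idx(j, "diff_spg"):
                state.spawn(lineage_id="X", cell_type="diff_spg", idx=j,
                            division_timer=9, differentiation_timer=9,
                            lifespan_timer=9)
        assert rules.attempt_division(state, stem, params, rng) == []
        assert state.counts["stem"] == 1


class TestSpermatogonialDivision:
    def test_round_cap(self, params, rng):
        state = make_state(params)
        a = put(state, "diff_spg", (14, 0), division_timer=0,
                differentiation_timer=100, lifespan_timer=200,
                mitosis_round=params.spg_mitosis_rounds)
        assert rules.attempt_division(state, a, params, rng) == []

    def test_daughter_inherits_clone_deadline(self, params, rng):
        state = make_state(params)
        a = put(state, "diff_spg", (14, 0), division_timer=0,
                differentiation_timer=117, lifespan_timer=200)
        (d,) = rules.attempt_division(state, a, params, rng)
        assert d.differentiation_timer == 117  # inherited, not reset
        assert d.mitosis_round == a.mitosis_round == 1
        assert a.division_timer == params.division_time["diff_spg"]


class TestMeioticDivisions:
    def test_diplotene_produces_two_secondaries(self, params, rng):
        state = make_state(params)
        a = put(state, "diplotene", (14, 5), division_timer=0,
                lifespan_timer=30)
        d1, d2 = rules.attempt_division(state, a, params, rng)
        assert {d1.cell_type, d2.cell_type} == {"secondary"}
        assert d1.idx == a.idx  # first daughter replaces the parent in place
        assert a.id not in state.agents
        assert {d1.lineage_id, d2.lineage_id} == \
            {a.lineage_id + ".1", a.lineage_id + ".2"}

    def test_diplotene_blocked_without_space(self, params, rng):
        state = make_state(params)
        a = put(state, "diplotene", (14, 5), division_timer=0,
                lifespan_timer=30)
        g = state.grid
        for j in g.neighbor_idx[a.idx]:
            if g.can_place_idx(j, "secondary"):
                state.spawn(lineage_id="X", cell_type="pachytene", idx=j,
                            differentiation_timer=9, lifespan_timer=9)
        assert rules.attempt_division(state, a, params, rng) == []
        assert a.id in state.agents  # still a diplotene; may die as one

    def test_secondary_always_completes_via_co_occupancy(self, params, rng):
        """Two round spermatids exist even with every neighbour full."""
        state = make_state(params)
        a = put(state, "secondary", (14, 5), division_timer=0,
                lifespan_timer=30)
        g = state.grid
        for j in g.neighbor_idx[a.idx]:
            if g.can_place_idx(j, "round_sptd"):
                state.spawn(lineage_id="X", cell_type="pachytene", idx=j,
                            differentiation_timer=9, lifespan_timer=9)
        d1, d2 = rules.attempt_division(state, a, params, rng)
        assert state.counts["round_sptd"] == 2
        assert d1.idx == d2.idx == a.idx  # co-occupied compartment

    def test_non_dividing_type_is_contract_violation(self, params, rng):
        state = make_state(params)
        a = put(state, "pachytene", (14, 6), differentiation_timer=5,
                lifespan_timer=50)
        with pytest.raises(ValueError):
            rules.attempt_division(state, a, params, rng)


class TestDeath:
    def test_expired_cell_removed_and_logged(self, params):
        state = make_state(params)
        a = put(state, "preleptotene", (14, 1), differentiation_timer=9,
                lifespan_timer=0)
        rules.apply_death(state, a)
        assert a.id not in state.agents
        assert state.counts["preleptotene"] == 0
        assert any(e[1] == "die" and e[3] == a.lineage_id
                   for e in state.events)

    def test_stem_death_forbidden(self, params):
        state = make_state(params)
        a = put(state, "stem", (14, 0), division_timer=5)
        with pytest.raises(ValueError):
            rules.apply_death(state, a)


class TestMovement:
    def test_pachytene_moves_strictly_inward(self, params, rng):
        state = make_state(params)
        a = put(state, "pachytene", (14, 3), differentiation_timer=9,
                lifespan_timer=50)  # radius 11, free inward neighbours
        r0 = state.grid.radius[a.idx]
        assert rules.attempt_move(state, a, params, rng)
        assert state.grid.radius[a.idx] < r0

    def test_stem_marker_distance_non_increasing(self, params, rng):
        state = make_state(params)
        a = put(state, "stem", (5, 3), division_timer=9)
        for _ in range(12):
            d0 = state.grid.marker_dist[a.idx]
            rules.attempt_move(state, a, params, rng)
            assert state.grid.marker_dist[a.idx] <= d0

    def test_diff_spg_stays_on_ring(self, params, rng):
        state = make_state(params)
        a = put(state, "diff_spg", (14, 0), division_timer=9,
                differentiation_timer=9, lifespan_timer=9)
        for _ in range(10):
            rules.attempt_move(state, a, params, rng)
            r = state.grid.radius[a.idx]
            assert 13.0 <= r <= 14.0  # horizontal drift along the basement

    def test_fully_blocked_cell_stays(self, params, rng):
        state = make_state(params)
        a = put(state, "pachytene", (14, 6), differentiation_timer=9,
                lifespan_timer=50)
        g = state.grid
        for j in g.neighbor_idx[a.idx]:
            state.spawn(lineage_id="X", cell_type="pachytene", idx=j,
                        differentiation_timer=9, lifespan_timer=9)
        idx0 = a.idx
        assert not rules.attempt_move(state, a, params, rng)
        assert a.idx == idx0


class TestDifferentiation:
    @pytest.mark.parametrize("old, new", [
        ("diff_spg", "preleptotene"), ("preleptotene", "leptotene"),
        ("leptotene", "zygotene"), ("zygotene", "pachytene"),
        ("pachytene", "diplotene"), ("round_sptd", "elongated_sptd"),
    ])
    def test_transition_chain(self, params, rng, old, new):
        state = make_state(params)
        dom = params.position_domain[old]
        pos = (14, 14 - int(dom[0]))
        a = put(state, old, pos, differentiation_timer=0, lifespan_timer=40,
                division_timer=0 if old == "diff_spg" else None)
        assert rules.apply_differentiation(state, a, params, rng) == new
        assert a.cell_type == new
        assert a.lineage_id.startswith("T")  # lineage preserved
        assert params.lifespan_min[new] <= a.lifespan_timer \
            <= params.lifespan_max[new]
        if new == "elongated_sptd":
            assert a.release_timer == params.release_delay
        if new == "diplotene":
            assert a.division_timer == params.division_time["diplotene"]

    @pytest.mark.parametrize("terminal", ["stem", "diplotene", "secondary",
                                          "elongated_sptd"])
    def test_terminal_types_never_differentiate(self, params, rng, terminal):
        state = make_state(params)
        a = put(state, terminal, (14, 5), division_timer=5, lifespan_timer=50)
        with pytest.raises(ValueError):
            rules.apply_differentiation(state, a, params, rng)


class TestRelease:
    def test_mature_adjacent_spermatid_released(self, params):
        state = make_state(params)
        # radius ~4.1: elongated domain, adjacent to the lumen boundary
        pos = (14, 10)
        assert ss.radial_distance(state.grid, pos) == 4.0
        a = put(state, "elongated_sptd", pos, release_timer=0,
                lifespan_timer=40)
        ev = rules.attempt_release(state, a, params)
        assert ev is not None
        assert a.id not in state.agents
        assert state.sperm_events[-1].lineage_id == a.lineage_id

    def test_immature_or_distant_not_released(self, params):
        state = make_state(params)
        a = put(state, "elongated_sptd", (14, 10), release_timer=3,
                lifespan_timer=40)
        # immature: the caller (step) does not invoke release; a distant
        # mature spermatid yields no event
        b = put(state, "elongated_sptd", (14, 8), release_timer=0,
                lifespan_timer=40)  # radius 6: not lumen-adjacent
        assert rules.attempt_release(state, b, params) is None
        assert state.sperm_events == []
        assert a.id in state.agents


def test_max_sperm_per_asymmetric_division(params):
    assert rules.max_sperm_per_asymmetric_division(params) == 32
    params.spg_mitosis_rounds = 4
    assert rules.max_sperm_per_asymmetric_division(params) == 64
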