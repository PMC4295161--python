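"""Hourly simulation driver: Stage-I initialisation, stepping, runs and
the calibration harness.

A simulation starts from Stage I of the seminiferous-epithelium cycle
(stem cells, differentiating spermatogonia, pachytenes, round and
elongated spermatids, randomly placed within their position domains) and
advances in one-hour steps.  Each hour every agent's timers tick down and
the agents, visited in a fresh random permutation, execute pending events
in the order division, death, movement, differentiation, release.

Cohort timers at initialisation are phase-consistent: each seeded cohort
carries the remaining time of its current stage, derived from the timer
chain, so the first cycle is synchronised with all later ones.  The cycle
anchor used throughout the package is the onset of preleptotenes (entry to
stage VII): the hour at which the preleptotene count rises from zero.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import numpy as np

from . import rules
from .environment import build_grid, TubuleGrid
from .parameters import (DIFF_SPG, DIPLOTENE, DIVIDING_TYPES, ELONGATED_SPTD,
                         NEXT_TYPE, PACHYTENE, PRELEPTOTENE, ROUND_SPTD,
                         SECONDARY, SPERMATID_TYPES, STEM, TYPE_ORDER,
                         ParameterSet, default_parameters, validate)
from .rules import CellAgent, draw_lifespan

__all__ = ["SimulationState", "SimulationResult", "initialize_stage_I",
           "step", "run", "calibrate", "CalibrationReport",
           "CalibrationError", "stage_schedule"]

#: hours between a preleptotene onset and the stem-division burst it licenses
BURST_LAG = 1

#: cell types paused by the spermatogonial-arrest scenario
SPERMATOGONIAL_TYPES = frozenset({STEM, DIFF_SPG})


# ---------------------------------------------------------------------------
# State
# ---------------------------------------------------------------------------


class SimulationState:
    """Mutable simulation state: grid, agents, counters, RNG and logs."""

    __slots__ = ("clock", "grid", "agents", "counts", "sperm_events",
                 "events", "rng", "feedback_now", "sperm_this_hour",
                 "radial_sum", "next_id", "record_events", "record_moves")

    def __init__(self, grid: TubuleGrid, rng: random.Random,
                 record_events: bool = True, record_moves: bool = False):
        self.clock = 0
        self.grid = grid
        self.agents: dict[int, CellAgent] = {}
        self.counts = {t: 0 for t in TYPE_ORDER}
        self.sperm_events: list[rules.SpermEvent] = []
        self.events: list[tuple] = []
        self.rng = rng
        self.feedback_now = False
        self.sperm_this_hour = 0
        self.radial_sum = {t: 0.0 for t in TYPE_ORDER}
        self.next_id = 0
        self.record_events = record_events
        self.record_moves = record_moves

    # -- agent lifecycle -------------------------------------------------

    def spawn(self, lineage_id: str, cell_type: str, idx: int,
              division_timer=None, differentiation_timer=None,
              lifespan_timer=None, release_timer=None, mitosis_round=0,
              in_place: bool = False) -> CellAgent:
        self.next_id += 1
        a = CellAgent(self.next_id, lineage_id, cell_type, idx, self.clock,
                      division_timer, differentiation_timer, lifespan_timer,
                      release_timer, mitosis_round)
        self.agents[a.id] = a
        self.grid.place_idx(idx, a.id, cell_type)
        self.counts[cell_type] += 1
        self.radial_sum[cell_type] += self.grid.radius[idx]
        return a

    def despawn(self, cell: CellAgent) -> None:
        self.grid.remove_idx(cell.idx, cell.id, cell.cell_type)
        del self.agents[cell.id]
        self.counts[cell.cell_type] -= 1
        self.radial_sum[cell.cell_type] -= self.grid.radius[cell.idx]

    def move(self, cell: CellAgent, new_idx: int) -> None:
        g = self.grid
        g.remove_idx(cell.idx, cell.id, cell.cell_type)
        g.place_idx(new_idx, cell.id, cell.cell_type)
        self.radial_sum[cell.cell_type] += g.radius[new_idx] - g.radius[cell.idx]
        if self.record_moves:
            self.events.append((self.clock, "move", cell.id, cell.lineage_id,
                                cell.cell_type, cell.cell_type, new_idx))
        cell.idx = new_idx

    def retype(self, cell: CellAgent, new_type: str) -> None:
        old = cell.cell_type
        self.counts[old] -= 1
        self.counts[new_type] += 1
        r = self.grid.radius[cell.idx]
        self.radial_sum[old] -= r
        self.radial_sum[new_type] += r
        if (old in SPERMATID_TYPES) != (new_type in SPERMATID_TYPES):
            self.grid.mark_spermatid(cell.idx,
                                     1 if new_type in SPERMATID_TYPES else -1)
        cell.cell_type = new_type

    def log(self, event: str, cell_id: int, lineage_id: str,
            type_before: str, type_after: str, idx: int) -> None:
        if self.record_events:
            self.events.append((self.clock, event, cell_id, lineage_id,
                                type_before, type_after, idx))

    # -- consistency audit ----------------------------------------------

    def audit(self) -> None:
        """Verify agents <-> occupancy consistency and the capacity rule;
        raises AssertionError with a diagnostic on any violation."""
        g = self.grid
        seen: dict[int, int] = {}
        for idx, ids in g.occupants.items():
            assert g.region[idx] == 2, \
                f"occupants at non-epithelium index {idx} (region {g.region[idx]})"
            assert 1 <= len(ids) <= 2, f"capacity exceeded at {idx}: {ids}"
            if len(ids) == 2:
                for i in ids:
                    assert self.agents[i].cell_type in SPERMATID_TYPES, \
                        f"non-spermatid co-occupancy at {idx}"
            for i in ids:
                assert i not in seen, f"agent {i} occupies two compartments"
                seen[i] = idx
        assert set(seen) == set(self.agents), \
            "agents and occupancy registry disagree"
        for i, a in self.agents.items():
            assert seen[i] == a.idx, f"agent {i} position mismatch"
        for t in TYPE_ORDER:
            n = sum(1 for a in self.agents.values() if a.cell_type == t)
            assert n == self.counts[t], f"count cache wrong for {t}"


# ---------------------------------------------------------------------------
# Stage-I initialisation
# ---------------------------------------------------------------------------


def stage_schedule(params: ParameterSet) -> dict:
    """Phase schedule of one cycle implied by the timer chain.

    Phase 0 is the preleptotene onset (entry to stage VII).  Returns the
    onset phase of each downstream stage, the cycle period
    (spermatogonial differentiation time + the burst lag) and the Stage-I
    initialisation phase (shortly after round spermatids appear).
    """
    P = params.differentiation_time
    D = params.division_time
    period = P[DIFF_SPG] + BURST_LAG
    lep_on = P[PRELEPTOTENE]
    zyg_on = lep_on + P["leptotene"]
    pach_on = zyg_on + P["zygotene"]
    dip_on = (pach_on + P[PACHYTENE]) % period
    sec_on = (dip_on + D[DIPLOTENE]) % period
    round_on = (sec_on + D[SECONDARY]) % period
    elong_on = (round_on + P[ROUND_SPTD]) % period
    return {
        "period": period,
        "lep_on": lep_on, "zyg_on": zyg_on, "pach_on": pach_on,
        "dip_on": dip_on, "sec_on": sec_on, "round_on": round_on,
        "elong_on": elong_on,
        "init_phase": (round_on + 8) % period,
    }


def _scatter(state: SimulationState, cell_type: str, count: int,
             rng: random.Random, **timers) -> list[CellAgent]:
    """Place ``count`` cells of one type at random free positions inside
    the type's domain; lifespan timers are adjusted by cohort age."""
    g = state.grid
    positions = [i for i in range(g.width * g.width)
                 if g.domain_ok[cell_type][i]]
    rng.shuffle(positions)
    if cell_type in SPERMATID_TYPES:
        positions = positions * 2  # two spermatids may share a compartment
    placed = []
    for idx in positions:
        if len(placed) == count:
            break
        if g.can_place_idx(idx, cell_type):
            placed.append(idx)
            g.place_idx(idx, 0, cell_type)  # reserve; replaced below
    if len(placed) < count:
        raise ValueError(
            f"initial count {count} for {cell_type} exceeds the capacity "
            f"of its position domain")
    agents = []
    for idx in placed:
        g.remove_idx(idx, 0, cell_type)
        agents.append(state.spawn(cell_type=cell_type, idx=idx, **timers,
                                  lineage_id=f"I{state.next_id + 1}"))
    return agents


def initialize_stage_I(params: ParameterSet, rng: random.Random,
                       variant: str = "normal",
                       record_events: bool = True,
                       record_moves: bool = False) -> SimulationState:
    """Seed Stage I of the cycle with phase-consistent cohort timers.

    ``variant="spermatogonia_only"`` seeds only stem cells and
    differentiating spermatogonia (the meiosis-arrest initial condition);
    the default seeds all five Stage-I types.
    """
    problems = validate(params)
    if problems:
        raise ValueError("invalid parameters: " + "; ".join(problems))
    grid = build_grid(params.geometry)
    grid.set_domains(params.position_domain)
    state = SimulationState(grid, rng, record_events, record_moves)
    sched = stage_schedule(params)
    period = sched["period"]
    init = sched["init_phase"]
    P, D = params.differentiation_time, params.division_time

    def age_since(onset):
        return (init - onset) % period

    def life_timer(cell_type, age):
        return max(draw_lifespan(params, cell_type, rng) - age, 0)

    # stem cells: timer set to fire at the next burst (next preleptotene
    # onset + lag); lineage roots "S1".."Sn"
    n_stem = params.initial_counts.get(STEM, params.initial_stem_count)
    stem_timer = (period - init) % period + BURST_LAG
    stems = _scatter(state, STEM, n_stem, rng, division_timer=stem_timer)
    for k, a in enumerate(stems, 1):
        a.lineage_id = f"S{k}"

    spg_age = age_since(BURST_LAG)
    n_rounds_done = min(spg_age // D[DIFF_SPG], params.spg_mitosis_rounds)
    next_div = (n_rounds_done + 1) * D[DIFF_SPG] - spg_age
    if n_rounds_done >= params.spg_mitosis_rounds or next_div < 0:
        next_div = D[DIFF_SPG]
    cohorts = {
        DIFF_SPG: dict(
            division_timer=max(next_div, 0),
            differentiation_timer=max(P[DIFF_SPG] - spg_age, 0),
            mitosis_round=n_rounds_done,
            lifespan_timer=None),  # drawn below with age correction
        PACHYTENE: dict(differentiation_timer=max(
            P[PACHYTENE] - age_since(sched["pach_on"]), 0)),
        ROUND_SPTD: dict(differentiation_timer=max(
            P[ROUND_SPTD] - age_since(sched["round_on"]), 0)),
        ELONGATED_SPTD: dict(release_timer=max(
            params.release_delay - age_since(sched["elong_on"]), 0)),
    }
    ages = {DIFF_SPG: spg_age, PACHYTENE: age_since(sched["pach_on"]),
            ROUND_SPTD: age_since(sched["round_on"]),
            ELONGATED_SPTD: age_since(sched["elong_on"])}
    if variant == "spermatogonia_only":
        seeded = (DIFF_SPG,)
    elif variant == "normal":
        seeded = (DIFF_SPG, PACHYTENE, ROUND_SPTD, ELONGATED_SPTD)
    else:
        raise ValueError(f"unknown initial-condition variant {variant!r}")
    for t in seeded:
        n = params.initial_counts.get(t, 0)
        if n <= 0:
            continue
        timers = dict(cohorts[t])
        agents = _scatter(state, t, n, rng, **timers)
        for a in agents:
            a.lifespan_timer = life_timer(t, ages[t])
    return state


# ---------------------------------------------------------------------------
# Stepping
# ---------------------------------------------------------------------------


def step(state: SimulationState, params: ParameterSet,
         scenario=None) -> SimulationState:
    """Advance the simulation by one hour.

    Applies any scenario overrides active at this hour, ticks all timers,
    then visits the agents in a fresh random permutation executing pending
    events per cell in the order division, death, movement,
    differentiation, release.
    """
    state.clock += 1
    hour = state.clock
    frozen_types = frozenset()
    if scenario is not None:
        params, frozen = scenario.effective(params, hour)
        if frozen:
            frozen_types = SPERMATOGONIAL_TYPES
    rng = state.rng
    state.sperm_this_hour = 0

    agents = list(state.agents.values())
    if frozen_types:
        agents = [a for a in agents if a.cell_type not in frozen_types]
    for a in agents:
        rules.tick_timers(a)

    state.feedback_now = (state.counts[PRELEPTOTENE]
                          >= params.preleptotene_threshold)

    rng.shuffle(agents)
    registry = state.agents
    dividing = set(DIVIDING_TYPES)
    for a in agents:
        if registry.get(a.id) is not a:
            continue  # consumed by an earlier meiotic division this hour
        t = a.cell_type
        if a.division_timer == 0 and t in dividing:
            rules.attempt_division(state, a, params, rng)
            if registry.get(a.id) is not a:
                continue  # meiotic parent replaced by daughters
            t = a.cell_type
        if a.lifespan_timer == 0 and t != STEM:
            rules.apply_death(state, a)
            continue
        rules.attempt_move(state, a, params, rng)
        if a.differentiation_timer == 0 and t in NEXT_TYPE:
            rules.apply_differentiation(state, a, params, rng)
        elif t == ELONGATED_SPTD and a.release_timer == 0:
            rules.attempt_release(state, a, params)
    return state


# ---------------------------------------------------------------------------
# Runs
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    """Hourly tallies, events and lineage records of one run."""

    params: ParameterSet
    seed: int
    hours: int
    scenario_name: str | None
    type_order: tuple[str, ...]
    counts: np.ndarray              # hours x 10, per-type counts
    sperm_released: np.ndarray      # hours, releases per hour
    radial_mean: np.ndarray         # hours x 10, nan when type absent
    anchors: list[int]              # preleptotene-onset hours (cycle starts)
    events: list[tuple]             # (t, event, id, lineage, before, after, idx)
    sperm_events: list = field(default_factory=list)

    @property
    def sperm_cumulative(self) -> np.ndarray:
        return np.cumsum(self.sperm_released)

    def counts_frame(self):
        import pandas as pd
        df = pd.DataFrame(self.counts, columns=list(self.type_order))
        df.insert(0, "hour", np.arange(1, self.hours + 1))
        df["sperm_released"] = self.sperm_released
        df["sperm_cumulative"] = self.sperm_cumulative
        return df


def run(params: ParameterSet | None = None, hours: int = 2070,
        seed: int = 0, scenario=None, record_events: bool = True,
        record_moves: bool = False, record_radial: bool = True,
        audit_every: int = 0) -> SimulationResult:
    """Run a complete simulation; reproducible from (params, seed, scenario)."""
    if hours < 1:
        raise ValueError("hours must be >= 1")
    params = (params or default_parameters()).copy()
    rng = random.Random(seed)
    variant = "normal"
    scenario_name = None
    if scenario is not None:
        variant = scenario.initial_condition_variant
        scenario_name = scenario.name
        scenario.reset()
    state = initialize_stage_I(params, rng, variant, record_events,
                               record_moves)
    ntypes = len(TYPE_ORDER)
    counts = np.zeros((hours, ntypes), dtype=np.int32)
    sperm = np.zeros(hours, dtype=np.int32)
    radial = np.full((hours, ntypes), np.nan)
    anchors: list[int] = []
    prev_prelep = state.counts[PRELEPTOTENE]
    for h in range(hours):
        step(state, params, scenario)
        c = state.counts
        for j, t in enumerate(TYPE_ORDER):
            counts[h, j] = c[t]
        sperm[h] = state.sperm_this_hour
        if record_radial:
            rs = state.radial_sum
            for j, t in enumerate(TYPE_ORDER):
                if c[t]:
                    radial[h, j] = rs[t] / c[t]
        if prev_prelep == 0 and c[PRELEPTOTENE] > 0:
            anchors.append(state.clock)
        prev_prelep = c[PRELEPTOTENE]
        if audit_every and state.clock % audit_every == 0:
            state.audit()
    return SimulationResult(
        params=params, seed=seed, hours=hours, scenario_name=scenario_name,
        type_order=TYPE_ORDER, counts=counts, sperm_released=sperm,
        radial_mean=radial, anchors=anchors, events=state.events,
        sperm_events=state.sperm_events)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


class CalibrationError(RuntimeError):
    pass


@dataclass
class CalibrationReport:
    period_hours: float
    transit_hours: float
    distinct_stages: int
    violations: list[str]

    @property
    def ok(self) -> bool:
        return not self.violations


#: calibration targets: cycle period 8.6 days, stem-to-sperm transit four
#: cycles (35 days), the full 12-stage sequence, persistent cycling
DEFAULT_CONSTRAINTS = {
    "period_hours": 206.4,
    "period_tol": 0.05,
    "transit_hours": 840.0,
    "transit_tol": 0.05,
    "stages": 12,
}


def check_calibration(params: ParameterSet, seed: int = 0,
                      cycles: int = 12,
                      constraints: dict | None = None) -> CalibrationReport:
    """Verify the calibration constraints on a fresh baseline run."""
    from . import analytics

    cons = dict(DEFAULT_CONSTRAINTS)
    if constraints:
        cons.update(constraints)
    period0 = stage_schedule(params)["period"]
    hours = int(cycles * period0 + period0)
    res = run(params, hours=hours, seed=seed, record_radial=False)
    violations: list[str] = []

    anchors = res.anchors
    if len(anchors) < 3:
        period = math.nan
        violations.append("no sustained cycling: fewer than 3 preleptotene "
                          "onsets observed")
    else:
        period = float(np.mean(np.diff(anchors)))
        tol = cons["period_tol"] * cons["period_hours"]
        if abs(period - cons["period_hours"]) > tol:
            violations.append(
                f"cycle period {period:.1f} h outside "
                f"{cons['period_hours']} +/- {tol:.1f} h")

    transits = analytics.transit_times(res)
    if not transits:
        transit = math.nan
        violations.append("no stem division produced a descendant sperm")
    else:
        transit = float(np.mean(transits))
        tol = cons["transit_tol"] * cons["transit_hours"]
        if abs(transit - cons["transit_hours"]) > tol:
            violations.append(
                f"stem-to-sperm transit {transit:.0f} h outside "
                f"{cons['transit_hours']} +/- {tol:.0f} h")

    # cells beyond leptotene must keep appearing (meiotic progression)
    half = hours // 2
    if res.counts[half:, TYPE_ORDER.index(PACHYTENE)].max(initial=0) == 0:
        violations.append("no cells beyond leptotene in the second half of "
                          "the run (meiotic progression lost)")

    n_stages = 0
    if len(anchors) >= 4:
        labels = analytics.label_stages(res)
        lo, hi = anchors[1], anchors[3]
        idx = {l.stage_index for l in labels[lo:hi]
               if l.stage_index is not None}
        n_stages = len(idx)
        if n_stages < cons["stages"]:
            violations.append(f"only {n_stages} of {cons['stages']} stages "
                              f"observed over cycles 2-3")

    # persistence: neither extinction nor unbounded growth
    tail = res.counts[-int(period0):].sum(axis=1)
    if tail.size and tail.min() == 0 and len(anchors) >= 3:
        violations.append("germ-cell extinction in the final cycle")
    capacity = 2 * np.pi * params.geometry.tubule_radius ** 2
    if res.counts.sum(axis=1).max() > capacity:
        violations.append("unbounded growth: cell number exceeds the "
                          "cross-section capacity")
    return CalibrationReport(period, transit, n_stages, violations)


def calibrate(params: ParameterSet | None = None, constraints: dict | None = None,
              seed: int = 0, search: bool = False, cycles: int = 12,
              max_evals: int = 24) -> ParameterSet:
    """Return a parameter set meeting the calibration constraints.

    In check mode (``search=False``, the default) the given set is verified
    and returned unchanged, or ``CalibrationError`` is raised naming the
    violated constraint.  With ``search=True`` a coordinate-descent pass
    perturbs the non-anchored timers (+/-10%, one at a time, keeping the
    printed baselines fixed) until the constraints hold or the evaluation
    budget is exhausted.
    """
    params = (params or default_parameters()).copy()
    report = check_calibration(params, seed, cycles, constraints)
    if report.ok:
        return params
    if not search:
        raise CalibrationError("; ".join(report.violations))

    anchored = {"differentiation_time.preleptotene", "division_time.diff_spg"}
    tunable = [(g, t) for g in ("differentiation_time", "division_time")
               for t in getattr(params, g) if f"{g}.{t}" not in anchored]
    best, best_n = params, len(report.violations)
    evals = 0
    for group, t in tunable:
        for factor in (0.9, 1.1):
            if evals >= max_evals:
                raise CalibrationError(
                    "search budget exhausted; best candidate still violates: "
                    + "; ".join(check_calibration(best, seed, cycles,
                                                  constraints).violations))
            cand = best.copy()
            getattr(cand, group)[t] = max(1, round(
                getattr(best, group)[t] * factor))
            rep = check_calibration(cand, seed, cycles, constraints)
            evals += 1
            if rep.ok:
                return cand
            if len(rep.violations) < best_n:
                best, best_n = cand, len(rep.violations)
    raise CalibrationError(
        "search budget exhausted; best candidate still violates: "
        + "; ".join(check_calibration(best, seed, cycles,
                                      constraints).violations))
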