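"""Per-agent behavioural rules: division, death, movement, differentiation
and sperm release.

Within one simulated hour each cell executes its pending events in the
fixed order division, death, movement, differentiation, release.  Timers
tick down once per hour; an event whose timer has reached zero but whose
preconditions fail (no free neighbouring micro-compartment, feedback gate
closed) stays pending and is retried the next hour.

Division rules:

* A spermatogonial stem cell divides asymmetrically (self-renewal plus one
  differentiating spermatogonium) only while the preleptotene feedback gate
  is open, i.e. the current preleptotene count has reached the threshold.
  Stem cells never die; the stem pool size is constant.
* A differentiating spermatogonium divides symmetrically, up to
  ``spg_mitosis_rounds`` on-section rounds; daughters inherit the parent's
  remaining differentiation timer so the whole clone enters meiosis
  together.  Differentiation to preleptotene fires on that timer; at the
  baseline 88 h division time two rounds fit into the clone's lifetime,
  while faster division squeezes in a third round - space permitting.
* Meiosis I (diplotene -> two secondary spermatocytes) replaces the parent
  in place and needs one free neighbour for the second daughter; a
  diplotene that never finds space dies as a diplotene at its lifespan.
* Meiosis II (secondary -> two round spermatids) can always complete: the
  second spermatid may co-occupy the parent compartment.

Movement is a greedy, one-compartment-per-hour step within the type's
radial position domain: stem cells approach the nearest interstitial
marker, differentiating spermatogonia slide along the basement membrane
(minimal radial change), and every other type descends the radial gradient
toward the lumen.  Ties are broken uniformly at random.
"""

from __future__ import annotations

from .environment import LUMEN, TubuleGrid
from .parameters import (DIFF_SPG, DIPLOTENE, ELONGATED_SPTD, NEXT_TYPE,
                         PRELEPTOTENE, ROUND_SPTD, SECONDARY, STEM,
                         ParameterSet)

__all__ = ["CellAgent", "SpermEvent", "tick_timers", "feedback_active",
           "attempt_division", "apply_death", "attempt_move",
           "apply_differentiation", "attempt_release",
           "max_sperm_per_asymmetric_division", "draw_lifespan"]


class CellAgent:
    """One germ cell: identity, lineage, position and pending timers.

    ``lineage_id`` is a dotted path; each daughter extends its parent's id
    (``"S3" -> "S3.1" -> "S3.1.2" ...``), so descent is a prefix relation.
    Timers that are meaningless for the type are ``None``.
    """

    __slots__ = ("id", "lineage_id", "cell_type", "idx", "division_timer",
                 "differentiation_timer", "lifespan_timer", "release_timer",
                 "mitosis_round", "birth_time", "child_count")

    def __init__(self, agent_id: int, lineage_id: str, cell_type: str,
                 idx: int, birth_time: int, division_timer=None,
                 differentiation_timer=None, lifespan_timer=None,
                 release_timer=None, mitosis_round=0):
        self.id = agent_id
        self.lineage_id = lineage_id
        self.cell_type = cell_type
        self.idx = idx
        self.birth_time = birth_time
        self.division_timer = division_timer
        self.differentiation_timer = differentiation_timer
        self.lifespan_timer = lifespan_timer
        self.release_timer = release_timer
        self.mitosis_round = mitosis_round
        self.child_count = 0

    def __repr__(self):  # pragma: no cover - debugging aid
        return (f"CellAgent({self.id}, {self.lineage_id!r}, {self.cell_type},"
                f" idx={self.idx})")


class SpermEvent:
    """A spermiation event: an elongated spermatid entering the lumen."""

    __slots__ = ("time", "lineage_id", "release_pos")

    def __init__(self, time: int, lineage_id: str, release_pos):
        self.time = time
        self.lineage_id = lineage_id
        self.release_pos = release_pos


def draw_lifespan(params: ParameterSet, cell_type: str, rng) -> int:
    """Uniform integer lifespan draw for ``cell_type`` (hours)."""
    return rng.randint(params.lifespan_min[cell_type],
                       params.lifespan_max[cell_type])


def max_sperm_per_asymmetric_division(params: ParameterSet) -> int:
    """Maximum sperm derivable from one asymmetric stem division.

    One differentiating spermatogonium undergoes at most
    ``spg_mitosis_rounds`` mitotic rounds, then each clone member passes
    through both meiotic divisions (x4): ``4 * 2**rounds`` (32 at default).
    """
    return 4 * 2 ** params.spg_mitosis_rounds


# ---------------------------------------------------------------------------
# Timers and feedback
# ---------------------------------------------------------------------------


def tick_timers(cell: CellAgent) -> CellAgent:
    """Decrement every present timer by one hour, floored at zero."""
    t = cell.division_timer
    if t is not None and t > 0:
        cell.division_timer = t - 1
    t = cell.differentiation_timer
    if t is not None and t > 0:
        cell.differentiation_timer = t - 1
    t = cell.lifespan_timer
    if t is not None and t > 0:
        cell.lifespan_timer = t - 1
    t = cell.release_timer
    if t is not None and t > 0:
        cell.release_timer = t - 1
    return cell


def feedback_active(state, params: ParameterSet) -> bool:
    """Preleptotene-to-stem feedback: open iff the current preleptotene
    count has reached the threshold (retinoic-acid source proxy)."""
    return state.counts[PRELEPTOTENE] >= params.preleptotene_threshold


# ---------------------------------------------------------------------------
# Division
# ---------------------------------------------------------------------------


def _random_placeable_neighbor(grid: TubuleGrid, idx: int, cell_type: str,
                               rng) -> int | None:
    cand = [j for j in grid.neighbor_idx[idx]
            if grid.can_place_idx(j, cell_type)]
    if not cand:
        return None
    return cand[rng.randrange(len(cand))] if len(cand) > 1 else cand[0]


def attempt_division(state, cell: CellAgent, params: ParameterSet, rng):
    """Execute a pending division; returns the new daughter agents.

    Returns an empty list when the division stays pending (no space, or the
    stem feedback gate is closed); the timer remains latched at zero and
    the division is retried next hour.
    """
    t = cell.cell_type
    grid = state.grid
    if t == STEM:
        if not state.feedback_now:
            return []
        j = _random_placeable_neighbor(grid, cell.idx, DIFF_SPG, rng)
        if j is None:
            return []
        cell.child_count += 1
        daughter = state.spawn(
            lineage_id=f"{cell.lineage_id}.{cell.child_count}",
            cell_type=DIFF_SPG, idx=j,
            division_timer=params.division_time[DIFF_SPG],
            differentiation_timer=params.differentiation_time[DIFF_SPG],
            lifespan_timer=draw_lifespan(params, DIFF_SPG, rng),
            mitosis_round=0)
        cell.division_timer = params.division_time[STEM]
        state.log("divide", cell.id, cell.lineage_id, STEM,
                  daughter.lineage_id, cell.idx)
        return [daughter]

    if t == DIFF_SPG:
        if cell.mitosis_round >= params.spg_mitosis_rounds:
            return []
        j = _random_placeable_neighbor(grid, cell.idx, DIFF_SPG, rng)
        if j is None:
            return []
        cell.mitosis_round += 1
        cell.division_timer = params.division_time[DIFF_SPG]
        cell.child_count += 1
        daughter = state.spawn(
            lineage_id=f"{cell.lineage_id}.{cell.child_count}",
            cell_type=DIFF_SPG, idx=j,
            division_timer=params.division_time[DIFF_SPG],
            differentiation_timer=cell.differentiation_timer,
            lifespan_timer=draw_lifespan(params, DIFF_SPG, rng),
            mitosis_round=cell.mitosis_round)
        state.log("divide", cell.id, cell.lineage_id, DIFF_SPG,
                  daughter.lineage_id, cell.idx)
        return [daughter]

    if t == DIPLOTENE:
        j = _random_placeable_neighbor(grid, cell.idx, SECONDARY, rng)
        if j is None:
            return []  # meiosis I blocked; may die as diplotene
        idx = cell.idx
        lid = cell.lineage_id
        c = cell.child_count  # continue the numbering of earlier daughters
        state.despawn(cell)
        d1 = state.spawn(lineage_id=f"{lid}.{c + 1}", cell_type=SECONDARY,
                         idx=idx,
                         division_timer=params.division_time[SECONDARY],
                         lifespan_timer=draw_lifespan(params, SECONDARY, rng),
                         in_place=True)
        d2 = state.spawn(lineage_id=f"{lid}.{c + 2}", cell_type=SECONDARY,
                         idx=j,
                         division_timer=params.division_time[SECONDARY],
                         lifespan_timer=draw_lifespan(params, SECONDARY, rng))
        state.log("divide", cell.id, lid, DIPLOTENE,
                  f"{d1.lineage_id}+{d2.lineage_id}", idx)
        return [d1, d2]

    if t == SECONDARY:
        idx = cell.idx
        lid = cell.lineage_id
        c = cell.child_count
        j = _random_placeable_neighbor(grid, idx, ROUND_SPTD, rng)
        state.despawn(cell)
        d1 = state.spawn(lineage_id=f"{lid}.{c + 1}", cell_type=ROUND_SPTD,
                         idx=idx,
                         differentiation_timer=params.differentiation_time[ROUND_SPTD],
                         lifespan_timer=draw_lifespan(params, ROUND_SPTD, rng),
                         in_place=True)
        # second spermatid: free neighbour, else co-occupy the parent
        # compartment (two spermatids per micro-compartment are allowed)
        d2 = state.spawn(lineage_id=f"{lid}.{c + 2}", cell_type=ROUND_SPTD,
                         idx=j if j is not None else idx,
                         differentiation_timer=params.differentiation_time[ROUND_SPTD],
                         lifespan_timer=draw_lifespan(params, ROUND_SPTD, rng),
                         in_place=j is None)
        state.log("divide", cell.id, lid, SECONDARY,
                  f"{d1.lineage_id}+{d2.lineage_id}", idx)
        return [d1, d2]

    raise ValueError(f"cell type {t} does not divide")


# ---------------------------------------------------------------------------
# Death
# ---------------------------------------------------------------------------


def apply_death(state, cell: CellAgent) -> None:
    """Remove a non-stem cell whose lifespan has expired."""
    if cell.cell_type == STEM:
        raise ValueError("stem cells are immortal")
    state.despawn(cell)
    state.log("die", cell.id, cell.lineage_id, cell.cell_type, "", cell.idx)


# ---------------------------------------------------------------------------
# Movement
# ---------------------------------------------------------------------------


def attempt_move(state, cell: CellAgent, params: ParameterSet, rng,
                 random_move_prob: float = 0.0) -> bool:
    """One greedy movement step within the type's position domain.

    Candidate compartments are the placeable Moore neighbours inside the
    domain.  Staying put competes with the candidates for every type except
    differentiating spermatogonia (whose horizontal bias would otherwise
    freeze them); ties are broken uniformly at random.  Returns True if the
    cell moved.
    """
    grid = state.grid
    t = cell.cell_type
    idx = cell.idx
    cand = [j for j in grid.neighbor_idx[idx] if grid.can_place_idx(j, t)]
    if not cand:
        return False
    if random_move_prob > 0.0 and rng.random() < random_move_prob:
        best = cand
    elif t == STEM:
        md = grid.marker_dist
        best, bs = [idx], md[idx]
        for j in cand:
            s = md[j]
            if s < bs:
                best, bs = [j], s
            elif s == bs:
                best.append(j)
    elif t == DIFF_SPG:
        rad = grid.radius
        r0 = rad[idx]
        best, bs = [], 1e9
        for j in cand:
            s = abs(rad[j] - r0)
            if s < bs:
                best, bs = [j], s
            elif s == bs:
                best.append(j)
    else:  # all other types descend toward the lumen
        rad = grid.radius
        best, bs = [idx], rad[idx]
        for j in cand:
            s = rad[j]
            if s < bs:
                best, bs = [j], s
            elif s == bs:
                best.append(j)
    j = best[rng.randrange(len(best))] if len(best) > 1 else best[0]
    if j == idx:
        return False
    state.move(cell, j)
    return True


# ---------------------------------------------------------------------------
# Differentiation and release
# ---------------------------------------------------------------------------


def apply_differentiation(state, cell: CellAgent, params: ParameterSet,
                          rng) -> str:
    """Advance the cell to the next developmental stage, in place.

    The lineage id is preserved; fresh stage timers and a fresh lifespan
    are drawn for the new type.  Position is kept even if it falls outside
    the new type's domain - subsequent movement restores compliance.
    """
    old = cell.cell_type
    new = NEXT_TYPE.get(old)
    if new is None:
        raise ValueError(f"cell type {old} does not differentiate")
    state.retype(cell, new)
    cell.differentiation_timer = params.differentiation_time.get(new)
    cell.division_timer = params.division_time.get(new)
    cell.release_timer = params.release_delay if new == ELONGATED_SPTD else None
    cell.lifespan_timer = draw_lifespan(params, new, rng)
    cell.mitosis_round = 0
    state.log("differentiate", cell.id, cell.lineage_id, old, new, cell.idx)
    return new


def attempt_release(state, cell: CellAgent, params: ParameterSet):
    """Spermiation: a mature elongated spermatid adjacent to the lumen is
    released and becomes sperm; otherwise it keeps moving lumen-ward."""
    grid = state.grid
    region = grid.region
    for j in grid.neighbor_idx[cell.idx]:
        if region[j] == LUMEN:
            ev = SpermEvent(state.clock, cell.lineage_id,
                            grid.position(cell.idx))
            state.despawn(cell)
            state.sperm_events.append(ev)
            state.sperm_this_hour += 1
            state.log("release", cell.id, cell.lineage_id, ELONGATED_SPTD,
                      "sperm", cell.idx)
            return ev
    return None
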