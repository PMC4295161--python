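"""Derived quantities: stage classification, cycle period, sperm-output
success rate, lineage trees and radial profiles.

The seminiferous-epithelium cycle is staged from the cell-type composition
alone: secondary spermatocytes mark stage XII, co-occurring zygotenes and
diplotenes stage XI, leptotenes without round spermatids stages IX-X,
preleptotenes stages VII-VIII, and the spermatogonia + pachytene + round +
elongated association stages I-VI.  Sub-stage indices within a group are
assigned by equal time-subdivision of the group's dwell time, giving the
canonical 12-stage sequence per cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parameters import (DIFF_SPG, DIPLOTENE, ELONGATED_SPTD, LEPTOTENE,
                         PACHYTENE, PRELEPTOTENE, ROUND_SPTD, SECONDARY,
                         STEM, TYPE_ORDER, ZYGOTENE)
from .rules import max_sperm_per_asymmetric_division
from .simulation import SimulationResult

__all__ = ["StageLabel", "classify_stage", "label_stages", "estimate_period",
           "cycle_anchors",
           "SuccessRate", "success_rate", "transit_times", "LineageTree",
           "LineageNode", "trace_lineage", "radial_profile",
           "stem_divisions"]


# ---------------------------------------------------------------------------
# Stage classification
# ---------------------------------------------------------------------------

#: composition groups and their sub-stage index ranges
GROUP_RANGES = {"I-VI": (1, 6), "VII-VIII": (7, 8), "IX-X": (9, 10),
                "XI": (11, 11), "XII": (12, 12)}

GROUP_SEQUENCE = ("I-VI", "VII-VIII", "IX-X", "XI", "XII")


@dataclass(frozen=True)
class StageLabel:
    """A stage call: composition group plus (optional) 1-12 sub-index."""

    group: str
    stage_index: int | None = None


def classify_stage(composition) -> StageLabel:
    """Classify one cell-type composition into a stage group.

    ``composition`` is a mapping from cell-type name to count (missing
    types count as zero).  The decision list mirrors the defining cell
    associations of the cycle; compositions matching none of them (e.g.
    spermatogonia only, after germ-cell depletion) are ``arrested``.
    """
    get = composition.get if hasattr(composition, "get") else composition.__getitem__
    n = {t: (get(t) or 0) for t in TYPE_ORDER}
    if n[SECONDARY] > 0:
        return StageLabel("XII", 12)
    if n[ZYGOTENE] > 0 and n[DIPLOTENE] > 0:
        return StageLabel("XI", 11)
    if n[LEPTOTENE] > 0 and n[ROUND_SPTD] == 0:
        return StageLabel("IX-X")
    if n[PRELEPTOTENE] > 0:
        return StageLabel("VII-VIII")
    if (n[PACHYTENE] > 0 and n[ROUND_SPTD] > 0 and n[PRELEPTOTENE] == 0
            and n[LEPTOTENE] == 0 and n[ZYGOTENE] == 0):
        return StageLabel("I-VI")
    return StageLabel("arrested")


def label_stages(result: SimulationResult) -> list[StageLabel]:
    """Per-hour stage labels with interpolated sub-stage indices.

    Within each maximal run of one composition group the run is divided
    into that group's number of stages in equal time shares (e.g. a 90-hour
    I-VI association yields stages I..VI of 15 hours each).
    """
    comps = [dict(zip(TYPE_ORDER, row)) for row in result.counts]
    groups = [classify_stage(c).group for c in comps]
    labels: list[StageLabel] = []
    i, H = 0, len(groups)
    while i < H:
        j = i
        while j < H and groups[j] == groups[i]:
            j += 1
        rng = GROUP_RANGES.get(groups[i])
        for k in range(i, j):
            if rng is None:
                labels.append(StageLabel(groups[i], None))
            else:
                lo, hi = rng
                nsub = hi - lo + 1
                sub = min((k - i) * nsub // (j - i), nsub - 1)
                labels.append(StageLabel(groups[i], lo + sub))
        i = j
    return labels


# ---------------------------------------------------------------------------
# Cycle period
# ---------------------------------------------------------------------------


def _onsets(series: np.ndarray) -> np.ndarray:
    """Hours at which a count series rises from zero to positive."""
    s = np.asarray(series)
    rising = (s[1:] > 0) & (s[:-1] == 0)
    onsets = np.flatnonzero(rising) + 1
    if s.size and s[0] > 0:
        onsets = np.concatenate([[0], onsets])
    return onsets


def estimate_period(series, min_cycles: int = 3) -> float:
    """Cycle period of one type's hourly count series, in hours.

    Uses the mean spacing of onset anchors (count rising from zero); when
    fewer than three anchors exist, falls back to the first peak of the
    autocorrelation function.  Returns ``nan`` when no recurrence is found.
    ``series`` should span at least ``min_cycles`` expected periods.
    """
    s = np.asarray(series, dtype=float)
    onsets = _onsets(s)
    if len(onsets) >= 3:
        return float(np.mean(np.diff(onsets)))
    x = s - s.mean()
    if not x.any():
        return float("nan")
    ac = np.correlate(x, x, mode="full")[x.size - 1:]
    # first local maximum after the zero-lag peak has fully decayed: skip
    # to the first local minimum, then take the highest peak after it
    if ac.size < 20:
        return float("nan")
    d = np.diff(ac)
    turning = np.flatnonzero(d[:-1] < 0) if d.size else np.array([])
    rising = np.flatnonzero((d[:-1] <= 0) & (d[1:] > 0))
    if rising.size == 0:
        return float("nan")
    lo = int(rising[0]) + 1
    seg = ac[lo:int(ac.size * 0.9)]
    if seg.size == 0 or seg.max() <= 0:
        return float("nan")
    return float(lo + int(np.argmax(seg)))


# ---------------------------------------------------------------------------
# Success rate of sperm production
# ---------------------------------------------------------------------------


def _cycle_of(times, anchors) -> np.ndarray:
    """Cycle index of each time: cycle c spans [anchor_c, anchor_{c+1})."""
    return np.searchsorted(anchors, np.asarray(times), side="right") - 1


def cycle_anchors(result: SimulationResult, min_fraction: float = 0.6) -> np.ndarray:
    """Consolidated cycle anchors for per-cycle accounting.

    A delayed spermatogonial clone can produce a brief extra preleptotene
    onset inside a cycle; onsets following the previous anchor by less
    than ``min_fraction`` of the median spacing are merged away so cycle
    windows keep their nominal length.
    """
    anchors = np.asarray(result.anchors)
    if anchors.size < 3:
        return anchors
    med = np.median(np.diff(anchors))
    keep = [int(anchors[0])]
    for a in anchors[1:]:
        if a - keep[-1] >= min_fraction * med:
            keep.append(int(a))
    return np.asarray(keep)


def stem_divisions(result: SimulationResult) -> list[tuple[int, str]]:
    """(time, daughter lineage id) of every asymmetric stem division."""
    return [(e[0], e[5]) for e in result.events
            if e[1] == "divide" and e[4] == STEM]


@dataclass
class SuccessRate:
    """Per-cycle and aggregate sperm-production success."""

    cycles: list[int]
    per_cycle: np.ndarray
    aggregate: float


def success_rate(result: SimulationResult,
                 cycle_window: tuple[int, int] | None = None) -> SuccessRate:
    """Fraction of the maximal potential sperm output actually released.

    For cycle ``c``, released sperm are attributed to the stem divisions
    four cycles earlier (the stem-to-sperm transit is four cycles):
    ``rate_c = sperm_c / (max_per_division * stem_divisions_{c-4})``.
    ``cycle_window = (first, last)`` restricts the aggregated cycles
    (half-open, in cycle indices); by default every complete cycle with a
    defined denominator from cycle 4 onward is used.
    """
    anchors = cycle_anchors(result)
    if anchors.size < 5:
        return SuccessRate([], np.array([]), float("nan"))
    cap = max_sperm_per_asymmetric_division(result.params)
    n_cycles = anchors.size - 1  # complete cycles only
    div_times = [t for t, _ in stem_divisions(result)]
    div_per = np.bincount(
        [c for c in _cycle_of(div_times, anchors) if 0 <= c < n_cycles],
        minlength=n_cycles)
    sperm_times = [ev.time for ev in result.sperm_events]
    sperm_per = np.bincount(
        [c for c in _cycle_of(sperm_times, anchors) if 0 <= c < n_cycles],
        minlength=n_cycles)
    lo, hi = 4, n_cycles
    if cycle_window is not None:
        lo = max(lo, cycle_window[0])
        hi = min(hi, cycle_window[1])
    cycles = [c for c in range(lo, hi) if div_per[c - 4] > 0]
    rates = np.array([sperm_per[c] / (cap * div_per[c - 4]) for c in cycles])
    agg = float(rates.mean()) if rates.size else float("nan")
    return SuccessRate(cycles, rates, agg)


def transit_times(result: SimulationResult) -> list[int]:
    """Stem-division-to-first-descendant-sperm intervals, in hours.

    For every asymmetric stem division whose clone released at least one
    sperm, the interval to the earliest such release.
    """
    first_release: dict[str, int] = {}
    for ev in result.sperm_events:
        parts = ev.lineage_id.split(".")
        if len(parts) < 2:
            continue
        root = parts[0] + "." + parts[1]  # the founding spermatogonium
        if root not in first_release or ev.time < first_release[root]:
            first_release[root] = ev.time
    out = []
    for t, daughter in stem_divisions(result):
        rel = first_release.get(daughter)
        if rel is not None and rel >= t:
            out.append(rel - t)
    return out


# ---------------------------------------------------------------------------
# Lineage trees
# ---------------------------------------------------------------------------


@dataclass
class LineageNode:
    lineage_id: str
    birth_time: int | None = None
    type_history: list[tuple[int, str]] = field(default_factory=list)
    fate: str = "alive"
    fate_time: int | None = None
    children: list[str] = field(default_factory=list)


@dataclass
class LineageTree:
    """The developmental tree descending from one lineage id."""

    root: str
    nodes: dict[str, LineageNode]

    @property
    def leaves(self) -> list[LineageNode]:
        return [n for n in self.nodes.values() if not n.children]

    def fate_counts(self) -> dict[str, int]:
        out = {"sperm": 0, "died": 0, "alive": 0}
        for n in self.leaves:
            out[n.fate] += 1
        return out


def trace_lineage(result: SimulationResult, root_lineage_id: str) -> LineageTree:
    """Reconstruct the lineage tree rooted at ``root_lineage_id`` from the
    event log; raises ``KeyError`` for an unknown root."""
    prefix = root_lineage_id + "."
    nodes: dict[str, LineageNode] = {}
    seen = False

    def node(lid: str) -> LineageNode:
        if lid not in nodes:
            nodes[lid] = LineageNode(lid)
        return nodes[lid]

    for t, event, _cid, lid, before, after, _idx in result.events:
        if not (lid == root_lineage_id or lid.startswith(prefix)):
            continue
        seen = True
        n = node(lid)
        if event == "divide":
            if before in (DIPLOTENE, SECONDARY):
                for child in after.split("+"):
                    c = node(child)
                    c.birth_time = t
                    c.type_history.append((t, {DIPLOTENE: SECONDARY,
                                               SECONDARY: ROUND_SPTD}[before]))
                    n.children.append(child)
                n.fate = "divided"
                n.fate_time = t
            else:  # stem or spermatogonial symmetric division
                c = node(after)
                c.birth_time = t
                c.type_history.append((t, DIFF_SPG))
                n.children.append(after)
        elif event == "differentiate":
            n.type_history.append((t, after))
        elif event == "die":
            n.fate, n.fate_time = "died", t
        elif event == "release":
            n.fate, n.fate_time = "sperm", t
    if not seen and root_lineage_id not in nodes:
        raise KeyError(f"lineage id {root_lineage_id!r} not found in the "
                       f"event log")
    node(root_lineage_id)
    # interior meiotic parents are not leaves; scrub their transient fate
    for n in nodes.values():
        if n.children and n.fate == "divided":
            n.fate = "alive"
    return LineageTree(root_lineage_id, nodes)


# ---------------------------------------------------------------------------
# Radial profiles
# ---------------------------------------------------------------------------


def radial_profile(result: SimulationResult):
    """Hourly mean distance to the tubule centre per type (compartments);
    ``NaN`` marks hours at which the type is absent."""
    import pandas as pd
    df = pd.DataFrame(result.radial_mean, columns=list(result.type_order))
    df.insert(0, "hour", np.arange(1, result.hours + 1))
    return df
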