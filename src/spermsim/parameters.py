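"""Parameter registry for the spermatogenic-cycle simulator.

Ten germ-cell types develop on a cross-section of the mouse seminiferous
tubule.  All kinetics are expressed as integer hourly timers: division times
for the four dividing types, differentiation times for the six types that
transition in place, and a uniform lifespan window for every non-stem type
(spermatogonial stem cells are immortal; their population is controlled by
division only).  The 29 scalars exposed to the global sensitivity sweep are
the 4 division times, 6 differentiation times, 18 lifespan bounds and the
initial stem-cell count.

Three baseline values are anchored to published perturbation experiments
(preleptotene differentiation 44 h, spermatogonial division 88 h,
preleptotene feedback threshold 5).  Every other default is the product of
the calibration procedure in :mod:`spermsim.simulation` (see
``docs/methods.md``): the shipped set reproduces an 8.6-day cycle, a 35-day
stem-to-sperm transit, the 12-stage composition sequence and the published
sperm-output statistics.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass

import yaml

__all__ = [
    "CellType",
    "CELL_TYPES",
    "TYPE_ORDER",
    "GridGeometry",
    "ParameterSet",
    "SweepEntry",
    "default_parameters",
    "validate",
    "sweepable_parameters",
    "apply_sweep",
    "load_params",
    "save_params",
    "params_to_flat",
    "params_from_flat",
]

# ---------------------------------------------------------------------------
# Cell types
# ---------------------------------------------------------------------------

STEM = "stem"
DIFF_SPG = "diff_spg"
PRELEPTOTENE = "preleptotene"
LEPTOTENE = "leptotene"
ZYGOTENE = "zygotene"
PACHYTENE = "pachytene"
DIPLOTENE = "diplotene"
SECONDARY = "secondary"
ROUND_SPTD = "round_sptd"
ELONGATED_SPTD = "elongated_sptd"

#: canonical developmental order of the ten germ-cell types
TYPE_ORDER: tuple[str, ...] = (
    STEM,
    DIFF_SPG,
    PRELEPTOTENE,
    LEPTOTENE,
    ZYGOTENE,
    PACHYTENE,
    DIPLOTENE,
    SECONDARY,
    ROUND_SPTD,
    ELONGATED_SPTD,
)

#: the two spermatid types that may co-occupy one micro-compartment
SPERMATID_TYPES = frozenset({ROUND_SPTD, ELONGATED_SPTD})

#: types whose population changes through division
DIVIDING_TYPES = (STEM, DIFF_SPG, DIPLOTENE, SECONDARY)

#: in-place differentiation map (stem, diplotene, secondary develop by
#: division; the elongated spermatid is terminal)
NEXT_TYPE = {
    DIFF_SPG: PRELEPTOTENE,
    PRELEPTOTENE: LEPTOTENE,
    LEPTOTENE: ZYGOTENE,
    ZYGOTENE: PACHYTENE,
    PACHYTENE: DIPLOTENE,
    ROUND_SPTD: ELONGATED_SPTD,
}

DIFFERENTIATING_TYPES = tuple(NEXT_TYPE)

#: non-stem types (all carry a lifespan window)
MORTAL_TYPES = TYPE_ORDER[1:]


@dataclass(frozen=True)
class CellType:
    """One germ-cell type: its name and cell diameter in micrometres.

    Diameters are morphological metadata used for rendering and for the
    micro-compartment size (13 um, the pachytene diameter); occupancy is
    one cell per compartment except that two spermatids may share one.
    """

    name: str
    diameter_um: float


#: registry of the ten germ-cell types with measured diameters (um);
#: the elongated spermatid entry records its 2-um width
CELL_TYPES: dict[str, CellType] = {
    STEM: CellType(STEM, 9.0),
    DIFF_SPG: CellType(DIFF_SPG, 10.0),
    PRELEPTOTENE: CellType(PRELEPTOTENE, 10.0),
    LEPTOTENE: CellType(LEPTOTENE, 9.0),
    ZYGOTENE: CellType(ZYGOTENE, 9.0),
    PACHYTENE: CellType(PACHYTENE, 13.0),
    DIPLOTENE: CellType(DIPLOTENE, 13.0),
    SECONDARY: CellType(SECONDARY, 11.0),
    ROUND_SPTD: CellType(ROUND_SPTD, 6.0),
    ELONGATED_SPTD: CellType(ELONGATED_SPTD, 2.0),
}


# ---------------------------------------------------------------------------
# Geometry and parameter set
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridGeometry:
    """Circular cross-section geometry in micro-compartment units."""

    compartment_um: float = 13.0
    tubule_radius: int = 14
    lumen_radius: int = 4
    sertoli_count: int = 10
    interstitial_count: int = 5


@dataclass
class ParameterSet:
    """Complete configuration of one simulation.

    ``division_time`` / ``differentiation_time`` are deterministic timers
    (hours); lifespans are drawn uniformly from
    ``[lifespan_min[t], lifespan_max[t]]`` when a cell enters type ``t``.
    ``position_domain`` maps each type to the radial annulus
    ``(inner, outer)`` (compartments) it may occupy.
    """

    division_time: dict[str, int]
    differentiation_time: dict[str, int]
    lifespan_min: dict[str, int]
    lifespan_max: dict[str, int]
    initial_stem_count: int
    preleptotene_threshold: int
    spg_mitosis_rounds: int
    release_delay: int
    geometry: GridGeometry
    position_domain: dict[str, tuple[float, float]]
    initial_counts: dict[str, int]

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)


def default_parameters() -> ParameterSet:
    """The shipped calibrated baseline.

    Anchored values: ``differentiation_time[preleptotene] = 44 h``,
    ``division_time[diff_spg] = 88 h``, ``preleptotene_threshold = 5``.
    The remaining timers place the stage boundaries of the 12-stage cycle
    at their observed phases and sum, along the differentiation path from
    a newborn differentiating spermatogonium to sperm release, to four
    cycles (~35 days).
    """
    return ParameterSet(
        division_time={
            STEM: 190,
            DIFF_SPG: 88,
            DIPLOTENE: 26,
            SECONDARY: 12,
        },
        differentiation_time={
            DIFF_SPG: 205,
            PRELEPTOTENE: 44,
            LEPTOTENE: 30,
            ZYGOTENE: 38,
            PACHYTENE: 168,
            ROUND_SPTD: 138,
        },
        lifespan_min={
            DIFF_SPG: 190,
            PRELEPTOTENE: 41,
            LEPTOTENE: 27,
            ZYGOTENE: 35,
            PACHYTENE: 155,
            DIPLOTENE: 23,
            SECONDARY: 11,
            ROUND_SPTD: 128,
            ELONGATED_SPTD: 200,
        },
        lifespan_max={
            DIFF_SPG: 280,
            PRELEPTOTENE: 82,
            LEPTOTENE: 68,
            ZYGOTENE: 76,
            PACHYTENE: 340,
            DIPLOTENE: 64,
            SECONDARY: 31,
            ROUND_SPTD: 250,
            ELONGATED_SPTD: 300,
        },
        initial_stem_count=10,
        preleptotene_threshold=5,
        spg_mitosis_rounds=3,
        release_delay=196,
        geometry=GridGeometry(),
        position_domain={
            STEM: (13.0, 14.0),
            DIFF_SPG: (13.0, 14.0),
            PRELEPTOTENE: (12.0, 14.0),
            LEPTOTENE: (10.0, 13.0),
            ZYGOTENE: (10.0, 13.0),
            PACHYTENE: (8.0, 12.0),
            DIPLOTENE: (8.0, 12.0),
            SECONDARY: (8.0, 12.0),
            ROUND_SPTD: (5.0, 9.0),
            ELONGATED_SPTD: (4.0, 6.0),
        },
        initial_counts={
            STEM: 10,
            DIFF_SPG: 20,
            PACHYTENE: 30,
            ROUND_SPTD: 100,
            ELONGATED_SPTD: 90,
        },
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate(params: ParameterSet) -> list[str]:
    """Return the list of invariant violations (empty iff valid).

    Violations are returned as data, one human-readable string naming the
    offending field and the broken rule each, rather than raised.
    """
    v: list[str] = []
    for name, expected in (
        ("division_time", set(DIVIDING_TYPES)),
        ("differentiation_time", set(DIFFERENTIATING_TYPES)),
        ("lifespan_min", set(MORTAL_TYPES)),
        ("lifespan_max", set(MORTAL_TYPES)),
    ):
        mapping = getattr(params, name)
        if set(mapping) != expected:
            v.append(f"{name}: expected exactly types {sorted(expected)}, "
                     f"got {sorted(mapping)}")
        for t, val in mapping.items():
            if val <= 0:
                v.append(f"{name}[{t}] = {val}: timers must be > 0")
    if STEM in params.lifespan_min or STEM in params.lifespan_max:
        v.append("lifespan: stem cells are immortal and carry no lifespan")
    for t in MORTAL_TYPES:
        lo = params.lifespan_min.get(t)
        hi = params.lifespan_max.get(t)
        if lo is not None and hi is not None and lo > hi:
            v.append(f"lifespan[{t}]: lifespan_min ({lo}) > lifespan_max ({hi})")
    if params.initial_stem_count < 1:
        v.append(f"initial_stem_count = {params.initial_stem_count}: must be >= 1")
    if params.preleptotene_threshold < 1:
        v.append("preleptotene_threshold: must be >= 1")
    if params.spg_mitosis_rounds < 0:
        v.append("spg_mitosis_rounds: must be >= 0")
    if params.release_delay <= 0:
        v.append("release_delay: must be > 0")
    g = params.geometry
    if g.lumen_radius >= g.tubule_radius:
        v.append(f"geometry: lumen_radius ({g.lumen_radius}) must be < "
                 f"tubule_radius ({g.tubule_radius})")
    if g.sertoli_count < 0 or g.interstitial_count < 0:
        v.append("geometry: sertoli_count and interstitial_count must be >= 0")
    for t in TYPE_ORDER:
        dom = params.position_domain.get(t)
        if dom is None:
            v.append(f"position_domain[{t}]: missing")
            continue
        inner, outer = dom
        if not (g.lumen_radius <= inner <= outer <= g.tubule_radius):
            v.append(f"position_domain[{t}] = {dom}: must lie within "
                     f"[{g.lumen_radius}, {g.tubule_radius}]")
    for t, n in params.initial_counts.items():
        if t not in TYPE_ORDER:
            v.append(f"initial_counts: unknown cell type {t!r}")
        elif n < 0:
            v.append(f"initial_counts[{t}] = {n}: must be >= 0")
    if params.initial_counts.get(STEM) != params.initial_stem_count:
        v.append("initial_counts[stem] must equal initial_stem_count")
    return v


# ---------------------------------------------------------------------------
# Sensitivity sweep registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SweepEntry:
    """One sweepable scalar: dotted name, baseline, and range policy.

    ``policy`` is ``"standard"`` (sampled in 0.5-1.5x of baseline) or
    ``"lifespan"`` (sampled between 0.5x the baseline minimum and the
    baseline maximum of that type's lifespan window).
    """

    name: str
    baseline: float
    policy: str
    low: float
    high: float


def sweepable_parameters(params: ParameterSet) -> list[SweepEntry]:
    """The ordered registry of the 29 scalars exposed to the sweep.

    Order is deterministic: division times, differentiation times, lifespan
    minima, lifespan maxima (each in developmental type order), then the
    initial stem-cell count.
    """
    entries: list[SweepEntry] = []
    for t in TYPE_ORDER:
        if t in params.division_time:
            b = params.division_time[t]
            entries.append(SweepEntry(f"division_time.{t}", b, "standard",
                                      0.5 * b, 1.5 * b))
    for t in TYPE_ORDER:
        if t in params.differentiation_time:
            b = params.differentiation_time[t]
            entries.append(SweepEntry(f"differentiation_time.{t}", b, "standard",
                                      0.5 * b, 1.5 * b))
    for bound in ("lifespan_min", "lifespan_max"):
        mapping = getattr(params, bound)
        for t in TYPE_ORDER:
            if t in mapping:
                lo = 0.5 * params.lifespan_min[t]
                hi = float(params.lifespan_max[t])
                entries.append(SweepEntry(f"{bound}.{t}", mapping[t],
                                          "lifespan", lo, hi))
    entries.append(SweepEntry("initial_stem_count",
                              params.initial_stem_count, "standard",
                              0.5 * params.initial_stem_count,
                              1.5 * params.initial_stem_count))
    assert len(entries) == 29
    return entries


def apply_sweep(params: ParameterSet, names: list[str],
                values: list[float]) -> ParameterSet:
    """Build a new ParameterSet with the named sweep scalars replaced.

    Timer values are rounded to whole hours (minimum 1); the stem count is
    rounded to an integer >= 1.  If a sampled lifespan pair is out of order
    the two bounds are swapped, so the resulting set is always valid.
    """
    p = params.copy()
    for name, value in zip(names, values):
        if name == "initial_stem_count":
            n = max(1, round(value))
            p.initial_stem_count = n
            p.initial_counts[STEM] = n
            continue
        group, t = name.split(".")
        getattr(p, group)[t] = max(1, round(value))
    for t in MORTAL_TYPES:
        lo, hi = p.lifespan_min[t], p.lifespan_max[t]
        if lo > hi:
            p.lifespan_min[t], p.lifespan_max[t] = hi, lo
    return p


# ---------------------------------------------------------------------------
# YAML configuration (flat dotted keys)
# ---------------------------------------------------------------------------


def params_to_flat(params: ParameterSet) -> dict:
    """Flatten a ParameterSet into dotted scalar keys for YAML/JSON."""
    flat: dict = {}
    for group in ("division_time", "differentiation_time",
                  "lifespan_min", "lifespan_max"):
        for t, val in getattr(params, group).items():
            flat[f"{group}.{t}"] = val
    for name in ("initial_stem_count", "preleptotene_threshold",
                 "spg_mitosis_rounds", "release_delay"):
        flat[name] = getattr(params, name)
    for f in dataclasses.fields(GridGeometry):
        flat[f"geometry.{f.name}"] = getattr(params.geometry, f.name)
    for t, (inner, outer) in params.position_domain.items():
        flat[f"position_domain.{t}"] = [inner, outer]
    for t, n in params.initial_counts.items():
        flat[f"initial_counts.{t}"] = n
    return flat


def params_from_flat(flat: dict, base: ParameterSet | None = None) -> ParameterSet:
    """Build a ParameterSet from dotted keys, overriding ``base`` defaults."""
    p = (base or default_parameters()).copy()
    geo = dataclasses.asdict(p.geometry)
    for key, val in flat.items():
        if key.startswith("geometry."):
            geo[key.split(".", 1)[1]] = val
        elif key.startswith("position_domain."):
            p.position_domain[key.split(".", 1)[1]] = (float(val[0]), float(val[1]))
        elif key.startswith("initial_counts."):
            p.initial_counts[key.split(".", 1)[1]] = int(val)
        elif "." in key:
            group, t = key.split(".", 1)
            getattr(p, group)[t] = int(val)
        else:
            setattr(p, key, int(val))
    p.geometry = GridGeometry(**geo)
    if "initial_stem_count" in flat and "initial_counts.stem" not in flat:
        p.initial_counts[STEM] = p.initial_stem_count
    return p


def load_params(path) -> ParameterSet:
    """Load a YAML config of flat dotted keys over the shipped defaults."""
    with open(path) as fh:
        flat = yaml.safe_load(fh) or {}
    return params_from_flat(flat)


def save_params(params: ParameterSet, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params_to_flat(params), fh, sort_keys=True)
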