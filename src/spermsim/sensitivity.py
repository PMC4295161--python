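"""Global parameter sensitivity: Latin hypercube sampling over the
29-scalar registry and partial rank correlation coefficients (PRCC).

Each of the 29 kinetic scalars is sampled uniformly within its policy
range (0.5-1.5x baseline for timers and the stem count; between half the
baseline minimum and the baseline maximum for lifespan bounds) with one
draw per equal-probability stratum per dimension.  Every sampled set is
simulated for one baseline cycle length from Stage I, several seeded
replicates each, and the output per cell type is the time-average count
over that cycle, averaged across replicates.

PRCC measures the monotone input-output association of one parameter
after removing the linear effects of the other parameters on the ranks;
it is computed here from the precision matrix of the rank-transformed
design, with two-sided p-values from a Student's t distribution on
``n - 2 - (K - 1)`` degrees of freedom.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.stats import qmc

from .parameters import (ParameterSet, TYPE_ORDER, apply_sweep,
                         default_parameters, sweepable_parameters)
from .simulation import run, stage_schedule

__all__ = ["SampleDesign", "SensitivityResult", "lhs_sample", "prcc",
           "run_sensitivity", "SIGNIFICANCE_P"]

#: significance level for the PRCC t-test
SIGNIFICANCE_P = 0.005


@dataclass
class SampleDesign:
    """A Latin-hypercube design over the sweepable parameters."""

    n_samples: int = 300
    n_reps: int = 3
    seed: int = 0
    ranges: list[tuple[str, float, float]] | None = None  # (name, low, high)

    def resolve_ranges(self, params: ParameterSet) -> list[tuple[str, float, float]]:
        if self.ranges is not None:
            return self.ranges
        return [(e.name, e.low, e.high) for e in sweepable_parameters(params)]


def lhs_sample(design: SampleDesign,
               params: ParameterSet | None = None) -> tuple[np.ndarray, list[str]]:
    """Draw the design matrix: ``n_samples`` rows, one column per swept
    scalar; per column exactly one draw falls in each of the
    ``n_samples`` equal-width strata of its range."""
    ranges = design.resolve_ranges(params or default_parameters())
    names = [r[0] for r in ranges]
    sampler = qmc.LatinHypercube(d=len(ranges), seed=design.seed)
    unit = sampler.random(design.n_samples)
    lows = np.array([r[1] for r in ranges])
    highs = np.array([r[2] for r in ranges])
    return qmc.scale(unit, lows, highs), names


# ---------------------------------------------------------------------------
# PRCC
# ---------------------------------------------------------------------------


def _rank(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=0)


def prcc(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """PRCC and two-sided p-value of each column of ``X`` against ``y``.

    Constant input columns carry no rank information; they are flagged
    with a warning and reported as ``NaN``.
    Requires ``n_samples > n_parameters + 2``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    if n <= k + 2:
        raise ValueError(f"PRCC needs more samples ({n}) than "
                         f"parameters + 2 ({k + 2})")
    keep = np.array([np.ptp(X[:, j]) > 0 for j in range(k)])
    if not keep.all():
        warnings.warn("constant parameter columns excluded from PRCC: "
                      + ", ".join(map(str, np.flatnonzero(~keep))))
    out_r = np.full(k, np.nan)
    out_p = np.full(k, np.nan)
    Xk = X[:, keep]
    kk = Xk.shape[1]
    Z = np.column_stack([_rank(Xk), _rank(y)])
    C = np.corrcoef(Z, rowvar=False)
    # partial correlations from the precision matrix; the tiny ridge keeps
    # the exactly-collinear limit (a noiseless monotone response) at +/-1
    # with the correct sign instead of a singular inversion
    P = np.linalg.inv(C + 1e-12 * np.eye(C.shape[0]))
    denom = np.sqrt(np.outer(np.diag(P), np.diag(P)))
    partial = -P / denom
    r = partial[:-1, -1]
    df = n - 2 - (kk - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt(df / np.clip(1.0 - r ** 2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    out_r[keep] = np.clip(r, -1.0, 1.0)
    out_p[keep] = p
    return out_r, out_p


# ---------------------------------------------------------------------------
# Full analysis
# ---------------------------------------------------------------------------


@dataclass
class SensitivityResult:
    """PRCC/p matrices: rows = swept parameters, columns = cell types."""

    parameter_names: list[str]
    output_types: list[str]
    prcc: np.ndarray
    pvalues: np.ndarray
    design_matrix: np.ndarray
    outputs: np.ndarray
    dropped_samples: list[int] = field(default_factory=list)

    @property
    def significant(self) -> np.ndarray:
        return self.pvalues < SIGNIFICANCE_P

    def significant_parameters(self) -> list[str]:
        """Parameters with a significant PRCC for at least one type."""
        mask = np.nan_to_num(self.pvalues, nan=1.0) < SIGNIFICANCE_P
        return [n for n, row in zip(self.parameter_names, mask) if row.any()]

    def to_frame(self):
        import pandas as pd
        rows = []
        for i, name in enumerate(self.parameter_names):
            for j, t in enumerate(self.output_types):
                rows.append((name, t, self.prcc[i, j], self.pvalues[i, j],
                             bool(self.pvalues[i, j] < SIGNIFICANCE_P)))
        return pd.DataFrame(rows, columns=["parameter", "output_type",
                                           "prcc", "p", "significant"])


def _sample_outputs(params: ParameterSet, window: int, n_reps: int,
                    seed_base: int) -> np.ndarray:
    reps = np.empty((n_reps, len(TYPE_ORDER)))
    for r in range(n_reps):
        res = run(params, hours=window, seed=(seed_base + r) % (2 ** 31 - 1),
                  record_events=False, record_radial=False)
        reps[r] = res.counts.mean(axis=0)
    return reps.mean(axis=0)


def run_sensitivity(params: ParameterSet | None = None,
                    design: SampleDesign | None = None,
                    window_hours: int | None = None,
                    progress: bool = False) -> SensitivityResult:
    """LHS + simulation + PRCC over the 29-parameter registry.

    Outputs are per-type mean counts over one baseline cycle from Stage I
    (``window_hours`` overrides the window).  Individual simulation
    failures drop the sample with a warning; the analysis proceeds when at
    least 90% of the design is retained.
    """
    params = params or default_parameters()
    design = design or SampleDesign()
    window = window_hours or stage_schedule(params)["period"]
    X, names = lhs_sample(design, params)
    n = X.shape[0]
    Y = np.empty((n, len(TYPE_ORDER)))
    dropped: list[int] = []
    for i in range(n):
        cand = apply_sweep(params, names, list(X[i]))
        try:
            Y[i] = _sample_outputs(cand, window, design.n_reps,
                                   seed_base=design.seed * 1000003 + i * design.n_reps)
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"sample {i} failed and was dropped: {exc}")
            dropped.append(i)
        if progress and (i + 1) % 25 == 0:
            print(f"  sensitivity: {i + 1}/{n} samples", flush=True)
    keep = np.setdiff1d(np.arange(n), dropped)
    if keep.size < math.ceil(0.9 * n):
        raise RuntimeError(f"only {keep.size}/{n} sensitivity samples "
                           f"succeeded; design invalid")
    Xk, Yk = X[keep], Y[keep]
    R = np.empty((len(names), len(TYPE_ORDER)))
    P = np.empty_like(R)
    for j in range(len(TYPE_ORDER)):
        R[:, j], P[:, j] = prcc(Xk, Yk[:, j])
    return SensitivityResult(names, list(TYPE_ORDER), R, P, Xk, Yk, dropped)
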