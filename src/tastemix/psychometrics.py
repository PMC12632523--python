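"""Four-parameter logistic psychometrics and extra-sum-of-squares curve tests.

The psychometric model is

    y(s) = (p1 - p4) / (1 + exp(-p2 (s - p3))) + p4,

with y the probability of a sucrose-side choice, s the %Sucrose of the
mixture, p1/p4 the upper/lower asymptotes, p2 the slope and p3 the inflection
point.  Fits are bounded least squares on per-stimulus mean responses
(0 <= p1 <= 1, 15 <= p3 <= 85, 0 <= p4 <= 1; the slope is unbounded), with a
deterministic multi-start over the slope so ascending and descending curves
are both reachable.

Curves are compared with an extra-sum-of-squares F-test: one curve fitted to
the pooled points (SSE1, df1 = N - 4) against separate curves per dataset
(SSE2, df2 = N - 8 for two datasets), F = ((SSE1-SSE2)/SSE2) * df2/(df1-df2),
with the p-value from the upper tail of F(df1-df2, df2) and an optional
Bonferroni multiplier of K-choose-2 for K curves under consideration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import expit

__all__ = ["logistic_4pl", "Psychometric4PL", "CurveComparison",
           "fit_psychometric", "compare_curves"]

BOUNDS_LO = (0.0, -np.inf, 15.0, 0.0)
BOUNDS_HI = (1.0, np.inf, 85.0, 1.0)
SLOPE_STARTS = (0.02, -0.02, 0.1, -0.1, 0.5, -0.5)


def logistic_4pl(s, p1, p2, p3, p4):
    """Evaluate the 4PL at stimulus value(s) ``s``."""
    s = np.asarray(s, dtype=float)
    return (p1 - p4) * expit(p2 * (s - p3)) + p4


@dataclass(frozen=True)
class Psychometric4PL:
    p1: float
    p2: float
    p3: float
    p4: float
    sse: float
    n_points: int

    @property
    def params(self) -> tuple[float, float, float, float]:
        return (self.p1, self.p2, self.p3, self.p4)

    def __call__(self, s):
        return logistic_4pl(s, *self.params)


@dataclass(frozen=True)
class CurveComparison:
    sse_joint: float
    sse_separate: float
    df_joint: int
    df_separate: int
    fstat: float
    p_value: float
    p_corrected: float
    bonferroni_k: int
    degenerate: bool = False


def _fit_once(s, y, p0) -> tuple[np.ndarray, float]:
    res = optimize.least_squares(
        lambda p: logistic_4pl(s, *p) - y, p0,
        bounds=(BOUNDS_LO, BOUNDS_HI), method="trf", xtol=1e-12, ftol=1e-12,
    )
    return res.x, float(np.sum(res.fun ** 2))


def fit_psychometric(points: Sequence[tuple[float, float]] | np.ndarray) -> Psychometric4PL:
    """Fit the 4PL to (stimulus, mean P(sucrose_side)) points.

    Requires at least 5 points so the separate-fit degrees of freedom stay
    positive.  The fit is deterministic: a fixed grid of slope starts is tried
    and the lowest-SSE solution returned.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (s, mean response)")
    if pts.shape[0] < 5:
        raise ValueError("need at least 5 points to fit a 4-parameter curve")
    s, y = pts[:, 0], pts[:, 1]
    ymax, ymin = float(np.max(y)), float(np.min(y))
    p3_0 = float(np.clip(np.median(s), 15, 85))
    best: tuple[np.ndarray, float] | None = None
    for p2_0 in SLOPE_STARTS:
        p0 = (np.clip(ymax, 0, 1), p2_0, p3_0, np.clip(ymin, 0, 1))
        try:
            sol = _fit_once(s, y, p0)
        except Exception:
            continue
        if best is None or sol[1] < best[1]:
            best = sol
    if best is None:
        raise RuntimeError("psychometric fit failed from all starts")
    p, sse = best
    return Psychometric4PL(*map(float, p), sse=sse, n_points=len(s))


def compare_curves(datasets: Sequence[np.ndarray], K: int | None = None) -> CurveComparison:
    """Extra-sum-of-squares F-test: one pooled curve vs separate curves.

    ``datasets`` is a sequence of (n_i, 2) point arrays.  ``K`` is the total
    number of curves under consideration for the Bonferroni multiplier
    (default: the number of datasets).
    """
    if len(datasets) < 2:
        raise ValueError("need at least 2 datasets to compare")
    arrays = [np.asarray(d, dtype=float) for d in datasets]
    pooled = np.vstack(arrays)
    n_points = pooled.shape[0]
    joint = fit_psychometric(pooled)
    sse2 = sum(fit_psychometric(a).sse for a in arrays)
    sse1 = joint.sse
    df1 = n_points - 4
    df2 = n_points - 4 * len(arrays)
    if df2 < 1:
        raise ValueError("too few points for separate fits (df2 < 1)")
    K = K if K is not None else len(arrays)
    kchoose2 = max(1, math.comb(K, 2))
    if sse2 <= 0:
        return CurveComparison(sse1, sse2, df1, df2, float("inf"), 0.0, 0.0,
                               kchoose2, degenerate=True)
    fstat = max(0.0, (sse1 - sse2) / sse2 * df2 / (df1 - df2))
    p = float(stats.f.sf(fstat, df1 - df2, df2))
    return CurveComparison(sse1, sse2, df1, df2, float(fstat), p,
                           min(1.0, p * kchoose2), kchoose2)


def psychometric_points(trial_table) -> np.ndarray:
    """Per-stimulus mean P(sucrose_side) from a trial table DataFrame."""
    grp = trial_table.groupby("stim_pct_sucrose")["choice"]
    means = grp.apply(lambda c: float(np.mean(c == "sucrose_side")))
    return np.column_stack([means.index.to_numpy(float), means.to_numpy(float)])
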