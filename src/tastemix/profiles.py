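"""Tuning-curve shape classification: linear vs step vs other.

A unit's response profile in a time window is its mean rate as a function of
the 8 mixture stimuli (correct trials).  Two templates are fitted by least
squares: a 2-parameter line f(s) = p1*s + p2, constrained so the fitted line
is nonnegative at all 8 stimulus values, and a 3-parameter step function with
inflection p3 restricted to {40, 50, 60} and plateau levels equal to the
side means.  Each template is scored against the mean-only null model with
the extra-sum-of-squares F statistic

    F = [(SSE_null - SSE_fit) / SSE_fit] * (Nd - Np) / (Np - 1),

and the winner (larger F) is assigned only if its upper-tail F(Np-1, Nd-Np)
p-value is below alpha = 0.005 (0.01 Bonferroni-corrected for the two
templates); otherwise the profile is "other".

Step winners are sub-classified with error trials: delta_x is the
above-50-minus-below-50 mean rate difference on outcome x.  A step at
p3 = 50 whose correct- and error-trial deltas have opposite signs is
"step_choice" (the unit follows the chosen side); consistent signs give
"step_perception"; a missing error side leaves the step unresolved.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .session import STIMULUS_SET
from .warp import WarpAxis

__all__ = ["ResponseProfile", "ShapeFit", "CodingLabel", "response_profile",
           "fit_line", "fit_step", "classify_profile", "coding_timecourse",
           "multiplex_summary", "moving_windows"]

ALPHA_TEMPLATE = 0.005
STEP_P3_CANDIDATES = (40.0, 50.0, 60.0)
CODING_LABELS = ("linear", "step_perception", "step_choice")


@dataclass
class ResponseProfile:
    """Mean rate per stimulus in a window, for one outcome."""

    stimuli: np.ndarray        # observed stimulus values (sorted)
    rates: np.ndarray          # mean Hz per stimulus
    n_trials: np.ndarray       # contributing trials per point
    outcome: str
    window: tuple[int, int]    # [start, end) bins on the warped axis

    @property
    def complete(self) -> bool:
        return len(self.stimuli) == len(STIMULUS_SET)

    def delta(self) -> float:
        """Mean rate above 50 %Sucrose minus mean below; NaN if a side is empty."""
        hi = self.stimuli > 50
        lo = self.stimuli < 50
        if not hi.any() or not lo.any():
            return float("nan")
        return float(self.rates[hi].mean() - self.rates[lo].mean())


@dataclass
class ShapeFit:
    template: str              # "line" | "step"
    params: tuple
    sse_null: float
    sse_fit: float
    n_points: int
    n_params: int
    fstat: float
    p_value: float
    valid: bool = True


@dataclass
class CodingLabel:
    label: str                 # linear | step_perception | step_choice | step_unresolved | other
    delta_correct: float = float("nan")
    delta_error: float = float("nan")
    line_fit: ShapeFit | None = None
    step_fit: ShapeFit | None = None


def response_profile(tensor_values: np.ndarray, stimuli: np.ndarray,
                     outcomes: np.ndarray, unit: int,
                     window: tuple[int, int], outcome: str = "correct"
                     ) -> ResponseProfile:
    """Window-mean tuning curve of one unit over trials of a given outcome."""
    lo, hi = window
    if hi <= lo:
        raise ValueError("window must contain at least one bin")
    wmean = tensor_values[:, unit, lo:hi].mean(axis=1)
    stim_vals, rates, counts = [], [], []
    for s in STIMULUS_SET:
        mask = (np.asarray(stimuli) == s) & (np.asarray(outcomes) == outcome)
        if mask.any():
            stim_vals.append(s)
            rates.append(float(wmean[mask].mean()))
            counts.append(int(mask.sum()))
    return ResponseProfile(stimuli=np.array(stim_vals), rates=np.array(rates),
                           n_trials=np.array(counts), outcome=outcome,
                           window=window)


def _fstat(sse_null: float, sse_fit: float, nd: int, np_: int
           ) -> tuple[float, float]:
    """Extra-sum-of-squares F vs the mean-only null and its p-value.

    SSE_fit = 0 with SSE_null > 0 is a perfect fit (F = inf, p = 0);
    SSE_null = 0 (constant profile) offers no improvement (F = 0, p = 1).
    """
    df2 = nd - np_
    df_num = np_ - 1
    if df2 < 1:
        return float("nan"), float("nan")
    if sse_null <= 1e-300:
        return 0.0, 1.0
    if sse_fit <= 1e-300:
        return float("inf"), 0.0
    f = (sse_null - sse_fit) / sse_fit * df2 / df_num
    f = max(f, 0.0)
    return f, float(stats.f.sf(f, df_num, df2))


def fit_line(profile: ResponseProfile) -> ShapeFit:
    """Constrained least-squares line fit, f(s) >= 0 at every stimulus point.

    The constrained quadratic program is solved exactly by enumeration: the
    unconstrained OLS solution if feasible, otherwise the best feasible fit
    with one active constraint (the line pinned to zero at one stimulus) or
    the zero line.
    """
    s, r = profile.stimuli.astype(float), profile.rates.astype(float)
    nd = len(s)
    if nd < 3:
        return ShapeFit("line", (np.nan, np.nan), np.nan, np.nan, nd, 2,
                        np.nan, np.nan, valid=False)
    X = np.column_stack([s, np.ones(nd)])
    candidates: list[np.ndarray] = []
    beta, *_ = np.linalg.lstsq(X, r, rcond=None)
    candidates.append(beta)
    for sj in s:
        # active constraint p1*sj + p2 = 0 -> substitute p2 = -p1*sj
        xs = s - sj
        denom = float(xs @ xs)
        p1 = float(xs @ r) / denom if denom > 0 else 0.0
        candidates.append(np.array([p1, -p1 * sj]))
    candidates.append(np.zeros(2))
    best, best_sse = None, np.inf
    for cand in candidates:
        pred = X @ cand
        if np.any(pred < -1e-9):
            continue
        sse = float(np.sum((r - pred) ** 2))
        if sse < best_sse:
            best, best_sse = cand, sse
    sse_null = float(np.sum((r - r.mean()) ** 2))
    f, p = _fstat(sse_null, best_sse, nd, 2)
    return ShapeFit("line", (float(best[0]), float(best[1])), sse_null,
                    best_sse, nd, 2, f, p)


def fit_step(profile: ResponseProfile) -> ShapeFit:
    """Step-template fit over inflection candidates {40, 50, 60}.

    For each candidate p3 the plateau levels are the side means; the SSE-best
    candidate wins.  A candidate with an empty side is skipped.
    """
    s, r = profile.stimuli.astype(float), profile.rates.astype(float)
    nd = len(s)
    best = None
    for p3 in STEP_P3_CANDIDATES:
        lo_mask, hi_mask = s < p3, s >= p3
        if not lo_mask.any() or not hi_mask.any():
            continue
        p1, p2 = float(r[lo_mask].mean()), float(r[hi_mask].mean())
        pred = np.where(lo_mask, p1, p2)
        sse = float(np.sum((r - pred) ** 2))
        if best is None or sse < best[0]:
            best = (sse, p1, p2, p3)
    if best is None:
        return ShapeFit("step", (np.nan,) * 3, np.nan, np.nan, nd, 3,
                        np.nan, np.nan, valid=False)
    sse, p1, p2, p3 = best
    sse_null = float(np.sum((r - r.mean()) ** 2))
    f, p = _fstat(sse_null, sse, nd, 3)
    return ShapeFit("step", (p1, p2, p3), sse_null, sse, nd, 3, f, p)


def classify_profile(r_correct: ResponseProfile,
                     r_error: ResponseProfile | None,
                     alpha: float = ALPHA_TEMPLATE) -> CodingLabel:
    """Assign a coding label from correct- (and, for steps, error-) trial profiles."""
    if not r_correct.complete:
        return CodingLabel(label="other")
    line = fit_line(r_correct)
    step = fit_step(r_correct)
    fits = [f for f in (line, step) if f.valid and not np.isnan(f.fstat)]
    if not fits:
        return CodingLabel(label="other", line_fit=line, step_fit=step)
    winner = max(fits, key=lambda f: f.fstat)
    if not (winner.p_value < alpha):
        return CodingLabel(label="other", line_fit=line, step_fit=step)
    if winner.template == "line":
        return CodingLabel(label="linear", line_fit=line, step_fit=step)

    delta_c = r_correct.delta()
    delta_e = r_error.delta() if r_error is not None else float("nan")
    p3 = winner.params[2]
    if not np.isfinite(delta_e):
        label = "step_unresolved"
    elif p3 == 50.0 and delta_c * delta_e < 0:
        label = "step_choice"
    else:
        label = "step_perception"
    return CodingLabel(label=label, delta_correct=delta_c, delta_error=delta_e,
                       line_fit=line, step_fit=step)


def moving_windows(n_bins: int = 117, width: int = 4) -> list[tuple[int, int]]:
    """Non-overlapping windows of ``width`` bins; the remainder forms the last."""
    windows = [(lo, min(lo + width, n_bins)) for lo in range(0, n_bins, width)]
    return windows


def coding_timecourse(tensor_values: np.ndarray, stimuli: np.ndarray,
                      outcomes: np.ndarray, axis: WarpAxis | None = None,
                      alpha: float = ALPHA_TEMPLATE
                      ) -> dict[str, object]:
    """Coding labels per unit per moving window, plus the two fixed windows.

    Moving windows are 4 bins (~200 ms warped) stepped by 4 over the 117-bin
    axis (the final window is 1 bin).  The fixed windows are the 10 warped
    bins adjacent to T and to D, matching the decoding windows.
    """
    axis = axis or WarpAxis()
    n_units = tensor_values.shape[1]
    windows = moving_windows(axis.total_bins)
    fixed = {
        "sampling": (axis.n_pre, axis.n_pre + 10),
        "delay": (axis.n_pre + axis.n_warp - 10, axis.n_pre + axis.n_warp),
    }
    labels = [[None] * len(windows) for _ in range(n_units)]
    fixed_labels: dict[str, list[CodingLabel]] = {k: [] for k in fixed}
    for u in range(n_units):
        for wi, w in enumerate(windows):
            labels[u][wi] = _classify_window(tensor_values, stimuli, outcomes,
                                             u, w, alpha)
        for name, w in fixed.items():
            fixed_labels[name].append(
                _classify_window(tensor_values, stimuli, outcomes, u, w, alpha))
    return {"windows": windows, "labels": labels, "fixed": fixed_labels,
            "fixed_windows": fixed}


def _classify_window(tensor_values, stimuli, outcomes, unit, window, alpha
                     ) -> CodingLabel:
    rc = response_profile(tensor_values, stimuli, outcomes, unit, window,
                          "correct")
    re = response_profile(tensor_values, stimuli, outcomes, unit, window,
                          "error")
    return classify_profile(rc, re if len(re.stimuli) else None, alpha=alpha)


def multiplex_summary(timecourse: dict, axis: WarpAxis | None = None
                      ) -> dict[str, int]:
    """Counts of units per non-empty subset of coding labels over task windows.

    Only windows overlapping the interval between T and D count; the 7 keys
    are '+'-joined sorted label combinations.
    """
    axis = axis or WarpAxis()
    lo, hi = axis.n_pre, axis.n_pre + axis.n_warp
    counts: dict[str, int] = {}
    for combo_len in (1, 2, 3):
        for combo in itertools.combinations(CODING_LABELS, combo_len):
            counts["+".join(combo)] = 0
    for unit_labels, unit_windows in zip(timecourse["labels"],
                                         [timecourse["windows"]] * len(timecourse["labels"])):
        seen = set()
        for lab, (wlo, whi) in zip(unit_labels, unit_windows):
            if whi <= lo or wlo >= hi:
                continue
            if lab.label in CODING_LABELS:
                seen.add(lab.label)
        if seen:
            counts["+".join(sorted(seen, key=CODING_LABELS.index))] += 1
    return counts
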