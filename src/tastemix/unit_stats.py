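"""Per-unit discrimination time courses and responsivity/selectivity tests.

The discrimination measure is the area under the ROC curve between firing-rate
distributions on predominantly-sucrose (s > 50) and predominantly-NaCl
(s < 50) correct trials, computed bin-by-bin on the warped axis.  The
convention follows the normalized Mann-Whitney U statistic of the NaCl-trial
sample: 0 means sucrose-trial rates are always greater, 1 means NaCl-trial
rates are always greater, 0.5 means the distributions overlap completely.
A unit's preference label comes from the time bin whose auROC deviates most
from 0.5 (earliest bin on ties; a flat 0.5 time course is left unlabeled).

Responsivity compares window-mean rates during sampling ([T, T+0.5 s]) or
delay ([D-0.5 s, D]) against pre-event baselines with two-sided Mann-Whitney
tests at alpha = 0.01; selectivity (sucrose- vs NaCl-side difference within
a period) is tested only among responsive units.  Experimental-format data
use the long baselines [T-3, T-2.5 s] and [D-5.5, D-5 s]; network-simulated
data, which have no long pre-stimulus epoch, use [T-0.5 s, T].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .session import Session
from .warp import WarpedRateTensor

__all__ = ["auroc", "AurocTimecourse", "preference_label",
           "ResponsivityResult", "responsivity_selectivity", "unit_stats_table"]

ALPHA = 0.01


def auroc(sample_a, sample_b) -> float:
    """auROC of ``sample_b`` (NaCl-trial rates) over ``sample_a`` (sucrose).

    Equals the normalized Mann-Whitney U statistic: the fraction of
    (a, b) pairs with b > a, ties counting 1/2.  Returns NaN when either
    sample is empty.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        return float("nan")
    # U statistic of b via rank sums (tie-aware), normalized by n_a * n_b
    u = stats.mannwhitneyu(b, a, alternative="two-sided").statistic
    return float(u) / (a.size * b.size)


@dataclass
class AurocTimecourse:
    values: np.ndarray          # (n_bins,), in [0, 1] or NaN
    peak_bin: int
    preference: str | None      # sucrose_preferring | nacl_preferring | None

    @property
    def peak_value(self) -> float:
        return float(self.values[self.peak_bin])


def preference_label(values: np.ndarray) -> AurocTimecourse:
    """Label a unit from its auROC time course.

    Peak = bin maximizing |auROC - 0.5| (earliest on ties).  The label is
    nacl_preferring iff the peak value exceeds 0.5; a degenerate all-0.5 (or
    all-missing) time course is unlabeled.
    """
    v = np.asarray(values, dtype=float)
    dev = np.abs(v - 0.5)
    if np.all(np.isnan(dev)):
        return AurocTimecourse(values=v, peak_bin=0, preference=None)
    peak = int(np.nanargmax(dev))
    if dev[peak] == 0:
        return AurocTimecourse(values=v, peak_bin=peak, preference=None)
    pref = "nacl_preferring" if v[peak] > 0.5 else "sucrose_preferring"
    return AurocTimecourse(values=v, peak_bin=peak, preference=pref)


def auroc_timecourse(tensor: WarpedRateTensor, stimuli: np.ndarray,
                     outcomes: np.ndarray, unit: int) -> AurocTimecourse:
    """Bin-by-bin auROC between correct s>50 and s<50 trials for one unit."""
    correct = outcomes == "correct"
    suc = correct & (stimuli > 50)
    nac = correct & (stimuli < 50)
    vals = np.full(tensor.values.shape[2], np.nan)
    if suc.any() and nac.any():
        a = tensor.values[suc, unit, :]
        b = tensor.values[nac, unit, :]
        for t in range(vals.size):
            vals[t] = auroc(a[:, t], b[:, t])
    return preference_label(vals)


@dataclass
class ResponsivityResult:
    responsive_sampling: bool
    selective_sampling: bool
    responsive_delay: bool
    selective_delay: bool
    p_responsive_sampling: float
    p_selective_sampling: float
    p_responsive_delay: float
    p_selective_delay: float
    available: bool = True


def _window_means(session: Session, unit: int,
                  window_fn) -> np.ndarray:
    """Per-trial mean rate (Hz) of a unit in a trial-relative window."""
    lookup = session.spike_lookup()
    out = np.zeros(len(session.trials))
    for i, trial in enumerate(session.trials):
        lo, hi = window_fn(trial)
        st = lookup.get((unit, trial.index))
        if st is not None and st.size:
            out[i] = np.sum((st >= lo) & (st < hi)) / (hi - lo)
    return out


def _mw_test(x: np.ndarray, y: np.ndarray) -> float:
    if x.size == 0 or y.size == 0:
        return float("nan")
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return 1.0  # identical constant samples: no evidence of a difference
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def responsivity_selectivity(session: Session, unit: int,
                             mode: str = "experimental",
                             alpha: float = ALPHA) -> ResponsivityResult:
    """Responsivity and (gated) selectivity of one unit, correct trials only.

    ``mode`` chooses the baseline windows: "experimental" uses [T-3, T-2.5]
    (sampling) and [D-5.5, D-5] (delay); "rnn" uses [T-0.5, T] for both.
    """
    trials = session.trials
    correct = np.array([t.outcome == "correct" for t in trials])
    suc = np.array([t.stimulus_s > 50 for t in trials]) & correct
    nac = np.array([t.stimulus_s < 50 for t in trials]) & correct

    sampling = _window_means(session, unit,
                             lambda tr: (tr.t_central, tr.t_central + 0.5))
    delay = _window_means(session, unit,
                          lambda tr: (tr.t_lateral - 0.5, tr.t_lateral))
    if mode == "experimental":
        base_samp = _window_means(session, unit,
                                  lambda tr: (tr.t_central - 3.0, tr.t_central - 2.5))
        base_delay = _window_means(session, unit,
                                   lambda tr: (tr.t_lateral - 5.5, tr.t_lateral - 5.0))
        # delay baseline may precede the available recording on short trials
        available = all(tr.t_lateral - 5.5 >= tr.t_central - 3.5 - 1e-9
                        for tr in trials)
    elif mode == "rnn":
        base_samp = _window_means(session, unit,
                                  lambda tr: (tr.t_central - 0.5, tr.t_central))
        base_delay = base_samp
        available = True
    else:
        raise ValueError(f"unknown mode {mode!r}")

    results = {}
    for period, rates, base in (("sampling", sampling, base_samp),
                                ("delay", delay, base_delay)):
        p_resp = _mw_test(rates[correct], base[correct])
        responsive = bool(np.isfinite(p_resp) and p_resp < alpha)
        p_sel = float("nan")
        selective = False
        if responsive:
            p_sel = _mw_test(rates[suc], rates[nac])
            selective = bool(np.isfinite(p_sel) and p_sel < alpha)
        results[period] = (responsive, selective, p_resp, p_sel)

    (rs, ss, prs, pss) = results["sampling"]
    (rd, sd, prd, psd) = results["delay"]
    return ResponsivityResult(rs, ss, rd, sd, prs, pss, prd, psd,
                              available=available)


def unit_stats_table(session: Session, tensor: WarpedRateTensor,
                     mode: str = "experimental") -> pd.DataFrame:
    """Per-unit summary: peak auROC, preference, responsivity/selectivity."""
    stimuli = np.array([t.stimulus_s for t in session.trials])
    outcomes = np.array([t.outcome for t in session.trials])
    rows = []
    for u in range(session.n_units):
        tc = auroc_timecourse(tensor, stimuli, outcomes, u)
        rr = responsivity_selectivity(session, u, mode=mode)
        rows.append({
            "unit": u,
            "peak_auroc": tc.peak_value if tc.preference else 0.5,
            "peak_bin": tc.peak_bin,
            "preference": tc.preference or "none",
            "responsive_sampling": rr.responsive_sampling,
            "selective_sampling": rr.selective_sampling,
            "responsive_delay": rr.responsive_delay,
            "selective_delay": rr.selective_delay,
        })
    return pd.DataFrame(rows)
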