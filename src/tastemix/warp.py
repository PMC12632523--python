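"""Event-warped firing-rate representation and PSTHs.

Spike trains are re-binned on a warped time axis anchored to the two
behavioral events of each trial: 20 fixed 50 ms bins before the first central
lick T, 77 bins spanning the trial-varying interval between T and the first
lateral lick D (each of duration (D-T)/77, so ~50 ms at the 3.85 s average
interval), and 20 fixed 50 ms bins after D — 117 bins in total.  Rates are
spike count divided by the actual bin duration, so the representation
conserves spike counts: sum(rate * duration) over the middle bins equals the
spike count in [T, D).

Trial-averaged PSTHs are computed per (stimulus, outcome) cell and smoothed
with an acausal Gaussian kernel 11 bins wide (sd 2 bins by default),
renormalized at the edges so constants are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .session import STIMULUS_SET, Session

__all__ = ["WarpAxis", "WarpedRateTensor", "PSTHSet", "warp_trial",
           "smooth_rates", "build_psths"]


@dataclass(frozen=True)
class WarpAxis:
    """The 20 + 77 + 20 = 117-bin warped time axis."""

    n_pre: int = 20
    n_warp: int = 77
    n_post: int = 20
    fixed_bin: float = 0.05

    def __post_init__(self) -> None:
        if self.fixed_bin <= 0:
            raise ValueError("fixed_bin must be > 0")

    @property
    def total_bins(self) -> int:
        return self.n_pre + self.n_warp + self.n_post

    def bin_edges(self, T: float, D: float) -> np.ndarray:
        """118 bin edges (seconds, session clock) for a trial with events T, D."""
        if not D > T:
            raise ValueError("D must be > T")
        pre = T - self.fixed_bin * np.arange(self.n_pre, 0, -1)
        mid = T + (D - T) / self.n_warp * np.arange(self.n_warp)
        post = D + self.fixed_bin * np.arange(self.n_post + 1)
        return np.concatenate([pre, mid, post])

    def bin_durations(self, T: float, D: float) -> np.ndarray:
        return np.diff(self.bin_edges(T, D))

    def middle_slice(self) -> slice:
        return slice(self.n_pre, self.n_pre + self.n_warp)


@dataclass
class WarpedRateTensor:
    """Firing rates (Hz) indexed (trial, unit, bin) on the warped axis."""

    values: np.ndarray
    axis: WarpAxis
    smoothed: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 3 or v.shape[2] != self.axis.total_bins:
            raise ValueError("values must be (trial, unit, bin) with "
                             f"{self.axis.total_bins} bins")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("rates must be finite and >= 0")
        self.values = v


@dataclass
class PSTHSet:
    """Trial-averaged rates per (stimulus, unit, bin), split by outcome.

    Cells with no contributing trials are NaN (missing), never 0.
    """

    correct: np.ndarray            # (n_stim, n_units, n_bins); NaN where missing
    error: np.ndarray
    n_correct: np.ndarray          # (n_stim,) trial counts
    n_error: np.ndarray
    stimuli: tuple[float, ...] = STIMULUS_SET
    axis: WarpAxis = field(default_factory=WarpAxis)

    def missing_correct(self) -> np.ndarray:
        return self.n_correct == 0


def warp_trial(spike_times: np.ndarray, T: float, D: float,
               axis: WarpAxis | None = None) -> np.ndarray:
    """Warped rate vector (Hz, one value per bin) for one unit on one trial.

    Bins are half-open [left, right); a spike exactly at T enters the first
    middle bin.  Spikes outside [T - n_pre*50ms, D + n_post*50ms) are ignored.
    """
    axis = axis or WarpAxis()
    edges = axis.bin_edges(T, D)
    t = np.asarray(spike_times, dtype=float)
    counts, _ = np.histogram(t, bins=edges)
    # np.histogram closes the last bin on the right; drop spikes exactly at the end
    if t.size and np.any(t == edges[-1]):
        counts[-1] -= int(np.sum(t == edges[-1]))
    return counts / axis.bin_durations(T, D)


def gaussian_kernel(halfwidth: int = 5, sd: float = 2.0) -> np.ndarray:
    x = np.arange(-halfwidth, halfwidth + 1, dtype=float)
    k = np.exp(-0.5 * (x / sd) ** 2)
    return k / k.sum()


def smooth_rates(rates: np.ndarray, kernel_halfwidth_bins: int = 5,
                 sd_bins: float = 2.0) -> np.ndarray:
    """Acausal Gaussian smoothing along the last axis, edge-renormalized.

    The kernel is renormalized at the edges (dividing by the sum of in-range
    kernel mass) so a constant input is returned exactly.  ``sd_bins <= 0``
    returns the input unchanged.
    """
    rates = np.asarray(rates, dtype=float)
    if sd_bins <= 0:
        import logging
        logging.getLogger(__name__).warning("sd_bins <= 0; smoothing skipped")
        return rates.copy()
    k = gaussian_kernel(kernel_halfwidth_bins, sd_bins)
    n = rates.shape[-1]
    flat = rates.reshape(-1, n)
    out = np.empty_like(flat)
    norm = np.convolve(np.ones(n), k, mode="same")
    for i in range(flat.shape[0]):
        out[i] = np.convolve(flat[i], k, mode="same") / norm
    return out.reshape(rates.shape)


def build_psths(session: Session, axis: WarpAxis | None = None,
                smooth: bool = True, sd_bins: float = 2.0,
                smooth_single_trials: bool = True
                ) -> tuple[WarpedRateTensor, PSTHSet]:
    """Per-trial warped rate tensor and (stimulus x outcome) PSTHs.

    PSTHs are smoothed after trial averaging; the single-trial tensor is
    smoothed per trial when ``smooth_single_trials`` (both smoothed and raw
    variants are one flag away, since downstream choices differ).
    """
    axis = axis or WarpAxis()
    trials = session.trials
    lookup = session.spike_lookup()
    n_bins = axis.total_bins
    raw = np.zeros((len(trials), session.n_units, n_bins))
    for ti, trial in enumerate(trials):
        for u in range(session.n_units):
            st = lookup.get((u, trial.index))
            if st is not None and st.size:
                raw[ti, u] = warp_trial(st, trial.t_central, trial.t_lateral, axis)

    stimuli = STIMULUS_SET
    n_stim = len(stimuli)
    correct = np.full((n_stim, session.n_units, n_bins), np.nan)
    error = np.full_like(correct, np.nan)
    n_correct = np.zeros(n_stim, dtype=int)
    n_error = np.zeros(n_stim, dtype=int)
    stim_arr = np.array([t.stimulus_s for t in trials])
    out_arr = np.array([t.outcome for t in trials])
    for si, s in enumerate(stimuli):
        for which, store, counts in (("correct", correct, n_correct),
                                     ("error", error, n_error)):
            mask = (stim_arr == s) & (out_arr == which)
            counts[si] = int(mask.sum())
            if counts[si]:
                store[si] = raw[mask].mean(axis=0)
    if smooth:
        for arr in (correct, error):
            ok = ~np.isnan(arr[:, 0, 0])
            if ok.any():
                arr[ok] = smooth_rates(arr[ok], sd_bins=sd_bins)

    tensor_values = smooth_rates(raw, sd_bins=sd_bins) if smooth_single_trials else raw
    tensor = WarpedRateTensor(values=tensor_values, axis=axis,
                              smoothed=smooth_single_trials)
    psths = PSTHSet(correct=correct, error=error, n_correct=n_correct,
                    n_error=n_error, stimuli=stimuli, axis=axis)
    return tensor, psths


def warp_tensor(session: Session, axis: WarpAxis | None = None,
                smooth: bool = False, sd_bins: float = 2.0) -> WarpedRateTensor:
    """Just the per-trial tensor (raw by default), without PSTH averaging."""
    tensor, _ = build_psths(session, axis=axis, smooth=False,
                            smooth_single_trials=smooth, sd_bins=sd_bins)
    return tensor
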