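"""Class-balanced leave-one-out nearest-centroid decoding.

At each time bin, every trial is a population firing-rate vector with a label
(the mixture stimulus, 8 classes, or the choice, 2 classes).  Each trial is
held out in turn, class centroids are recomputed without it, and the trial is
assigned the label of the nearest centroid (Euclidean distance; ties broken
toward the smallest label).  Accuracy is class-balanced: the mean over labels
of the per-label hit rate, so chance is 1/|U| regardless of class imbalance.

The significance threshold on session-averaged accuracy is the binomial k/N
with k the smallest hit count whose upper-tail probability under
Binomial(N, chance) is below alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .warp import WarpAxis

__all__ = ["LabeledActivity", "DecodingResult", "min_distance_loo",
           "binomial_threshold", "decode_timecourse"]


@dataclass
class LabeledActivity:
    """Per-trial population vectors with labels; singleton labels dropped."""

    vectors: np.ndarray                 # (n_trials, n_units)
    labels: np.ndarray                  # (n_trials,)
    dropped_labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        lab = np.asarray(self.labels)
        uniq, counts = np.unique(lab, return_counts=True)
        singles = uniq[counts < 2]
        if singles.size:
            # a label with one trial has no centroid once held out
            self.dropped_labels = list(singles)
            keep = ~np.isin(lab, singles)
            v, lab = v[keep], lab[keep]
        self.vectors, self.labels = v, lab

    @property
    def label_set(self) -> np.ndarray:
        return np.unique(self.labels)


def min_distance_loo(activity: LabeledActivity) -> float:
    """Class-balanced leave-one-out accuracy of the nearest-centroid decoder."""
    v, lab = activity.vectors, activity.labels
    uniq = activity.label_set
    if uniq.size < 2:
        raise ValueError("need at least 2 labels with >= 2 trials each")
    n, d = v.shape
    sums = np.stack([v[lab == u].sum(axis=0) for u in uniq])        # (U, d)
    counts = np.array([(lab == u).sum() for u in uniq], dtype=float)
    label_idx = np.searchsorted(uniq, lab) if uniq.dtype.kind in "if" else \
        np.array([list(uniq).index(l) for l in lab])

    hits = np.zeros(uniq.size)
    for i in range(n):
        li = label_idx[i]
        cents = sums / counts[:, None]
        # remove the held-out trial from its own class centroid
        cents[li] = (sums[li] - v[i]) / (counts[li] - 1)
        dists = np.linalg.norm(cents - v[i], axis=1)
        pred = int(np.argmin(dists))    # argmin returns first (smallest label) on ties
        if pred == li:
            hits[li] += 1
    per_label = hits / counts
    return float(per_label.mean())


def binomial_threshold(alpha: float, N: int, p: float) -> float:
    """One-tailed significance threshold k/N on decoding accuracy.

    k is the minimum hit count x such that P(X >= x) < alpha for
    X ~ Binomial(N, p).  Raises when no x <= N satisfies the condition.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if N < 1:
        raise ValueError("N must be >= 1")
    x = np.arange(N + 1)
    upper_tail = stats.binom.sf(x - 1, N, p)    # P(X >= x)
    ok = np.nonzero(upper_tail < alpha)[0]
    if ok.size == 0:
        raise ValueError("threshold unattainable: no k <= N with tail < alpha")
    return float(ok[0]) / N


@dataclass
class DecodingResult:
    accuracy: np.ndarray        # (n_bins,)
    chance: float
    threshold: float
    labeling: str

    @property
    def peak_accuracy(self) -> float:
        return float(np.nanmax(self.accuracy))

    @property
    def peak_bin(self) -> int:
        return int(np.nanargmax(self.accuracy))

    def window_mean(self, bins: slice | np.ndarray) -> float:
        return float(np.nanmean(self.accuracy[bins]))


def decode_timecourse(tensor_values: np.ndarray, labels: np.ndarray,
                      labeling: str = "stimulus", alpha: float = 0.01,
                      chance: float | None = None) -> DecodingResult:
    """Leave-one-out decoding accuracy per warped time bin.

    ``tensor_values`` is (trial, unit, bin).  ``chance`` defaults to
    1/(number of labels); the threshold uses the session's trial count.
    """
    labels = np.asarray(labels)
    act0 = LabeledActivity(tensor_values[:, :, 0], labels)
    n_classes = act0.label_set.size
    chance = chance if chance is not None else 1.0 / n_classes
    n_bins = tensor_values.shape[2]
    acc = np.full(n_bins, np.nan)
    for t in range(n_bins):
        acc[t] = min_distance_loo(LabeledActivity(tensor_values[:, :, t], labels))
    threshold = binomial_threshold(alpha, tensor_values.shape[0], chance)
    return DecodingResult(accuracy=acc, chance=chance, threshold=threshold,
                          labeling=labeling)


def sampling_delay_means(result: DecodingResult, axis: WarpAxis | None = None,
                         subtract_chance: bool = True) -> tuple[float, float]:
    """Accuracy averaged over the first 10 bins after T and last 10 before D."""
    axis = axis or WarpAxis()
    samp = slice(axis.n_pre, axis.n_pre + 10)
    delay = slice(axis.n_pre + axis.n_warp - 10, axis.n_pre + axis.n_warp)
    offset = result.chance if subtract_chance else 0.0
    return (result.window_mean(samp) - offset, result.window_mean(delay) - offset)
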