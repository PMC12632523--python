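"""Population geometry: pairwise-distance structure and demixed PCA.

Trial-averaged firing rates are organized as X̃ with axes
(neuron, stimulus S=8, choice Q=2, time T=117) and decomposed into additive
marginalizations

    time          X_t                     (condition-independent dynamics)
    stimulus      X_st - X_t              (stimulus + stimulus-time)
    choice        X_qt - X_t              (choice + choice-time)
    interaction   X - X_st - X_qt + X_t   (stimulus-choice + s-c-time)

where X_t, X_st, X_qt are condition averages of the per-neuron-centered data;
the four pieces sum back to the centered X̃ exactly.  For each marginalization
phi a rank-q linear map F_phi D_phi is found by minimizing

    || X_phi - F D X ||^2 + S*Q*T * || F D C^{1/2} ||^2 + mu * || F D ||^2,

a ridge/noise-regularized reduced-rank regression, solved in closed form:
the full-rank ridge solution B = X_phi X^T (X X^T + SQT*C + mu I)^{-1} is
rank-truncated by projecting onto the leading left singular vectors of its
fitted values.  At mu = 0, C = 0 this reduces to plain reduced-rank least
squares.  The "principal axis" of a marginalization is the decoder row whose
projection of X̃ has maximal variance, sign-oriented so that stimulus
projections correlate positively with %Sucrose and sucrose-side choice
projects positive.

Sessions missing a (stimulus, choice) condition are completed by per-bin
linear regression of rate on stim, choice and their interaction; conditions
with a single trial are duplicated before trial splitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .session import STIMULUS_SET
from .warp import PSTHSet

logger = logging.getLogger(__name__)

__all__ = ["ConditionTensor", "DPCAResult", "pairwise_distances",
           "impute_missing", "fit_dpca", "select_regularization", "project",
           "overlap", "condition_tensor"]

MARGINALIZATIONS = ("time", "stimulus", "choice", "interaction")


@dataclass
class ConditionTensor:
    """Trial-resolved and trial-averaged condition data for dPCA.

    ``trials[s][q]`` is a (n_trials_sq, n_units, n_bins) array (possibly
    empty); ``mean`` is (n_units, S, Q, T) with NaN for missing conditions.
    """

    trials: list[list[np.ndarray]]
    mean: np.ndarray
    stimuli: tuple[float, ...] = STIMULUS_SET

    @property
    def n_units(self) -> int:
        return self.mean.shape[0]

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.mean[0, :, :, 0]) if self.n_units else np.zeros((8, 2), bool)

    def matrix(self) -> np.ndarray:
        """X̃ flattened to (n_units, S*Q*T)."""
        return self.mean.reshape(self.n_units, -1)


def condition_tensor(tensor_values: np.ndarray, stimuli: np.ndarray,
                     choices: np.ndarray,
                     stimulus_set: tuple[float, ...] = STIMULUS_SET
                     ) -> ConditionTensor:
    """Group a (trial, unit, bin) tensor by (stimulus, choice) condition.

    Single-trial conditions are duplicated so that split-half procedures stay
    defined.  Choice 0 is nacl_side, choice 1 is sucrose_side.
    """
    choices = np.asarray(choices)
    stimuli = np.asarray(stimuli, dtype=float)
    n_units, n_bins = tensor_values.shape[1], tensor_values.shape[2]
    trials: list[list[np.ndarray]] = []
    mean = np.full((n_units, len(stimulus_set), 2, n_bins), np.nan)
    for si, s in enumerate(stimulus_set):
        row = []
        for qi, side in enumerate(("nacl_side", "sucrose_side")):
            mask = (stimuli == s) & (choices == side)
            block = tensor_values[mask]
            if block.shape[0] == 1:
                block = np.concatenate([block, block], axis=0)
            row.append(block)
            if block.shape[0]:
                mean[:, si, qi, :] = block.mean(axis=0).reshape(n_units, n_bins)
        trials.append(row)
    return ConditionTensor(trials=trials, mean=mean,
                           stimuli=tuple(stimulus_set))


def pairwise_distances(psths: PSTHSet) -> np.ndarray:
    """Euclidean distances in neuron space between all (stimulus, time) pairs.

    Returns an (S*T, S*T) symmetric matrix over correct-trial PSTH points,
    with NaN rows/columns for stimuli whose PSTH cell is missing.
    """
    n_stim, n_units, n_bins = psths.correct.shape
    pts = np.transpose(psths.correct, (0, 2, 1)).reshape(n_stim * n_bins, n_units)
    diff = pts[:, None, :] - pts[None, :, :]
    return np.sqrt(np.sum(diff ** 2, axis=2))


def impute_missing(tensor: ConditionTensor) -> ConditionTensor:
    """Fill missing (stimulus, choice) condition means by per-bin regression.

    Per neuron and time bin, observed condition means are regressed on
    stim (%Sucrose), choice (0/1) and stim*choice; missing cells take the
    predicted values.  Observed cells are untouched.  An unfittable bin
    (< 4 observed cells) falls back to the mean over observed conditions.
    """
    missing = tensor.missing
    if not missing.any():
        return tensor
    mean = tensor.mean.copy()
    n_units, S, Q, T = mean.shape
    stim = np.repeat(np.asarray(tensor.stimuli, float), Q)
    choice = np.tile(np.arange(Q, dtype=float), S)
    design = np.column_stack([np.ones(S * Q), stim, choice, stim * choice])
    obs = ~missing.reshape(-1)
    flat = mean.reshape(n_units, S * Q, T)
    if obs.sum() >= 4:
        X = design[obs]
        # one least-squares solve per (neuron, bin), batched over columns
        Y = flat[:, obs, :].reshape(n_units, obs.sum(), T)
        for u in range(n_units):
            beta, *_ = np.linalg.lstsq(X, Y[u], rcond=None)
            pred = design[~obs] @ beta
            flat[u, ~obs, :] = pred
    else:
        logger.warning("impute_missing: <4 observed conditions; using marginal mean")
        fallback = np.nanmean(flat, axis=1, keepdims=True)
        flat[:, ~obs, :] = np.broadcast_to(fallback, flat.shape)[:, ~obs, :]
    return ConditionTensor(trials=tensor.trials,
                           mean=flat.reshape(n_units, S, Q, T),
                           stimuli=tensor.stimuli)


def marginalize(mean: np.ndarray) -> dict[str, np.ndarray]:
    """Additive marginalizations of the per-neuron-centered condition means."""
    center = mean - mean.mean(axis=(1, 2, 3), keepdims=True)
    x_t = center.mean(axis=(1, 2), keepdims=True)
    x_st = center.mean(axis=2, keepdims=True)
    x_qt = center.mean(axis=1, keepdims=True)
    parts = {
        "time": np.broadcast_to(x_t, center.shape).copy(),
        "stimulus": np.broadcast_to(x_st - x_t, center.shape).copy(),
        "choice": np.broadcast_to(x_qt - x_t, center.shape).copy(),
        "interaction": center - x_st - x_qt + x_t,
    }
    return parts


@dataclass
class DPCAResult:
    encoders: dict[str, np.ndarray]     # F_phi: (n_units, q)
    decoders: dict[str, np.ndarray]     # D_phi: (q, n_units)
    marginalized: dict[str, np.ndarray]  # X̃_phi as (n_units, S, Q, T)
    mu: float
    n_components: int
    neuron_means: np.ndarray            # per-neuron grand mean removed before fitting
    principal_axes: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def stimulus_axis(self) -> np.ndarray:
        return self.principal_axes["stimulus"]

    @property
    def choice_axis(self) -> np.ndarray:
        return self.principal_axes["choice"]


def _noise_covariance(tensor: ConditionTensor, parts: dict[str, np.ndarray],
                      source: str) -> np.ndarray:
    n_units = tensor.n_units
    S, Q, T = tensor.mean.shape[1:]
    if source == "marginalization":
        # average of X_phi X_phi^T over the marginalizations, / SQT
        C = np.zeros((n_units, n_units))
        for m in parts.values():
            flat = m.reshape(n_units, -1)
            C += flat @ flat.T
        return C / (len(parts) * S * Q * T)
    if source == "residual":
        # average single-trial covariance around condition means
        C = np.zeros((n_units, n_units))
        count = 0
        for row in tensor.trials:
            for block in row:
                if block.shape[0] >= 2:
                    resid = block - block.mean(axis=0, keepdims=True)
                    flat = np.transpose(resid, (1, 0, 2)).reshape(n_units, -1)
                    C += flat @ flat.T / (block.shape[0] - 1)
                    count += 1
        return C / max(count, 1) / T
    raise ValueError(f"unknown noise source {source!r}")


def fit_dpca(tensor: ConditionTensor, mu: float = 0.0, n_components: int = 3,
             noise: str | None = "marginalization") -> DPCAResult:
    """Demixed PCA of a complete (imputed) condition tensor.

    ``noise=None`` drops the noise-covariance term entirely (C = 0), which
    with ``mu=0`` makes the fit exact reduced-rank least squares.
    """
    if tensor.missing.any():
        tensor = impute_missing(tensor)
    n_units = tensor.n_units
    S, Q, T = tensor.mean.shape[1:]
    neuron_means = tensor.mean.mean(axis=(1, 2, 3))
    parts = marginalize(tensor.mean)
    X = (tensor.mean - neuron_means[:, None, None, None]).reshape(n_units, -1)

    C = (np.zeros((n_units, n_units)) if noise is None
         else _noise_covariance(tensor, parts, noise))
    reg = S * Q * T * C + mu * np.eye(n_units)

    gram = X @ X.T + reg
    encoders, decoders, principal = {}, {}, {}
    for name, m in parts.items():
        Y = m.reshape(n_units, -1)
        B = Y @ X.T @ np.linalg.pinv(gram)
        # rank truncation: leading left singular vectors of the fitted values
        # of the augmented problem [X, reg^{1/2}] — equivalently of B applied
        # to the augmented design
        if np.any(reg):
            w, V = np.linalg.eigh((reg + reg.T) / 2)
            M = V @ np.diag(np.sqrt(np.clip(w, 0, None))) @ V.T
            fitted = np.hstack([B @ X, B @ M])
        else:
            fitted = B @ X
        U, _, _ = np.linalg.svd(fitted, full_matrices=False)
        Uq = U[:, :n_components]
        F = Uq
        D = Uq.T @ B
        encoders[name], decoders[name] = F, D
        proj = D @ X
        principal[name] = D[int(np.argmax(proj.var(axis=1)))].copy()

    _orient_axes(principal, X, S, Q, T, tensor.stimuli)
    return DPCAResult(encoders=encoders, decoders=decoders,
                      marginalized=parts, mu=mu, n_components=n_components,
                      neuron_means=neuron_means, principal_axes=principal)


def _orient_axes(principal: dict[str, np.ndarray], X: np.ndarray,
                 S: int, Q: int, T: int, stimuli) -> None:
    """Fix axis signs: stimulus projection increases with %Sucrose; the
    sucrose-side choice projects positive."""
    cond = X.reshape(X.shape[0], S, Q, T)
    if "stimulus" in principal:
        proj = np.einsum("n,nsqt->sqt", principal["stimulus"], cond)
        per_stim = np.nanmean(proj, axis=(1, 2))
        if np.corrcoef(np.asarray(stimuli, float), per_stim)[0, 1] < 0:
            principal["stimulus"] *= -1
    if "choice" in principal:
        proj = np.einsum("n,nsqt->sqt", principal["choice"], cond)
        if np.nanmean(proj[:, 1]) < np.nanmean(proj[:, 0]):
            principal["choice"] *= -1


def select_regularization(tensor: ConditionTensor,
                          grid: np.ndarray | None = None,
                          seed: int = 0, noise: str | None = "marginalization",
                          n_components: int = 3) -> float:
    """Choose mu by split-half cross-validation over trials.

    Trials in each condition are split in half (deterministically given
    ``seed``); dPCA is fitted on one half's condition means and scored by the
    reconstruction error of the other half's means, summed over
    marginalizations.  Falls back to mu = 0 when conditions are too thin.
    """
    if grid is None:
        scale = float(np.mean(tensor.mean[~np.isnan(tensor.mean)] ** 2)) + 1e-12
        grid = np.concatenate([[0.0], scale * np.logspace(-4, 2, 7)])
    rng = np.random.default_rng(seed)
    n_units = tensor.n_units
    S, Q, T = tensor.mean.shape[1:]
    halves = [np.full((n_units, S, Q, T), np.nan) for _ in range(2)]
    ok = True
    for si, row in enumerate(tensor.trials):
        for qi, block in enumerate(row):
            if block.shape[0] < 2:
                ok = False
                continue
            perm = rng.permutation(block.shape[0])
            mid = block.shape[0] // 2
            halves[0][:, si, qi, :] = block[perm[:mid]].mean(0)
            halves[1][:, si, qi, :] = block[perm[mid:]].mean(0)
    if not ok or any(np.isnan(h).any() for h in halves):
        logger.warning("select_regularization: insufficient trials; mu = 0")
        return 0.0
    train = ConditionTensor(trials=tensor.trials, mean=halves[0],
                            stimuli=tensor.stimuli)
    test_parts = marginalize(halves[1])
    Xtest = (halves[1] - halves[1].mean(axis=(1, 2, 3), keepdims=True)
             ).reshape(n_units, -1)
    errs = []
    for mu in grid:
        res = fit_dpca(train, mu=float(mu), noise=noise,
                       n_components=n_components)
        err = 0.0
        for name in MARGINALIZATIONS:
            F, D = res.encoders[name], res.decoders[name]
            pred = F @ (D @ Xtest)
            err += float(np.sum((test_parts[name].reshape(n_units, -1) - pred) ** 2))
        errs.append(err)
    return float(grid[int(np.argmin(errs))])


def project(activity: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Inner product of an axis with activity along the neuron dimension.

    ``activity`` may be (n_units, ...) — any trailing shape; returns the
    projection with the neuron dimension contracted.
    """
    activity = np.asarray(activity, dtype=float)
    axis = np.asarray(axis, dtype=float)
    if activity.shape[0] != axis.shape[0]:
        raise ValueError("activity and axis disagree on the neuron dimension")
    return np.tensordot(axis, activity, axes=(0, 0))


def overlap(u: np.ndarray, v: np.ndarray) -> float:
    """Absolute cosine similarity |u.v| / (|u||v|) between two axes."""
    u = np.asarray(u, float).ravel()
    v = np.asarray(v, float).ravel()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("overlap undefined for zero vectors")
    return float(abs(u @ v) / (nu * nv))
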