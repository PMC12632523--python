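"""Data-constrained recurrent rate network with NumPy backprop-through-time.

The network has N = Nc + Nu units (Nc "constrained" units matched to recorded
neurons, Nu = round(5.88 * Nc) unconstrained ones).  Internal activity h
follows the leaky rate equation

    tau dh/dt = -h + m(x) + Wrec f(h + b) + eta,

integrated by forward Euler with step alpha = dt/tau = 0.2.  The transfer
function f(z) = min(max(z, 0), 80) caps rates at 80 Hz; r = f(h + b) are the
firing rates.  The stimulus is the mixture as a 2-vector x = [%Suc, %NaCl]/100
passed through m(x) = A2 tanh(A1 x); x = 0 when the stimulus is off.
A decision unit z, external to the recurrence, integrates tau dz/dt = -z +
wz.r, and the choice is the sign of c = tanh(z) averaged over the decision
window.

Training minimizes L = 150 * L_beh + L_neu, where L_beh pins c near 0 before
the stimulus and near the signed target gamma in the decision window, and
L_neu is the mean squared error between the constrained units' rates and the
correct-trial PSTHs of the session (resampled onto the model clock).
Gradients are computed by hand-derived backpropagation through time and
applied with Adam (lr 0.01) under global-norm gradient clipping at 1.0; the
recurrent matrix diagonal is masked to zero after every update
(self-connections prohibited).  Training runs one presentation of each of
the 8 stimuli per iteration (internal noise active, no input noise) for up
to 2000 iterations or until L < 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .session import STIMULUS_SET
from .warp import WarpAxis

logger = logging.getLogger(__name__)

__all__ = ["RNNParams", "DynamicsConfig", "TrainConfig", "transfer",
           "stimulus_embed", "simulate_batch", "simulate_trial", "loss_terms",
           "train", "psth_targets", "init_params"]

RATE_CAP = 80.0
UNCONSTRAINED_RATIO = 5.88


def n_unconstrained(nc: int) -> int:
    return int(round(UNCONSTRAINED_RATIO * nc))


@dataclass
class DynamicsConfig:
    """Integration and trial-protocol constants.

    Only alpha = dt/tau is printed by the model definition; dt = 50 ms and
    tau = 250 ms realize it on a grid where the 5.9 s trial is 118 steps,
    stimulus onset T falls at step 20 (1.0 s) and the decision time D at
    step 98 (4.9 s), 3.9 s after stimulus onset.
    """

    alpha: float = 0.2
    dt: float = 0.05
    tau: float = 0.25
    rate_cap: float = RATE_CAP
    sigma_eta: float = 0.25          # 0.05 / alpha, per the printed formula
    trial_length: float = 5.9
    stim_onset: float = 1.0
    stim_duration: float = 1.2
    decision_time: float = 4.9
    decision_window: float = 0.1

    @property
    def n_steps(self) -> int:
        return int(round(self.trial_length / self.dt))

    @property
    def stim_steps(self) -> np.ndarray:
        """Step indices (1-based states) during which the stimulus is on."""
        t = self.dt * np.arange(1, self.n_steps + 1)
        on = (t > self.stim_onset) & (t <= self.stim_onset + self.stim_duration)
        return np.nonzero(on)[0]

    @property
    def decision_steps(self) -> np.ndarray:
        t = self.dt * np.arange(1, self.n_steps + 1)
        on = (t > self.decision_time - self.decision_window) & \
            (t <= self.decision_time + 1e-9)
        return np.nonzero(on)[0]

    @property
    def prestim_steps(self) -> np.ndarray:
        """win0 = [T - 1 s, T]: all steps up to stimulus onset."""
        t = self.dt * np.arange(1, self.n_steps + 1)
        return np.nonzero(t <= self.stim_onset + 1e-9)[0]


@dataclass
class RNNParams:
    """All trainable parameters.  Wrec's diagonal is identically zero."""

    A1: np.ndarray          # (H, 2)
    A2: np.ndarray          # (N, H)
    Wrec: np.ndarray        # (N, N), zero diagonal
    b: np.ndarray           # (N,)
    wz: np.ndarray          # (N,)
    h0: np.ndarray          # (N,)
    n_constrained: int

    @property
    def n_units(self) -> int:
        return self.Wrec.shape[0]

    @property
    def n_unconstrained(self) -> int:
        return self.n_units - self.n_constrained

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"A1": self.A1, "A2": self.A2, "Wrec": self.Wrec,
                "b": self.b, "wz": self.wz, "h0": self.h0}


@dataclass
class TrainConfig:
    lambda_beh: float = 150.0
    lambda_neu: float = 1.0
    lr: float = 0.01
    grad_clip: float = 1.0
    max_iters: int = 2000
    loss_stop: float = 1.0
    embed_width: int = 100
    internal_noise: bool = True
    seed: int = 0


def init_params(nc: int, embed_width: int = 100,
                rng: np.random.Generator | None = None) -> RNNParams:
    """Random initialization: A ~ N(0,1), Wrec ~ N(0, 0.1/N) zero-diagonal,
    wz ~ N(0, 1/N), b = h0 = 0."""
    rng = rng or np.random.default_rng(0)
    nu = n_unconstrained(nc)
    n = nc + nu
    A1 = rng.normal(0.0, 1.0, (embed_width, 2))
    A2 = rng.normal(0.0, 1.0, (n, embed_width))
    Wrec = rng.normal(0.0, np.sqrt(0.1 / n), (n, n))
    np.fill_diagonal(Wrec, 0.0)
    wz = rng.normal(0.0, np.sqrt(1.0 / n), n)
    return RNNParams(A1=A1, A2=A2, Wrec=Wrec, b=np.zeros(n), wz=wz,
                     h0=np.zeros(n), n_constrained=nc)


def transfer(z: np.ndarray, cap: float = RATE_CAP) -> np.ndarray:
    """Rectified-linear transfer with saturation: f(z) = min(max(z, 0), cap)."""
    return np.clip(z, 0.0, cap)


def stimulus_vector(stimulus_s: float) -> np.ndarray:
    """Mixture as [%Sucrose, %NaCl] / 100, e.g. 25/75 -> [0.25, 0.75]."""
    return np.array([stimulus_s / 100.0, 1.0 - stimulus_s / 100.0])


def stimulus_embed(x: np.ndarray, A1: np.ndarray, A2: np.ndarray) -> np.ndarray:
    """m(x) = A2 tanh(A1 x); x may be (2,) or (batch, 2)."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != A1.shape[1]:
        raise ValueError("stimulus dimension mismatch")
    return np.tanh(x @ A1.T) @ A2.T


def gamma_target(stimulus_s: float) -> float:
    """Signed choice target: +1 for predominantly sucrose, -1 for NaCl."""
    return 1.0 if stimulus_s > 50 else -1.0


def simulate_batch(params: RNNParams, config: DynamicsConfig,
                   stimuli: np.ndarray, rng: np.random.Generator,
                   input_noise_sigma: float = 0.0,
                   internal_noise: bool = True,
                   clamp_units: np.ndarray | None = None,
                   record: bool = False) -> dict:
    """Simulate a batch of trials (one row per stimulus value).

    Returns rates (K, steps+1, N), choice activity c (K, steps+1), choices,
    and (when ``record``) the internals needed for backprop.  Input noise
    perturbs x at every step, stimulus on or off.  ``clamp_units`` zeroes
    those units' rates before both the recurrent input and the readout
    (virtual ablation).
    """
    K = len(stimuli)
    N = params.n_units
    steps = config.n_steps
    a = config.alpha
    X = np.stack([stimulus_vector(s) for s in stimuli])       # (K, 2)
    on = np.zeros(steps + 1, dtype=bool)
    on[config.stim_steps + 1] = True        # state index t corresponds to step t

    h = np.tile(params.h0, (K, 1))
    z = np.zeros(K)
    rates = np.empty((K, steps + 1, N))
    cs = np.empty((K, steps + 1))
    clamp_mask = np.ones(N)
    if clamp_units is not None and len(clamp_units):
        clamp_units = np.asarray(clamp_units, int)
        if clamp_units.min() < 0 or clamp_units.max() >= N:
            raise ValueError("clamp unit id out of range")
        clamp_mask[clamp_units] = 0.0

    rec = {"h": np.empty((K, steps + 1, N)), "z": np.empty((K, steps + 1)),
           "x_eff": np.empty((K, steps, 2)), "eta_on": on} if record else None

    r = transfer(h + params.b) * clamp_mask
    rates[:, 0] = r
    cs[:, 0] = np.tanh(z)
    if record:
        rec["h"][:, 0] = h
        rec["z"][:, 0] = z

    for t in range(1, steps + 1):
        x_eff = X * float(on[t])
        if input_noise_sigma > 0:
            x_eff = x_eff + rng.normal(0.0, input_noise_sigma, (K, 2))
        m = stimulus_embed(x_eff, params.A1, params.A2)
        eta = rng.normal(0.0, config.sigma_eta, (K, N)) if internal_noise \
            else 0.0
        h = h + a * (-h + m + r @ params.Wrec.T + eta)
        z = z + a * (-z + r @ params.wz)
        r = transfer(h + params.b) * clamp_mask
        rates[:, t] = r
        cs[:, t] = np.tanh(z)
        if record:
            rec["h"][:, t] = h
            rec["z"][:, t] = z
            rec["x_eff"][:, t - 1] = x_eff
    if not np.all(np.isfinite(h)):
        raise FloatingPointError("network state diverged (non-finite h)")

    dwin = config.decision_steps + 1
    mean_c = cs[:, dwin].mean(axis=1)
    choices = np.where(mean_c > 0, "sucrose_side", "nacl_side")
    if np.any(mean_c == 0):
        logger.warning("mean decision activity exactly 0; nacl_side by convention")
    return {"rates": rates, "c": cs, "choices": choices, "mean_c": mean_c,
            "record": rec, "clamp_mask": clamp_mask}


def simulate_trial(params: RNNParams, config: DynamicsConfig, stimulus_s: float,
                   input_noise_sigma: float = 0.0, seed: int = 0,
                   internal_noise: bool = True) -> dict:
    """Single-trial convenience wrapper around :func:`simulate_batch`."""
    rng = np.random.default_rng(seed)
    out = simulate_batch(params, config, np.array([stimulus_s]), rng,
                         input_noise_sigma=input_noise_sigma,
                         internal_noise=internal_noise)
    return {"rates": out["rates"][0], "c": out["c"][0],
            "choice": str(out["choices"][0]), "mean_c": float(out["mean_c"][0])}


def psth_targets(psths, config: DynamicsConfig, nc: int,
                 assumed_iei: float = 3.9) -> np.ndarray:
    """Correct-trial PSTHs resampled onto the model clock.

    The 117 warped bins are placed at their physical times for a trial with
    the average 3.9 s sampling-to-decision interval starting 1 s into the
    trial, then linearly interpolated at the model's state times
    (steps 1..n_steps).  Returns (8, n_steps, nc); raises if any stimulus
    lacks a correct-trial PSTH for a constrained unit.
    """
    axis: WarpAxis = psths.axis
    T0 = config.stim_onset
    D0 = T0 + assumed_iei
    edges = axis.bin_edges(T0, D0)
    centers = (edges[:-1] + edges[1:]) / 2.0
    t_model = config.dt * np.arange(1, config.n_steps + 1)
    targets = np.empty((len(psths.stimuli), config.n_steps, nc))
    for si in range(len(psths.stimuli)):
        if psths.n_correct[si] == 0:
            raise ValueError(
                f"no correct-trial PSTH for stimulus {psths.stimuli[si]}")
        for u in range(nc):
            targets[si, :, u] = np.interp(t_model, centers,
                                          psths.correct[si, u, :])
    return targets


def loss_terms(out: dict, targets: np.ndarray, gammas: np.ndarray,
               config: DynamicsConfig, tc: TrainConfig
               ) -> tuple[float, float, float]:
    """(L, L_beh, L_neu) for a recorded batch.

    L_beh penalizes c^2 over the pre-stimulus window and (c - gamma)^2 over
    the decision window; L_neu is the squared rate error of the constrained
    units against the PSTH targets.  Each is normalized by its term count.
    """
    c = out["c"]
    K = c.shape[0]
    nc = targets.shape[2]
    pre = config.prestim_steps + 1
    dec = config.decision_steps + 1
    beta_beh = K * (pre.size + dec.size)
    l_beh = (np.sum(c[:, pre] ** 2)
             + np.sum((c[:, dec] - gammas[:, None]) ** 2)) / beta_beh
    r = out["rates"][:, 1:, :nc]
    beta_neu = r.size
    l_neu = float(np.sum((r - targets) ** 2)) / beta_neu
    total = tc.lambda_beh * l_beh + tc.lambda_neu * l_neu
    return float(total), float(l_beh), float(l_neu)


def _backward(params: RNNParams, config: DynamicsConfig, tc: TrainConfig,
              out: dict, targets: np.ndarray, gammas: np.ndarray
              ) -> dict[str, np.ndarray]:
    """Hand-derived BPTT gradients of the total loss for one recorded batch."""
    rec = out["record"]
    h_traj, z_traj = rec["h"], rec["z"]
    rates, cs = out["rates"], out["c"]
    a = config.alpha
    steps = config.n_steps
    K, N = rates.shape[0], params.n_units
    nc = targets.shape[2]

    pre = set((config.prestim_steps + 1).tolist())
    dec = set((config.decision_steps + 1).tolist())
    beta_beh = K * (len(pre) + len(dec))
    beta_neu = K * steps * nc

    g = {k: np.zeros_like(v) for k, v in params.as_dict().items()}
    gh_next = np.zeros((K, N))      # dL/dh_{t+1} during the loop
    gz_next = np.zeros(K)
    gm_accum = np.zeros((K, N))     # sum over stimulus-on steps of alpha * gh
    on = rec["eta_on"]

    for t in range(steps, 0, -1):
        c_t = cs[:, t]
        gz_direct = np.zeros(K)
        if t in pre:
            gz_direct += tc.lambda_beh * 2.0 * c_t / beta_beh * (1 - c_t ** 2)
        if t in dec:
            gz_direct += tc.lambda_beh * 2.0 * (c_t - gammas) / beta_beh \
                * (1 - c_t ** 2)
        gz = gz_direct + (1 - a) * gz_next

        gr_direct = np.zeros((K, N))
        gr_direct[:, :nc] = tc.lambda_neu * 2.0 \
            * (rates[:, t, :nc] - targets[:, t - 1]) / beta_neu
        # r_t also feeds the t+1 updates of h and z
        gr = gr_direct + a * (gh_next @ params.Wrec) \
            + a * np.outer(gz_next, params.wz)
        gr *= out["clamp_mask"]
        s_t = h_traj[:, t] + params.b
        gs = gr * ((s_t > 0) & (s_t < config.rate_cap))

        gh = (1 - a) * gh_next + gs
        g["b"] += gs.sum(axis=0)
        # the step-t update consumed r_{t-1}, m(x_t) and eta_t
        g["Wrec"] += a * gh.T @ rates[:, t - 1]
        g["wz"] += a * rates[:, t - 1].T @ gz
        if on[t]:
            gm_accum += a * gh
        gh_next = gh
        gz_next = gz

    # tail at t = 0: r_0 = f(h_0 + b) fed the first update; h_0 = h0 trainable
    gr0 = (a * (gh_next @ params.Wrec) + a * np.outer(gz_next, params.wz)) \
        * out["clamp_mask"]
    s0 = h_traj[:, 0] + params.b
    gs0 = gr0 * ((s0 > 0) & (s0 < config.rate_cap))
    g["b"] += gs0.sum(axis=0)
    gh0 = (1 - a) * gh_next + gs0
    g["h0"] += gh0.sum(axis=0)

    # embedding gradients: m is the same (noiseless) vector at every on-step
    x_on = rec["x_eff"][:, config.stim_steps[0], :]   # (K, 2)
    u = x_on @ params.A1.T                            # (K, H)
    v = np.tanh(u)
    g["A2"] += gm_accum.T @ v
    gv = gm_accum @ params.A2
    gu = gv * (1 - v ** 2)
    g["A1"] += gu.T @ x_on

    np.fill_diagonal(g["Wrec"], 0.0)
    return g


def _adam_step(state: dict, grads: dict[str, np.ndarray], params: RNNParams,
               tc: TrainConfig) -> None:
    # global-norm gradient clipping at tc.grad_clip
    total = np.sqrt(sum(float(np.sum(g ** 2)) for g in grads.values()))
    if total > tc.grad_clip:
        scale = tc.grad_clip / (total + 1e-12)
        grads = {k: g * scale for k, g in grads.items()}
    state["t"] += 1
    t = state["t"]
    b1, b2, eps = 0.9, 0.999, 1e-8
    pd = params.as_dict()
    for k, gk in grads.items():
        state["m"][k] = b1 * state["m"][k] + (1 - b1) * gk
        state["v"][k] = b2 * state["v"][k] + (1 - b2) * gk ** 2
        mhat = state["m"][k] / (1 - b1 ** t)
        vhat = state["v"][k] / (1 - b2 ** t)
        pd[k] -= tc.lr * mhat / (np.sqrt(vhat) + eps)
    np.fill_diagonal(params.Wrec, 0.0)


def train(psths, nc: int, config: DynamicsConfig | None = None,
          tc: TrainConfig | None = None,
          stimuli: tuple[float, ...] = STIMULUS_SET
          ) -> tuple[RNNParams, dict]:
    """Train a constrained network against a session's correct-trial PSTHs.

    One noiseless presentation of each stimulus per iteration (internal noise
    active unless disabled); Adam with gradient clipping; stops at
    ``max_iters`` or when the total loss drops below ``loss_stop``.
    Returns the trained parameters and a history dict.
    """
    config = config or DynamicsConfig()
    tc = tc or TrainConfig()
    rng = np.random.default_rng(tc.seed)
    params = init_params(nc, embed_width=tc.embed_width, rng=rng)
    targets = psth_targets(psths, config, nc)
    gammas = np.array([gamma_target(s) for s in stimuli])
    stim_arr = np.asarray(stimuli, float)

    adam = {"t": 0,
            "m": {k: np.zeros_like(v) for k, v in params.as_dict().items()},
            "v": {k: np.zeros_like(v) for k, v in params.as_dict().items()}}
    history = {"loss": [], "loss_beh": [], "loss_neu": []}
    for it in range(tc.max_iters):
        out = simulate_batch(params, config, stim_arr, rng,
                             internal_noise=tc.internal_noise, record=True)
        L, L_beh, L_neu = loss_terms(out, targets, gammas, config, tc)
        if not np.isfinite(L):
            raise FloatingPointError(f"non-finite loss at iteration {it}")
        history["loss"].append(L)
        history["loss_beh"].append(L_beh)
        history["loss_neu"].append(L_neu)
        if L < tc.loss_stop:
            break
        grads = _backward(params, config, tc, out, targets, gammas)
        _adam_step(adam, grads, params, tc)
    return params, history
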