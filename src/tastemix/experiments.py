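"""Post-training protocol: noise calibration, batch simulation, ablations.

A trained network is first *calibrated*: the SD sigma of the persistent
input noise (added to the 2-d stimulus vector at every step) is searched so
that the model's overall accuracy over 20 trials per mixture lands within 5
percentage points of the accuracy of the session it was trained on.  The
search walks a coarse grid sigma = 0.05 .. 1.5 (step 0.05) with a fixed
seed per candidate and falls back to bisection between the best bracketing
pair if no grid point meets tolerance.

Calibrated models are then simulated in batches of 160 trials (20 per
stimulus) and the output is cast into the same (trial table, warped-rate
tensor) form as recorded sessions, so every analysis applies unchanged:
the model's T is the stimulus onset and D the decision time, and the
117-bin tensor is read directly off the model clock.

Virtual ablations clamp the rates of a labeled unit subset to zero at every
step — removing them from both the recurrence and the decision readout —
with seeds matched to the control batch.  Ablation unit sets come from the
response-profile classifier run on the control simulation (a unit belongs to
a coding set if it carries that label in any moving window); "other" units
are those never labeled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .session import STIMULUS_SET, expected_outcome
from . import geometry, profiles
from .psychometrics import fit_psychometric, psychometric_points
from .rnn import DynamicsConfig, RNNParams, simulate_batch

logger = logging.getLogger(__name__)

__all__ = ["CalibrationResult", "SimulatedSession", "calibrate_noise",
           "run_batch", "ablate_and_run", "coding_unit_sets",
           "ablation_report"]

ABLATION_CONDITIONS = ("control", "linear", "step_perception", "step_choice",
                       "other")


@dataclass
class CalibrationResult:
    sigma: float
    achieved_accuracy: float
    target_accuracy: float
    tolerance: float
    trace: list[tuple[float, float]]
    success: bool


@dataclass
class SimulatedSession:
    """A simulated batch in analysis-ready form."""

    trials: pd.DataFrame            # trial, stim_pct_sucrose, choice, outcome
    tensor: np.ndarray              # (trial, unit, 117 bins) rates, Hz
    sigma: float
    seed: int
    clamped_units: np.ndarray = field(default_factory=lambda: np.array([], int))

    @property
    def accuracy(self) -> float:
        return float((self.trials["outcome"] == "correct").mean())

    @property
    def stimuli(self) -> np.ndarray:
        return self.trials["stim_pct_sucrose"].to_numpy(float)

    @property
    def choices(self) -> np.ndarray:
        return self.trials["choice"].to_numpy()

    @property
    def outcomes(self) -> np.ndarray:
        return self.trials["outcome"].to_numpy()


def _batch_accuracy(params: RNNParams, config: DynamicsConfig, sigma: float,
                    n_per_stim: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    stimuli = np.repeat(STIMULUS_SET, n_per_stim)
    out = simulate_batch(params, config, stimuli, rng,
                         input_noise_sigma=sigma, internal_noise=True)
    correct = [expected_outcome(s, c) == "correct"
               for s, c in zip(stimuli, out["choices"])]
    return float(np.mean(correct))


def calibrate_noise(params: RNNParams, target_accuracy: float,
                    config: DynamicsConfig | None = None,
                    n_per_stim: int = 20, tolerance: float = 0.05,
                    seed: int = 0, grid_lo: float = 0.05,
                    grid_hi: float = 1.5, grid_step: float = 0.05,
                    max_bisect: int = 12) -> CalibrationResult:
    """Find the input-noise SD matching the model's accuracy to a target.

    Walks the coarse grid in ascending sigma (fixed seed per candidate) and
    returns the first sigma within tolerance; otherwise bisects between the
    two neighboring grid points whose accuracies bracket the target.
    """
    if not 0.5 < target_accuracy <= 1.0:
        raise ValueError("target accuracy must be in (0.5, 1]")
    config = config or DynamicsConfig()
    trace: list[tuple[float, float]] = []
    grid = np.arange(grid_lo, grid_hi + grid_step / 2, grid_step)
    accs = []
    for sigma in grid:
        acc = _batch_accuracy(params, config, float(sigma), n_per_stim, seed)
        trace.append((float(sigma), acc))
        accs.append(acc)
        if abs(acc - target_accuracy) <= tolerance:
            return CalibrationResult(float(sigma), acc, target_accuracy,
                                     tolerance, trace, success=True)
    # bisection between the bracketing neighbors (accuracy decreases with sigma
    # on average; pick the adjacent pair straddling the target)
    accs = np.array(accs)
    lo_i = None
    for i in range(len(grid) - 1):
        if (accs[i] - target_accuracy) * (accs[i + 1] - target_accuracy) < 0:
            lo_i = i
            break
    if lo_i is None:
        best = int(np.argmin(np.abs(accs - target_accuracy)))
        return CalibrationResult(float(grid[best]), float(accs[best]),
                                 target_accuracy, tolerance, trace,
                                 success=False)
    lo, hi = float(grid[lo_i]), float(grid[lo_i + 1])
    for _ in range(max_bisect):
        mid = (lo + hi) / 2
        acc = _batch_accuracy(params, config, mid, n_per_stim, seed)
        trace.append((mid, acc))
        if abs(acc - target_accuracy) <= tolerance:
            return CalibrationResult(mid, acc, target_accuracy, tolerance,
                                     trace, success=True)
        # accuracy is (stochastically) decreasing in sigma
        if acc > target_accuracy:
            lo = mid
        else:
            hi = mid
    sigma, acc = trace[-1]
    return CalibrationResult(sigma, acc, target_accuracy, tolerance, trace,
                             success=False)


def run_batch(params: RNNParams, sigma: float,
              config: DynamicsConfig | None = None, n_per_stim: int = 20,
              seed: int = 0,
              clamp_units: np.ndarray | None = None) -> SimulatedSession:
    """Simulate n_per_stim trials per mixture and cast to session form.

    The warped-tensor bins 1..117 of the model clock are taken directly as
    the 117-bin axis (T at bin 20, D at bin 97 boundary), since model trials
    all share the 3.9 s stimulus-to-decision interval.
    """
    config = config or DynamicsConfig()
    rng = np.random.default_rng(seed)
    stimuli = np.repeat(STIMULUS_SET, n_per_stim).astype(float)
    out = simulate_batch(params, config, stimuli, rng,
                         input_noise_sigma=sigma, internal_noise=True,
                         clamp_units=clamp_units)
    choices = out["choices"]
    outcomes = [expected_outcome(s, c) or "correct"
                for s, c in zip(stimuli, choices)]
    trials = pd.DataFrame({
        "trial": np.arange(len(stimuli)),
        "stim_pct_sucrose": stimuli,
        "choice": choices,
        "outcome": outcomes,
    })
    tensor = out["rates"][:, 1:118, :].transpose(0, 2, 1)   # (trial, unit, 117)
    return SimulatedSession(
        trials=trials, tensor=tensor, sigma=sigma, seed=seed,
        clamped_units=np.asarray(clamp_units if clamp_units is not None else [],
                                 int))


def ablate_and_run(params: RNNParams, unit_ids: np.ndarray, sigma: float,
                   config: DynamicsConfig | None = None, n_per_stim: int = 20,
                   seed: int = 0) -> SimulatedSession:
    """Run a batch with the given units' rates clamped to zero throughout."""
    return run_batch(params, sigma, config=config, n_per_stim=n_per_stim,
                     seed=seed, clamp_units=np.asarray(unit_ids, int))


def coding_unit_sets(control: SimulatedSession,
                     alpha: float = profiles.ALPHA_TEMPLATE
                     ) -> dict[str, np.ndarray]:
    """Unit sets per ablation condition from control-simulation labels.

    A unit belongs to a coding set if the classifier assigns it that label in
    at least one moving window of the control batch; "other" units are those
    never assigned any coding label.
    """
    tc = profiles.coding_timecourse(control.tensor, control.stimuli,
                                    control.outcomes, alpha=alpha)
    n_units = control.tensor.shape[1]
    sets: dict[str, set[int]] = {k: set() for k in profiles.CODING_LABELS}
    labeled = set()
    for u in range(n_units):
        for lab in tc["labels"][u]:
            if lab.label in sets:
                sets[lab.label].add(u)
                labeled.add(u)
    out = {k: np.array(sorted(v), int) for k, v in sets.items()}
    out["other"] = np.array(sorted(set(range(n_units)) - labeled), int)
    out["control"] = np.array([], int)
    return out


def _condition_separation(tensor: np.ndarray, cond: np.ndarray,
                          axis: np.ndarray) -> float:
    """Mean |projection| of condition means after centering across conditions.

    Measures how much condition (stimulus or choice) separation survives
    along an axis; ablating the units that carry the corresponding signal
    blunts it toward zero.
    """
    levels = np.unique(cond)
    means = np.stack([tensor[cond == u].mean(axis=0) for u in levels])
    centered = means - means.mean(axis=0, keepdims=True)
    proj = np.einsum("n,cnt->ct", axis, centered)
    return float(np.mean(np.abs(proj)))


def ablation_report(params: RNNParams, sigma: float,
                    config: DynamicsConfig | None = None, n_per_stim: int = 20,
                    seed: int = 0, min_trials_per_choice: int = 2,
                    dpca_mu: float = 0.0) -> dict:
    """Full ablation experiment for one model.

    Runs the control batch, derives coding unit sets from it, re-runs with
    each set clamped (matched seeds), and reports per condition: accuracy,
    a psychometric fit, mean |projection| on the control stimulus/choice
    axes, re-fit axes, and their overlap with the control axes.  The model
    is excluded (``included = False``) when any condition has fewer than 2
    trials for either choice direction.
    """
    config = config or DynamicsConfig()
    control = run_batch(params, sigma, config=config, n_per_stim=n_per_stim,
                        seed=seed)
    sets = coding_unit_sets(control)
    sessions = {"control": control}
    for cond in ("linear", "step_perception", "step_choice", "other"):
        sessions[cond] = ablate_and_run(params, sets[cond], sigma,
                                        config=config, n_per_stim=n_per_stim,
                                        seed=seed)

    included = all(
        min((s.choices == side).sum() for side in ("sucrose_side", "nacl_side"))
        >= min_trials_per_choice
        for s in sessions.values())
    if not included:
        logger.info("model excluded: <%d trials for a choice direction",
                    min_trials_per_choice)

    ct = geometry.condition_tensor(control.tensor, control.stimuli,
                                   control.choices)
    base = geometry.fit_dpca(geometry.impute_missing(ct), mu=dpca_mu)
    report: dict = {"included": included, "unit_sets": {k: v.tolist()
                                                        for k, v in sets.items()},
                    "conditions": {}}
    for cond, sess in sessions.items():
        entry: dict = {"accuracy": sess.accuracy,
                       "n_clamped": int(sess.clamped_units.size)}
        pts = psychometric_points(sess.trials)
        if pts.shape[0] >= 5:
            fit = fit_psychometric(pts)
            entry["psychometric"] = {"p1": fit.p1, "p2": fit.p2,
                                     "p3": fit.p3, "p4": fit.p4}
        for name, cond_var in (("stimulus", sess.stimuli),
                               ("choice", sess.choices)):
            axis = base.principal_axes[name]
            entry[f"mean_abs_projection_{name}"] = \
                _condition_separation(sess.tensor, cond_var, axis)
        ct_c = geometry.condition_tensor(sess.tensor, sess.stimuli,
                                         sess.choices)
        refit = geometry.fit_dpca(geometry.impute_missing(ct_c), mu=dpca_mu)
        for name in ("stimulus", "choice"):
            u, v = base.principal_axes[name], refit.principal_axes[name]
            try:
                entry[f"overlap_{name}"] = geometry.overlap(u, v)
            except ValueError:
                entry[f"overlap_{name}"] = float("nan")
        report["conditions"][cond] = entry
    return report
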