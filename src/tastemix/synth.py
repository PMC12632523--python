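"""Synthetic taste-mixture session generator.

Generates sessions with the statistical structure the downstream analyses
assume: a 4-parameter-logistic psychometric drives choices, and each unit
spikes as an inhomogeneous Poisson process whose rate expresses one of five
coding types —

``linear``
    rate tracks the mixture linearly, ``baseline + gain * (s/100) * env(t)``;
``step_perception``
    rate jumps at the 50/50 category boundary with the *stimulus* side, in
    both correct and error trials;
``step_choice``
    rate jumps with the *chosen* side regardless of stimulus;
``other_responsive``
    stimulus- and choice-independent bumps locked to the behavioral events;
``other_flat``
    constant baseline.

Tuning is expressed inside a temporal envelope: a Gaussian bump just after
the first central lick T (``sampling``), a linear ramp into the first lateral
lick D (``delay``), or their pointwise maximum (``both``).  Spiking uses
time-discretized Poisson thinning on a 1 ms grid, so spike counts in any
window are Poisson with the integrated rate.  Everything is reproducible from
the config seed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .session import STIMULUS_SET, Session, SpikeTrain, Trial, expected_outcome
from .psychometrics import logistic_4pl

logger = logging.getLogger(__name__)

__all__ = ["UnitSpec", "GenConfig", "GroundTruth", "draw_choice", "unit_rate",
           "generate_session"]

CODING_TYPES = ("linear", "step_perception", "step_choice", "other_responsive",
                "other_flat")


@dataclass(frozen=True)
class UnitSpec:
    """Ground-truth tuning of one synthetic unit."""

    unit_id: int
    coding_type: str
    baseline_rate: float
    gain: float
    envelope: str = "sampling"           # sampling | delay | both
    envelope_width: float = 0.5          # s; bump/ramp time scale
    preferred_side: str = "sucrose_side"  # step_choice only

    def __post_init__(self) -> None:
        if self.coding_type not in CODING_TYPES:
            raise ValueError(f"unknown coding_type {self.coding_type!r}")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")


@dataclass
class GenConfig:
    """Study conditions of a generated session.

    Defaults emulate a typical recording: 137 trials over the 8 mixtures,
    27 simultaneously recorded units of mixed coding types, choices following
    a 4PL psychometric with asymptotes 0.95/0.05 and slope 0.08 per %Sucrose
    (expected overall accuracy ~0.78), and a sampling-to-decision interval
    averaging 3.85 s.
    """

    n_trials: int = 137
    n_units: int = 27
    stimulus_set: tuple[float, ...] = STIMULUS_SET
    psycho_params: tuple[float, float, float, float] = (0.95, 0.08, 50.0, 0.05)
    iei_mean: float = 3.85
    iei_sd: float = 0.8
    iei_min: float = 1.0
    pre_T_window: float = 3.5   # s of pre-central-lick activity (baselines need >= 3 s)
    post_D_window: float = 1.0
    inter_trial_gap: float = 0.5
    coding_mix: dict[str, float] = field(default_factory=lambda: {
        "linear": 0.20, "step_perception": 0.15, "step_choice": 0.15,
        "other_responsive": 0.20, "other_flat": 0.30,
    })
    baseline_range: tuple[float, float] = (3.0, 6.0)
    gain_range: tuple[float, float] = (8.0, 14.0)
    seed: int = 0

    def validate(self) -> "GenConfig":
        p1, p2, p3, p4 = self.psycho_params
        if not (0 <= p1 <= 1 and 0 <= p4 <= 1 and 15 <= p3 <= 85):
            raise ValueError("psycho_params outside fitting constraints "
                             "(0<=p1,p4<=1, 15<=p3<=85)")
        total = sum(self.coding_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"coding_mix proportions sum to {total}, not 1")
        if self.iei_mean <= 0:
            raise ValueError("iei_mean must be > 0")
        return self


@dataclass
class GroundTruth:
    """Per-unit generating parameters plus the generating psychometric."""

    units: list[UnitSpec]
    psycho_params: tuple[float, float, float, float]

    def labels(self) -> dict[int, str]:
        return {u.unit_id: u.coding_type for u in self.units}

    def to_json(self) -> str:
        return json.dumps({
            "psycho_params": list(self.psycho_params),
            "units": [asdict(u) for u in self.units],
        }, indent=1)


def draw_choice(stimulus_s: float, psycho_params: Sequence[float],
                rng: np.random.Generator) -> str:
    """Bernoulli choice with P(sucrose_side) given by the 4PL psychometric."""
    if not 0 <= stimulus_s <= 100:
        raise ValueError("stimulus_s must be in [0, 100]")
    p1, p2, p3, p4 = psycho_params
    if not (0 <= p1 <= 1 and 0 <= p4 <= 1 and 15 <= p3 <= 85):
        raise ValueError("psychometric parameters outside fitting constraints")
    p_suc = float(logistic_4pl(stimulus_s, p1, p2, p3, p4))
    return "sucrose_side" if rng.random() < p_suc else "nacl_side"


def _envelope(spec: UnitSpec, trial: Trial, t: np.ndarray) -> np.ndarray:
    """Temporal envelope in [0, 1] on trial-clock times ``t`` (seconds)."""
    T, D = trial.t_central, trial.t_lateral
    w = spec.envelope_width
    samp = np.exp(-0.5 * ((t - (T + w / 2)) / (w / 2)) ** 2)
    ramp_start = D - 3.0 * w
    delay = np.clip((t - ramp_start) / (D - ramp_start), 0.0, 1.0)
    delay = np.where(t > D, 0.0, delay)
    if spec.envelope == "sampling":
        return samp
    if spec.envelope == "delay":
        return delay
    return np.maximum(samp, delay)


def unit_rate(spec: UnitSpec, trial: Trial, t: float | np.ndarray) -> np.ndarray:
    """Instantaneous firing rate (Hz) of a unit at time(s) ``t`` on one trial."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    env = _envelope(spec, trial, t)
    s = trial.stimulus_s
    if spec.coding_type == "linear":
        drive = spec.gain * (s / 100.0)
    elif spec.coding_type == "step_perception":
        drive = spec.gain * float(s > 50)
    elif spec.coding_type == "step_choice":
        drive = spec.gain * float(trial.choice == spec.preferred_side)
    elif spec.coding_type == "other_responsive":
        drive = spec.gain
    else:  # other_flat
        drive = 0.0
        env = np.zeros_like(env)
    rate = spec.baseline_rate + drive * env
    if np.any(rate < 0):
        logger.warning("unit %d: negative rate clipped to 0", spec.unit_id)
        rate = np.maximum(rate, 0.0)
    return rate


def _draw_unit_specs(config: GenConfig, rng: np.random.Generator) -> list[UnitSpec]:
    counts = _largest_remainder(config.coding_mix, config.n_units)
    specs: list[UnitSpec] = []
    uid = 0
    for ctype in CODING_TYPES:
        for _ in range(counts.get(ctype, 0)):
            lo, hi = config.baseline_range
            baseline = rng.uniform(lo, hi)
            glo, ghi = config.gain_range
            gain = rng.uniform(glo, ghi)
            envelope = rng.choice(["sampling", "delay", "both"])
            width = 0.5 if envelope == "sampling" else rng.uniform(0.5, 0.8)
            specs.append(UnitSpec(
                unit_id=uid, coding_type=ctype, baseline_rate=float(baseline),
                gain=float(gain), envelope=str(envelope),
                envelope_width=float(width),
                preferred_side=str(rng.choice(["sucrose_side", "nacl_side"])),
            ))
            uid += 1
    return specs


def _largest_remainder(mix: dict[str, float], n: int) -> dict[str, int]:
    raw = {k: v * n for k, v in mix.items()}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    if short:
        logger.info("coding_mix * n_units not integral; largest-remainder rounding")
        order = sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)
        for k in order[:short]:
            counts[k] += 1
    return counts


def _poisson_spikes(rate_fn, t0: float, t1: float, rng: np.random.Generator,
                    dt: float = 1e-3) -> np.ndarray:
    """Time-discretized thinning: Bernoulli(rate*dt) per 1 ms grid cell."""
    grid = np.arange(t0, t1, dt)
    rates = rate_fn(grid)
    keep = rng.random(grid.size) < rates * dt
    return grid[keep] + dt / 2.0


def generate_session(config: GenConfig,
                     session_id: str = "synthetic") -> tuple[Session, GroundTruth]:
    """Generate a full session plus its generating ground truth.

    Trials are laid end-to-end on a session clock.  Per trial: stimulus drawn
    uniformly from the stimulus set, choice from the psychometric, T at a
    fixed offset from trial start, and D = T + IEI with IEI drawn from a
    normal truncated below at ``iei_min``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    specs = _draw_unit_specs(config, rng)

    trials: list[Trial] = []
    clock = 0.0
    for k in range(config.n_trials):
        s = float(rng.choice(config.stimulus_set))
        choice = draw_choice(s, config.psycho_params, rng)
        outcome = expected_outcome(s, choice) or "correct"
        iei = -1.0
        while iei < config.iei_min:
            iei = rng.normal(config.iei_mean, config.iei_sd)
        T = clock + config.pre_T_window
        D = T + iei
        trials.append(Trial(index=k, stimulus_s=s, choice=choice,
                            outcome=outcome, t_central=T, t_lateral=D))
        clock = D + config.post_D_window + config.inter_trial_gap

    spikes: list[SpikeTrain] = []
    for spec in specs:
        for trial in trials:
            t0 = trial.t_central - config.pre_T_window
            t1 = trial.t_lateral + config.post_D_window
            times = _poisson_spikes(lambda t: unit_rate(spec, trial, t),
                                    t0, t1, rng)
            if times.size:
                spikes.append(SpikeTrain(unit_id=spec.unit_id,
                                         trial_index=trial.index,
                                         spike_times=times))

    session = Session(session_id=session_id, trials=trials, spikes=spikes,
                      n_units=config.n_units).validate()
    return session, GroundTruth(units=specs, psycho_params=config.psycho_params)


def write_ground_truth(gt: GroundTruth, directory: str | Path) -> None:
    Path(directory).mkdir(parents=True, exist_ok=True)
    (Path(directory) / "ground_truth.json").write_text(gt.to_json())
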