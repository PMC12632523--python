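"""Canonical data model for behavioral-electrophysiology sessions and its file I/O.

A session couples a trial table from a two-alternative taste-mixture task
(stimulus in %Sucrose, choice, outcome, and the two behavioral anchor events:
first central lick ``T`` and first lateral lick ``D``) with per-unit spike-time
lists on a common session clock.  All times are seconds.  Unit and trial
indices are 0-based, and choices are encoded semantically by taste side
(``sucrose_side`` / ``nacl_side``) so that left/right counterbalancing is
abstracted away.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STIMULUS_SET",
    "Trial",
    "SpikeTrain",
    "Session",
    "SessionFormatError",
    "SessionValidationError",
    "read_session",
    "write_session",
]

#: The eight %Sucrose mixture levels of the task, from pure NaCl to pure sucrose.
STIMULUS_SET: tuple[float, ...] = (0.0, 25.0, 35.0, 45.0, 55.0, 65.0, 75.0, 100.0)

CHOICES = ("sucrose_side", "nacl_side")
OUTCOMES = ("correct", "error")

TRIALS_COLUMNS = ["trial", "stim_pct_sucrose", "choice", "outcome", "t_central", "t_lateral"]
SPIKES_COLUMNS = ["unit", "trial", "spike_time"]


class SessionFormatError(ValueError):
    """A session file is malformed (missing column, bad enum value, ...)."""


class SessionValidationError(ValueError):
    """Session contents violate a data-model invariant."""


@dataclass(frozen=True)
class Trial:
    """One completed trial: stimulus, choice, outcome and event times.

    ``t_central`` is the first central-spout lick (stimulus sampling onset, T)
    and ``t_lateral`` the first lateral-spout lick (decision execution, D);
    both are on the session clock and ``t_lateral > t_central``.
    """

    index: int
    stimulus_s: float
    choice: str
    outcome: str
    t_central: float
    t_lateral: float

    def validate(self) -> None:
        if self.index < 0:
            raise SessionValidationError(f"trial index {self.index} < 0")
        if self.stimulus_s not in STIMULUS_SET:
            raise SessionValidationError(
                f"trial {self.index}: stimulus {self.stimulus_s} not one of {STIMULUS_SET}"
            )
        if self.choice not in CHOICES:
            raise SessionFormatError(f"trial {self.index}: bad choice {self.choice!r}")
        if self.outcome not in OUTCOMES:
            raise SessionFormatError(f"trial {self.index}: bad outcome {self.outcome!r}")
        if not (np.isfinite(self.t_central) and np.isfinite(self.t_lateral)):
            raise SessionValidationError(f"trial {self.index}: non-finite event times")
        if not self.t_lateral > self.t_central:
            raise SessionValidationError(
                f"trial {self.index}: t_lateral ({self.t_lateral}) <= t_central ({self.t_central})"
            )
        expected = expected_outcome(self.stimulus_s, self.choice)
        if expected is not None and expected != self.outcome:
            raise SessionValidationError(
                f"trial {self.index}: outcome {self.outcome!r} inconsistent with "
                f"stimulus {self.stimulus_s} and choice {self.choice!r}"
            )

    @property
    def iei(self) -> float:
        """Inter-event interval D - T in seconds."""
        return self.t_lateral - self.t_central


def expected_outcome(stimulus_s: float, choice: str) -> str | None:
    """Outcome implied by stimulus side and choice; None at the 50/50 boundary."""
    if stimulus_s > 50:
        return "correct" if choice == "sucrose_side" else "error"
    if stimulus_s < 50:
        return "correct" if choice == "nacl_side" else "error"
    return None


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times (sorted, seconds, session clock) of one unit on one trial."""

    unit_id: int
    trial_index: int
    spike_times: np.ndarray

    def validate(self) -> None:
        t = np.asarray(self.spike_times, dtype=float)
        if t.ndim != 1:
            raise SessionValidationError(
                f"unit {self.unit_id} trial {self.trial_index}: spike_times must be 1-D"
            )
        if t.size and not np.all(np.isfinite(t)):
            raise SessionValidationError(
                f"unit {self.unit_id} trial {self.trial_index}: non-finite spike time"
            )
        if t.size > 1 and np.any(np.diff(t) < 0):
            raise SessionValidationError(
                f"unit {self.unit_id} trial {self.trial_index}: spike times not sorted"
            )


@dataclass
class Session:
    """Trial table plus spike trains for one recording or simulation."""

    session_id: str
    trials: list[Trial]
    spikes: list[SpikeTrain]
    n_units: int = field(default=0)

    def __post_init__(self) -> None:
        if self.n_units == 0 and self.spikes:
            self.n_units = max(s.unit_id for s in self.spikes) + 1

    def validate(self) -> "Session":
        trial_ids = {t.index for t in self.trials}
        if len(trial_ids) != len(self.trials):
            raise SessionValidationError("duplicate trial indices")
        for t in self.trials:
            t.validate()
        unit_ids = set()
        for s in self.spikes:
            s.validate()
            unit_ids.add(s.unit_id)
            if s.trial_index not in trial_ids:
                raise SessionValidationError(
                    f"spike train refers to unknown trial {s.trial_index}"
                )
        if unit_ids and (min(unit_ids) < 0 or max(unit_ids) >= self.n_units):
            raise SessionValidationError(
                f"unit ids {sorted(unit_ids)} not within 0..{self.n_units - 1}"
            )
        return self

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def trial_table(self) -> pd.DataFrame:
        """Trial metadata as a DataFrame indexed by trial."""
        return pd.DataFrame(
            {
                "trial": [t.index for t in self.trials],
                "stim_pct_sucrose": [t.stimulus_s for t in self.trials],
                "choice": [t.choice for t in self.trials],
                "outcome": [t.outcome for t in self.trials],
                "t_central": [t.t_central for t in self.trials],
                "t_lateral": [t.t_lateral for t in self.trials],
            }
        ).set_index("trial", drop=False)

    def spike_lookup(self) -> dict[tuple[int, int], np.ndarray]:
        """Map (unit_id, trial_index) -> spike time array (empty if absent)."""
        return {(s.unit_id, s.trial_index): np.asarray(s.spike_times, float) for s in self.spikes}

    def accuracy(self) -> float:
        """Fraction of correct trials."""
        if not self.trials:
            return float("nan")
        return sum(t.outcome == "correct" for t in self.trials) / len(self.trials)


def read_session(trials_path: str | Path, spikes_path: str | Path,
                 session_id: str | None = None, n_units: int | None = None) -> Session:
    """Read a session from the plain CSV pair (trial table + long spike table).

    Raises :class:`SessionFormatError` when a required column is missing and
    :class:`SessionValidationError` when rows violate trial or spike-train
    invariants (e.g. ``t_lateral <= t_central``, unsorted spike times).
    """
    trials_path, spikes_path = Path(trials_path), Path(spikes_path)
    tdf = pd.read_csv(trials_path, float_precision="round_trip")
    for col in TRIALS_COLUMNS:
        if col not in tdf.columns:
            raise SessionFormatError(f"trials file missing column {col!r}")
    sdf = pd.read_csv(spikes_path, float_precision="round_trip")
    if len(sdf) == 0 and not set(SPIKES_COLUMNS) <= set(sdf.columns):
        sdf = pd.DataFrame(columns=SPIKES_COLUMNS)
    for col in SPIKES_COLUMNS:
        if col not in sdf.columns:
            raise SessionFormatError(f"spikes file missing column {col!r}")

    trials = [
        Trial(
            index=int(row.trial),
            stimulus_s=float(row.stim_pct_sucrose),
            choice=str(row.choice),
            outcome=str(row.outcome),
            t_central=float(row.t_central),
            t_lateral=float(row.t_lateral),
        )
        for row in tdf.itertuples(index=False)
    ]

    spikes: list[SpikeTrain] = []
    if len(sdf):
        for (unit, trial), grp in sdf.groupby(["unit", "trial"], sort=True):
            spikes.append(
                SpikeTrain(
                    unit_id=int(unit),
                    trial_index=int(trial),
                    spike_times=np.asarray(grp["spike_time"], dtype=float),
                )
            )

    sid = session_id or trials_path.stem.replace("_trials", "")
    sess = Session(session_id=sid, trials=trials, spikes=spikes,
                   n_units=n_units or 0)
    return sess.validate()


def read_session_dir(directory: str | Path) -> Session:
    """Read a session written by :func:`write_session` using its manifest."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    return read_session(
        directory / manifest["trials_file"],
        directory / manifest["spikes_file"],
        session_id=manifest["session_id"],
        n_units=manifest["n_units"],
    )


def write_session(session: Session, directory: str | Path) -> dict:
    """Write trial/spike CSVs plus a JSON manifest; round-trips exactly.

    Times are written with ``repr`` precision so that
    ``read_session(write_session(s))`` reproduces ``s`` bit-for-bit.
    """
    session.validate()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    trials_file = f"{session.session_id}_trials.csv"
    spikes_file = f"{session.session_id}_spikes.csv"

    tdf = session.trial_table().reset_index(drop=True)
    # shortest round-trip repr so times survive the CSV bit-for-bit
    for col in ("t_central", "t_lateral", "stim_pct_sucrose"):
        tdf[col] = [repr(float(v)) for v in tdf[col]]
    tdf.to_csv(directory / trials_file, index=False)

    rows = []
    for s in sorted(session.spikes, key=lambda s: (s.unit_id, s.trial_index)):
        for t in np.asarray(s.spike_times, float):
            rows.append((s.unit_id, s.trial_index, repr(float(t))))
    sdf = pd.DataFrame(rows, columns=SPIKES_COLUMNS)
    sdf.to_csv(directory / spikes_file, index=False)

    manifest = {
        "session_id": session.session_id,
        "n_units": session.n_units,
        "n_trials": session.n_trials,
        "trials_file": trials_file,
        "spikes_file": spikes_file,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
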