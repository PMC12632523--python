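"""Generate a synthetic session and recover each unit's coding type.

Builds a 400-trial session with known ground-truth tuning (linear,
step-perception, step-choice, other), warps spikes onto the 117-bin axis,
and runs the moving-window template classifier.  Prints, per coding type,
how many ground-truth units were recovered in at least one window.
"""

import numpy as np

from tastemix import profiles
from tastemix.synth import GenConfig, generate_session
from tastemix.warp import build_psths

cfg = GenConfig(n_trials=400, n_units=20, seed=5)
session, gt = generate_session(cfg)
print(f"session: {session.n_trials} trials, {session.n_units} units, "
      f"accuracy {session.accuracy():.3f}")

tensor, _ = build_psths(session)
stim = np.array([t.stimulus_s for t in session.trials])
outcome = np.array([t.outcome for t in session.trials])
tc = profiles.coding_timecourse(tensor.values, stim, outcome)

for target in ("linear", "step_perception", "step_choice"):
    units = [u.unit_id for u in gt.units if u.coding_type == target]
    hit = sum(target in {l.label for l in tc["labels"][u]} for u in units)
    print(f"{target:16s} {hit}/{len(units)} units recovered")

print("multiplexing (units per coding-type combination between T and D):")
for combo, n in profiles.multiplex_summary(tc).items():
    if n:
        print(f"  {combo}: {n}")
# Recovered counts at the generating labels show the classifier works at the
# session's trial counts and firing-rate gains; multiplexed combinations are
# units whose label changes across the trial.
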