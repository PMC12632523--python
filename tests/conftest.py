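"""Shared fixtures: synthetic sessions and a small trained network.

Session-scoped so expensive artifacts (generation, warping, RNN training)
are built once per test run.
"""

import numpy as np
import pytest

from tastemix import rnn
from tastemix.synth import GenConfig, generate_session
from tastemix.warp import build_psths


@pytest.fixture(scope="session")
def small_session():
    """A default-scale session: 120 trials, 8 units of mixed coding types."""
    cfg = GenConfig(n_trials=120, n_units=8, seed=3)
    session, gt = generate_session(cfg)
    return session, gt


@pytest.fixture(scope="session")
def recovery_bundle():
    """A session large enough for tuning-curve label recovery (~50 trials/stim)."""
    cfg = GenConfig(n_trials=400, n_units=20, seed=5)
    session, gt = generate_session(cfg)
    tensor, psths = build_psths(session)
    stim = np.array([t.stimulus_s for t in session.trials])
    choice = np.array([t.choice for t in session.trials])
    outcome = np.array([t.outcome for t in session.trials])
    return dict(session=session, gt=gt, tensor=tensor, psths=psths,
                stim=stim, choice=choice, outcome=outcome)


@pytest.fixture(scope="session")
def toy_trained():
    """A small constrained network (Nc=5) trained on a synthetic session."""
    cfg = GenConfig(n_trials=300, n_units=5, seed=7)
    session, _ = generate_session(cfg)
    _, psths = build_psths(session)
    tc = rnn.TrainConfig(seed=11, max_iters=1000)
    params, history = rnn.train(psths, 5, tc=tc)
    return dict(session=session, psths=psths, params=params, history=history)
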