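"""Tuning-curve template fits and coding-type classification."""

import numpy as np
import pytest
from scipy import optimize, stats

from tastemix import profiles
from tastemix.profiles import (CodingLabel, ResponseProfile, classify_profile,
                               fit_line, fit_step, moving_windows,
                               multiplex_summary, response_profile)
from tastemix.session import STIMULUS_SET

STIMS = np.array(STIMULUS_SET)


def _profile(rates, outcome="correct"):
    return ResponseProfile(stimuli=STIMS, rates=np.asarray(rates, float),
                           n_trials=np.full(8, 10), outcome=outcome,
                           window=(20, 24))


def test_exact_step_profile():
    fit = fit_step(_profile([2, 2, 2, 2, 9, 9, 9, 9]))
    assert fit.params == (2.0, 9.0, 50.0)
    assert fit.sse_fit == pytest.approx(0.0)
    assert np.isinf(fit.fstat) and fit.p_value == 0.0


def test_constant_profile_yields_no_improvement():
    line = fit_line(_profile([4.0] * 8))
    step = fit_step(_profile([4.0] * 8))
    assert line.fstat == 0.0 and line.p_value == 1.0
    assert step.fstat == 0.0 and step.p_value == 1.0
    assert classify_profile(_profile([4.0] * 8), None).label == "other"


def test_line_fit_matches_ols_when_unconstrained_is_feasible():
    rng = np.random.default_rng(0)
    r = 3.0 + 0.05 * STIMS + rng.normal(0, 0.3, 8)
    fit = fit_line(_profile(r))
    X = np.column_stack([STIMS, np.ones(8)])
    beta, *_ = np.linalg.lstsq(X, r, rcond=None)
    assert fit.params == pytest.approx(tuple(beta))


def test_constrained_line_fit_matches_numerical_qp_oracle():
    rng = np.random.default_rng(1)
    for _ in range(30):
        # slopes that force the line negative at one end
        r = rng.normal(0.0, 2.0, 8) + 0.06 * STIMS - 3.0
        prof = _profile(np.maximum(r, 0))
        fit = fit_line(prof)
        X = np.column_stack([STIMS, np.ones(8)])
        res = optimize.minimize(
            lambda p: np.sum((prof.rates - X @ p) ** 2), x0=[0.0, 1.0],
            constraints=[{"type": "ineq", "fun": lambda p, s=s: p[0] * s + p[1]}
                         for s in STIMS], method="SLSQP",
            options={"maxiter": 500, "ftol": 1e-14})
        assert fit.sse_fit <= np.sum((prof.rates - X @ res.x) ** 2) + 1e-6


def test_step_fit_matches_exhaustive_enumeration():
    rng = np.random.default_rng(2)
    for _ in range(30):
        r = rng.uniform(0, 10, 8)
        fit = fit_step(_profile(r))
        best = min(
            ((np.sum((r - np.where(STIMS < p3, r[STIMS < p3].mean(),
                                   r[STIMS >= p3].mean())) ** 2), p3)
             for p3 in (40.0, 50.0, 60.0)))
        assert fit.sse_fit == pytest.approx(best[0])
        assert fit.params[2] == best[1]


def test_f_statistic_against_direct_formula():
    rng = np.random.default_rng(3)
    r = rng.uniform(1, 9, 8)
    fit = fit_step(_profile(r))
    if fit.sse_fit > 0:
        f = (fit.sse_null - fit.sse_fit) / fit.sse_fit * (8 - 3) / (3 - 1)
        assert fit.fstat == pytest.approx(f)
        assert fit.p_value == pytest.approx(stats.f.sf(f, 2, 5))


def test_step_choice_requires_inverted_error_delta():
    correct = _profile([2, 2, 2, 2, 9, 9, 9, 9])
    error_mirror = _profile([9, 9, 9, 9, 2, 2, 2, 2], outcome="error")
    error_same = _profile([2, 2, 2, 2, 9, 9, 9, 9], outcome="error")
    assert classify_profile(correct, error_mirror).label == "step_choice"
    assert classify_profile(correct, error_same).label == "step_perception"
    assert classify_profile(correct, None).label == "step_unresolved"


def test_step_unresolved_when_one_error_side_missing():
    correct = _profile([2, 2, 2, 2, 9, 9, 9, 9])
    half_error = ResponseProfile(stimuli=STIMS[:4],
                                 rates=np.array([9.0, 9, 9, 9]),
                                 n_trials=np.full(4, 3), outcome="error",
                                 window=(20, 24))
    assert classify_profile(correct, half_error).label == "step_unresolved"


def test_moving_windows_tile_the_axis():
    w = moving_windows(117, 4)
    assert len(w) == 30
    assert w[0] == (0, 4) and w[-1] == (116, 117)
    assert sum(hi - lo for lo, hi in w) == 117


def test_response_profile_from_single_trials():
    rng = np.random.default_rng(4)
    tensor = rng.uniform(0, 10, (8, 1, 117))
    stim = STIMS.copy()
    outcome = np.array(["correct"] * 8)
    prof = response_profile(tensor, stim, outcome, 0, (10, 20))
    np.testing.assert_allclose(prof.rates, tensor[:, 0, 10:20].mean(axis=1))
    with pytest.raises(ValueError):
        response_profile(tensor, stim, outcome, 0, (10, 10))


def test_multiplex_partition_identity():
    labels = {
        0: ["linear", "other", "step_choice"],
        1: ["other", "other", "other"],
        2: ["step_perception", "step_perception", "other"],
        3: ["linear", "linear", "linear"],
    }
    windows = [(20, 24), (40, 44), (60, 64)]
    tc = {"windows": windows,
          "labels": [[CodingLabel(label=l) for l in labels[u]]
                     for u in range(4)]}
    counts = multiplex_summary(tc)
    assert counts["linear+step_choice"] == 1
    assert counts["step_perception"] == 1
    assert counts["linear"] == 1
    assert sum(counts.values()) == 3      # units with >= 1 coding label


def test_ground_truth_labels_recovered(recovery_bundle):
    tc = profiles.coding_timecourse(recovery_bundle["tensor"].values,
                                    recovery_bundle["stim"],
                                    recovery_bundle["outcome"])
    gt = recovery_bundle["gt"]
    for target in ("linear", "step_perception", "step_choice"):
        units = [u.unit_id for u in gt.units if u.coding_type == target]
        hit = sum(target in {l.label for l in tc["labels"][u]} for u in units)
        assert hit / len(units) >= 0.8
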