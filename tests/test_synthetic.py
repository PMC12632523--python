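"""Synthetic generator: determinism, rate formulas, Poisson statistics,
psychometric behavior."""

import numpy as np
import pytest
from scipy import stats

from tastemix.psychometrics import (fit_psychometric, logistic_4pl,
                                    psychometric_points)
from tastemix.session import Trial
from tastemix.synth import (GenConfig, UnitSpec, draw_choice,
                            generate_session, unit_rate)


def test_same_seed_identical_sessions():
    cfg = GenConfig(n_trials=30, n_units=4, seed=9)
    s1, gt1 = generate_session(cfg)
    s2, gt2 = generate_session(cfg)
    assert s1.trials == s2.trials
    k1, k2 = s1.spike_lookup(), s2.spike_lookup()
    assert set(k1) == set(k2)
    for key in k1:
        np.testing.assert_array_equal(k1[key], k2[key])
    assert gt1.units == gt2.units


def test_draw_choice_flat_curve_is_fair_coin():
    rng = np.random.default_rng(0)
    draws = [draw_choice(35.0, (0.5, 0.1, 50, 0.5), rng) for _ in range(4000)]
    frac = np.mean([d == "sucrose_side" for d in draws])
    assert abs(frac - 0.5) < 0.03


def test_draw_choice_saturated_curve():
    rng = np.random.default_rng(0)
    assert all(draw_choice(100.0, (1.0, 50.0, 50, 0.0), rng) == "sucrose_side"
               for _ in range(50))


def test_draw_choice_midpoint_of_asymptotes():
    # at s = p3 the 4PL evaluates to the midpoint of the asymptotes
    assert logistic_4pl(50, 0.95, 0.08, 50, 0.05) == pytest.approx(0.5)


def test_draw_choice_rejects_out_of_bounds_params():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError):
        draw_choice(50.0, (1.2, 0.1, 50, 0.0), rng)


@pytest.mark.parametrize("ctype,s,choice,expected", [
    ("other_flat", 75.0, "sucrose_side", 5.0),
    ("linear", 100.0, "sucrose_side", 10.0),
    ("linear", 0.0, "nacl_side", 2.0),
])
def test_unit_rate_formulas(ctype, s, choice, expected):
    base = 5.0 if ctype == "other_flat" else 2.0
    spec = UnitSpec(unit_id=0, coding_type=ctype, baseline_rate=base,
                    gain=8.0, envelope="sampling", envelope_width=0.5)
    outcome = "correct" if (s > 50) == (choice == "sucrose_side") else "error"
    trial = Trial(0, s, choice, outcome, 3.5, 7.4)
    # envelope peaks at T + width/2; evaluate there where env = 1
    rate = unit_rate(spec, trial, 3.5 + 0.25)
    assert rate[0] == pytest.approx(expected, abs=1e-9)


def test_step_choice_unit_is_choice_locked_on_error_trials():
    spec = UnitSpec(unit_id=0, coding_type="step_choice", baseline_rate=2.0,
                    gain=10.0, envelope="sampling", envelope_width=0.5,
                    preferred_side="sucrose_side")
    # error trial: s = 25 but the animal chose the sucrose side
    err = Trial(0, 25.0, "sucrose_side", "error", 3.5, 7.4)
    cor = Trial(1, 25.0, "nacl_side", "correct", 3.5, 7.4)
    assert unit_rate(spec, err, 3.75)[0] > unit_rate(spec, cor, 3.75)[0] + 5


def test_flat_units_spike_at_poisson_rate():
    cfg = GenConfig(n_trials=100, n_units=3, seed=21,
                    coding_mix={"other_flat": 1.0},
                    baseline_range=(10.0, 10.0))
    session, _ = generate_session(cfg)
    lookup = session.spike_lookup()
    for u in range(3):
        # fixed-length window so counts are identically distributed Poisson
        counts = []
        for t in session.trials:
            lo, hi = t.t_central - 3.0, t.t_central
            st = lookup.get((u, t.index), np.empty(0))
            counts.append(np.sum((st >= lo) & (st < hi)))
        expect = 10.0 * 3.0
        se = np.sqrt(expect / len(session.trials))
        assert abs(np.mean(counts) - expect) < 3 * se
        # index of dispersion ~ 1 for Poisson counts
        disp = np.var(counts) / np.mean(counts)
        assert 0.6 < disp < 1.5


def test_psychometric_recovery_from_generated_choices():
    gen_params = (0.95, 0.08, 50.0, 0.05)
    cfg = GenConfig(n_trials=5000, n_units=0, coding_mix={"other_flat": 1.0},
                    psycho_params=gen_params, seed=13)
    session, _ = generate_session(cfg)
    fit = fit_psychometric(psychometric_points(session.trial_table()))
    assert abs(fit.p2 - gen_params[1]) / gen_params[1] < 0.20


def test_choice_frequencies_match_generating_curve():
    cfg = GenConfig(n_trials=2000, n_units=0, coding_mix={"other_flat": 1.0},
                    seed=17)
    session, _ = generate_session(cfg)
    df = session.trial_table()
    chi2 = 0.0
    for s, grp in df.groupby("stim_pct_sucrose"):
        n = len(grp)
        k = int((grp["choice"] == "sucrose_side").sum())
        p = float(logistic_4pl(s, *cfg.psycho_params))
        chi2 += (k - n * p) ** 2 / (n * p * (1 - p))
    p_gof = stats.chi2.sf(chi2, df=8)
    assert p_gof > 0.01
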