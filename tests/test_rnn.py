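"""Constrained rate network: dynamics, gradients, training behavior."""

import numpy as np
import pytest

from tastemix import rnn


def test_transfer_is_capped_rectifier():
    assert rnn.transfer(np.array([-5.0]))[0] == 0.0
    assert rnn.transfer(np.array([100.0]))[0] == 80.0
    assert rnn.transfer(np.array([37.2]))[0] == 37.2


def test_unit_count_arithmetic():
    params = rnn.init_params(27, embed_width=4)
    assert params.n_unconstrained == 159       # round(5.88 * 27)
    assert params.n_units == 186


def test_stimulus_vector_encoding():
    np.testing.assert_allclose(rnn.stimulus_vector(100.0), [1.0, 0.0])
    np.testing.assert_allclose(rnn.stimulus_vector(25.0), [0.25, 0.75])


def test_embedding_matches_matrix_arithmetic():
    A1 = np.array([[0.5, -1.0], [2.0, 0.25]])
    A2 = np.array([[1.0, 0.0], [0.5, -0.5], [2.0, 1.0]])
    x = np.array([0.25, 0.75])
    expected = A2 @ np.tanh(A1 @ x)
    np.testing.assert_allclose(rnn.stimulus_embed(x, A1, A2), expected)
    assert np.all(rnn.stimulus_embed(np.zeros(2), A1, A2) == 0)
    with pytest.raises(ValueError):
        rnn.stimulus_embed(np.zeros(3), A1, A2)


def _interior_params(n=4):
    rng = np.random.default_rng(0)
    params = rnn.init_params(1, embed_width=3, rng=rng)
    return params


def test_leaky_integration_fixed_point():
    # Wrec = 0, no noise, constant input: h converges to m geometrically
    rng = np.random.default_rng(1)
    params = rnn.init_params(2, embed_width=3, rng=rng)
    params.Wrec[:] = 0.0
    cfg = rnn.DynamicsConfig(trial_length=5.9, stim_onset=0.0,
                             stim_duration=5.9)
    out = rnn.simulate_batch(params, cfg, np.array([75.0]),
                             np.random.default_rng(0), internal_noise=False,
                             record=True)
    m = rnn.stimulus_embed(rnn.stimulus_vector(75.0), params.A1, params.A2)
    h = out["record"]["h"][0]
    # residual shrinks by (1 - alpha) each step
    res = np.linalg.norm(h - m, axis=1)
    ratios = res[1:20] / res[:19]
    np.testing.assert_allclose(ratios, 1 - cfg.alpha, atol=1e-8)
    np.testing.assert_allclose(h[-1], m, atol=1e-8)


def test_zero_params_zero_state_stays_zero():
    params = rnn.init_params(2, embed_width=3)
    for arr in params.as_dict().values():
        arr[:] = 0.0
    cfg = rnn.DynamicsConfig()
    out = rnn.simulate_batch(params, cfg, np.array([75.0]),
                             np.random.default_rng(0), internal_noise=False)
    assert np.all(out["rates"] == 0) and np.all(out["c"] == 0)


def test_single_euler_step_matches_hand_computation():
    params = rnn.init_params(1, embed_width=2, rng=np.random.default_rng(2))
    # small 7-unit net; compute one update by hand for a no-noise step
    cfg = rnn.DynamicsConfig(trial_length=0.1, stim_onset=0.0,
                             stim_duration=0.1, decision_time=0.05)
    out = rnn.simulate_batch(params, cfg, np.array([100.0]),
                             np.random.default_rng(0), internal_noise=False,
                             record=True)
    h0 = params.h0
    r0 = np.clip(h0 + params.b, 0, 80)
    m = rnn.stimulus_embed(rnn.stimulus_vector(100.0), params.A1, params.A2)
    h1 = h0 + cfg.alpha * (-h0 + m + params.Wrec @ r0)
    np.testing.assert_allclose(out["record"]["h"][0, 1], h1, atol=1e-12)
    z1 = cfg.alpha * (params.wz @ r0)
    np.testing.assert_allclose(out["record"]["z"][0, 1], z1, atol=1e-12)


def test_simulation_deterministic_given_seed():
    params = rnn.init_params(2, embed_width=3, rng=np.random.default_rng(3))
    cfg = rnn.DynamicsConfig()
    a = rnn.simulate_trial(params, cfg, 75.0, input_noise_sigma=0.3, seed=5)
    b = rnn.simulate_trial(params, cfg, 75.0, input_noise_sigma=0.3, seed=5)
    np.testing.assert_array_equal(a["rates"], b["rates"])
    assert a["choice"] == b["choice"]


def test_zero_readout_weights_give_single_class():
    params = rnn.init_params(2, embed_width=3, rng=np.random.default_rng(4))
    params.wz[:] = 0.0
    cfg = rnn.DynamicsConfig()
    out = rnn.simulate_batch(params, cfg,
                             np.array([0.0, 25.0, 75.0, 100.0]),
                             np.random.default_rng(0), internal_noise=False)
    assert np.all(out["mean_c"] == 0)
    assert len(set(out["choices"])) == 1


def test_analytic_gradients_match_finite_differences():
    nc, H = 3, 4
    cfg = rnn.DynamicsConfig(trial_length=0.5, stim_onset=0.1,
                             stim_duration=0.2, decision_time=0.45,
                             decision_window=0.1)
    tc = rnn.TrainConfig(embed_width=H, internal_noise=False)
    rng = np.random.default_rng(3)
    params = rnn.init_params(nc, embed_width=H, rng=rng)
    params.A1 *= 0.3
    params.A2 *= 0.3
    params.b[:] = rng.normal(2.0, 0.5, params.n_units)
    params.h0[:] = rng.normal(1.0, 0.3, params.n_units)
    stim = np.array([25.0, 75.0])
    gammas = np.array([rnn.gamma_target(s) for s in stim])
    targets = rng.uniform(1, 5, (2, cfg.n_steps, nc))

    def loss_of(p):
        out = rnn.simulate_batch(p, cfg, stim, np.random.default_rng(0),
                                 internal_noise=False, record=True)
        return rnn.loss_terms(out, targets, gammas, cfg, tc)[0], out

    _, out = loss_of(params)
    grads = rnn._backward(params, cfg, tc, out, targets, gammas)
    eps = 1e-6
    check_rng = np.random.default_rng(1)
    for name, arr in params.as_dict().items():
        flat_idx = check_rng.choice(arr.size, min(5, arr.size), replace=False)
        for fi in flat_idx:
            idx = np.unravel_index(fi, arr.shape)
            if name == "Wrec" and idx[0] == idx[1]:
                continue
            old = arr[idx]
            arr[idx] = old + eps
            lp, _ = loss_of(params)
            arr[idx] = old - eps
            lm, _ = loss_of(params)
            arr[idx] = old
            fd = (lp - lm) / (2 * eps)
            an = grads[name][idx]
            assert abs(fd - an) / max(1e-8, abs(fd) + abs(an)) < 1e-4, \
                f"{name}{idx}: fd={fd} analytic={an}"


def test_rates_and_choice_activity_bounded(toy_trained):
    params = toy_trained["params"]
    out = rnn.simulate_batch(params, rnn.DynamicsConfig(),
                             np.array([0.0, 45.0, 100.0]),
                             np.random.default_rng(0), input_noise_sigma=0.5)
    assert np.all(out["rates"] >= 0) and np.all(out["rates"] <= 80)
    assert np.all(np.abs(out["c"]) < 1)


def test_recurrent_diagonal_stays_zero_through_training(toy_trained):
    assert np.all(np.diag(toy_trained["params"].Wrec) == 0)


def test_loss_trend_decreases(toy_trained):
    loss = np.array(toy_trained["history"]["loss"])
    smooth = np.convolve(loss, np.ones(50) / 50, mode="valid")
    assert smooth[-1] < smooth[0] * 0.5
    assert smooth[-1] == np.min(smooth[[0, len(smooth) // 2, -1]])


def test_trained_model_matches_target_psths(toy_trained):
    params = toy_trained["params"]
    psths = toy_trained["psths"]
    cfg = rnn.DynamicsConfig()
    targets = rnn.psth_targets(psths, cfg, 5)
    out = rnn.simulate_batch(params, cfg, np.array(list(psths.stimuli), float),
                             np.random.default_rng(0), internal_noise=True)
    r = out["rates"][:, 1:, :5]
    rmse = np.sqrt(((r - targets) ** 2).mean(axis=(0, 1)))
    assert np.median(rmse) < 2.0


def test_trained_model_solves_easy_mixtures_noiselessly(toy_trained):
    params = toy_trained["params"]
    cfg = rnn.DynamicsConfig()
    easy = np.array([0.0, 25.0, 35.0, 65.0, 75.0, 100.0])
    out = rnn.simulate_batch(params, cfg, easy, np.random.default_rng(0),
                             internal_noise=False)
    expected = np.where(easy > 50, "sucrose_side", "nacl_side")
    assert list(out["choices"]) == list(expected)
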