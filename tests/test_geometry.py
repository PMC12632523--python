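"""Pairwise distances, dPCA marginalizations, imputation, projections."""

import numpy as np
import pytest

from tastemix import geometry
from tastemix.warp import PSTHSet, WarpAxis


def _random_condition_tensor(rng, n_units=5, T=15, low_rank=None, noise=0.0):
    if low_rank:
        U = rng.normal(0, 1, (n_units, low_rank))
        V = rng.normal(0, 1, (low_rank, 8 * 2 * T))
        mean = (U @ V).reshape(n_units, 8, 2, T) + 5.0
    else:
        mean = rng.normal(5, 2, (n_units, 8, 2, T))
    if noise:
        mean = mean + rng.normal(0, noise, mean.shape)
    trials = [[rng.normal(m, 1.0, (4, n_units, T)) for m in
               (mean[:, s, 0, :], mean[:, s, 1, :])] for s in range(8)]
    trials = [[np.transpose(b, (0, 1, 2)) for b in row] for row in trials]
    return geometry.ConditionTensor(trials=trials, mean=mean)


def test_pairwise_distance_345_triangle():
    axis = WarpAxis(n_pre=0, n_warp=1, n_post=0)
    correct = np.full((8, 2, 1), np.nan)
    correct[0, :, 0] = [0.0, 0.0]
    correct[7, :, 0] = [3.0, 4.0]
    psths = PSTHSet(correct=correct, error=np.full_like(correct, np.nan),
                    n_correct=np.array([1, 0, 0, 0, 0, 0, 0, 1]),
                    n_error=np.zeros(8, int), axis=axis)
    d = geometry.pairwise_distances(psths)
    assert d[0, 7] == pytest.approx(5.0)
    assert d[0, 0] == 0.0


def test_pairwise_distance_metric_axioms():
    rng = np.random.default_rng(0)
    axis = WarpAxis(n_pre=0, n_warp=3, n_post=0)
    correct = rng.uniform(0, 10, (8, 4, 3))
    psths = PSTHSet(correct=correct, error=np.full_like(correct, np.nan),
                    n_correct=np.ones(8, int), n_error=np.zeros(8, int),
                    axis=axis)
    d = geometry.pairwise_distances(psths)
    np.testing.assert_allclose(d, d.T)
    np.testing.assert_allclose(np.diag(d), 0, atol=1e-12)
    n = d.shape[0]
    idx = rng.integers(0, n, (40, 3))
    for i, j, k in idx:
        assert d[i, k] <= d[i, j] + d[j, k] + 1e-9


def test_marginalizations_sum_to_centered_data():
    rng = np.random.default_rng(1)
    mean = rng.normal(5, 2, (6, 8, 2, 20))
    parts = geometry.marginalize(mean)
    center = mean - mean.mean(axis=(1, 2, 3), keepdims=True)
    assert np.abs(sum(parts.values()) - center).max() < 1e-10


def test_dpca_equals_reduced_rank_least_squares_at_zero_regularization():
    rng = np.random.default_rng(2)
    ct = _random_condition_tensor(rng, n_units=6, T=12)
    res = geometry.fit_dpca(ct, mu=0.0, noise=None, n_components=2)
    center = ct.mean - ct.mean.mean(axis=(1, 2, 3), keepdims=True)
    X = center.reshape(6, -1)
    for name, m in geometry.marginalize(ct.mean).items():
        Y = m.reshape(6, -1)
        B = Y @ X.T @ np.linalg.pinv(X @ X.T)
        U, _, _ = np.linalg.svd(B @ X, full_matrices=False)
        Uq = U[:, :2]
        oracle = Uq @ Uq.T @ B @ X
        fitted = res.encoders[name] @ (res.decoders[name] @ X)
        np.testing.assert_allclose(fitted, oracle, atol=1e-8)


def test_zero_choice_variance_gives_flat_choice_component():
    rng = np.random.default_rng(3)
    mean = rng.normal(5, 2, (5, 8, 1, 10))
    mean = np.repeat(mean, 2, axis=2)          # both choices identical
    ct = geometry.ConditionTensor(trials=[[np.empty((0, 5, 10))] * 2] * 8,
                                  mean=mean)
    parts = geometry.marginalize(mean)
    assert np.abs(parts["choice"]).max() < 1e-12


def test_impute_identity_when_complete():
    rng = np.random.default_rng(4)
    ct = _random_condition_tensor(rng)
    out = geometry.impute_missing(ct)
    np.testing.assert_array_equal(out.mean, ct.mean)


def test_impute_recovers_exact_regression_data():
    # condition means generated exactly from the per-bin linear model
    rng = np.random.default_rng(5)
    stims = np.array([0, 25, 35, 45, 55, 65, 75, 100], float)
    T, n_units = 6, 3
    beta = rng.normal(0, 1, (n_units, 4, T))
    mean = np.empty((n_units, 8, 2, T))
    for si, s in enumerate(stims):
        for q in (0, 1):
            x = np.array([1.0, s, q, s * q])
            mean[:, si, q, :] = np.einsum("j,njt->nt", x, beta)
    full = mean.copy()
    mean[:, 2, 1, :] = np.nan
    mean[:, 6, 0, :] = np.nan
    ct = geometry.ConditionTensor(trials=[[np.empty((0, n_units, T))] * 2] * 8,
                                  mean=mean)
    out = geometry.impute_missing(ct)
    np.testing.assert_allclose(out.mean, full, atol=1e-8)


def test_single_trial_condition_is_duplicated():
    rng = np.random.default_rng(6)
    tensor = rng.uniform(0, 5, (4, 3, 10))
    stim = np.array([0.0, 0.0, 25.0, 100.0])
    choice = np.array(["nacl_side", "nacl_side", "nacl_side", "sucrose_side"])
    ct = geometry.condition_tensor(tensor, stim, choice)
    assert ct.trials[1][0].shape[0] == 2           # s=25, nacl: 1 trial copied
    np.testing.assert_array_equal(ct.trials[1][0][0], ct.trials[1][0][1])


def test_regularization_selection_prefers_zero_for_noiseless_low_rank():
    rng = np.random.default_rng(7)
    ct = _random_condition_tensor(rng, low_rank=2)
    # make split halves identical: no trial noise at all
    trials = [[np.repeat(ct.mean[:, s, q, :][None], 4, axis=0)
               for q in range(2)] for s in range(8)]
    ct = geometry.ConditionTensor(trials=trials, mean=ct.mean)
    mu = geometry.select_regularization(ct, seed=0, noise=None)
    assert mu == 0.0


def test_regularization_selection_is_seed_deterministic():
    rng = np.random.default_rng(8)
    ct = _random_condition_tensor(rng, low_rank=2)
    mu1 = geometry.select_regularization(ct, seed=3)
    mu2 = geometry.select_regularization(ct, seed=3)
    assert mu1 == mu2


def test_heavy_noise_selects_positive_regularization():
    rng = np.random.default_rng(9)
    n_units, T = 6, 10
    mean = np.zeros((n_units, 8, 2, T)) + 5.0
    trials = [[5.0 + rng.normal(0, 6.0, (3, n_units, T)) for _ in range(2)]
              for _ in range(8)]
    emp = np.stack([[b.mean(0) for b in row] for row in trials])
    emp = np.transpose(emp, (2, 0, 1, 3))
    ct = geometry.ConditionTensor(trials=trials, mean=emp)
    # noise=None isolates the ridge term: with pure-noise data the
    # cross-validated mu must shrink the fit
    mu = geometry.select_regularization(ct, seed=1, noise=None)
    assert mu > 0


def test_projection_linearity_and_unit_axis():
    rng = np.random.default_rng(10)
    X = rng.normal(0, 1, (5, 8, 117))
    Y = rng.normal(0, 1, (5, 8, 117))
    ax = rng.normal(0, 1, 5)
    np.testing.assert_allclose(
        geometry.project(2 * X + 3 * Y, ax),
        2 * geometry.project(X, ax) + 3 * geometry.project(Y, ax), atol=1e-10)
    e2 = np.zeros(5)
    e2[2] = 1.0
    np.testing.assert_array_equal(geometry.project(X, e2), X[2])
    with pytest.raises(ValueError):
        geometry.project(X, np.ones(4))


def test_overlap_properties():
    u, v = np.array([1.0, 0.0]), np.array([1.0, 1.0])
    assert geometry.overlap(u, u) == pytest.approx(1.0)
    assert geometry.overlap(u, np.array([0.0, 1.0])) == pytest.approx(0.0)
    assert geometry.overlap(u, v) == pytest.approx(1 / np.sqrt(2))
    assert geometry.overlap(u, v) == geometry.overlap(v, u)
    assert geometry.overlap(u, 7.3 * v) == pytest.approx(geometry.overlap(u, v))
    with pytest.raises(ValueError):
        geometry.overlap(u, np.zeros(2))


def test_stimulus_axis_projection_monotone_in_mixture(recovery_bundle):
    ct = geometry.condition_tensor(recovery_bundle["tensor"].values,
                                   recovery_bundle["stim"],
                                   recovery_bundle["choice"])
    ct = geometry.impute_missing(ct)
    res = geometry.fit_dpca(ct, mu=0.0)
    axis = res.stimulus_axis
    cond = (ct.mean - res.neuron_means[:, None, None, None])
    proj = np.einsum("n,nsqt->sqt", axis, cond)
    samp = proj[:, :, 20:30].mean(axis=(1, 2))     # sampling window
    # ordered by mixture, with the dominant separation at the 50% boundary
    # (step units contribute categorically, linear units monotonically)
    rho = np.corrcoef(np.arange(8), samp)[0, 1]
    assert rho > 0.75
    assert samp[4:].mean() > samp[:4].mean()
    assert samp[7] > samp[0]
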