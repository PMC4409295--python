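import numpy as np
import pytest

import semiaft as sa
from semiaft.inference import (SolverOptions, _score_closures, default_tolerance,
                               omega_hat, solve_equation)

from conftest import toy_dataset


def test_solve_linear_equation_to_high_precision():
    opts = SolverOptions(tol=1e-8, xatol=1e-9, restarts=2, step=0.5)
    root, norm, conv, _ = solve_equation(lambda x: x - 1.0, np.array([0.0]), opts)
    assert conv and abs(root[0] - 1.0) < 1e-6


def test_solve_step_function_lands_in_crossing_interval():
    # score jumps from -1 to +1 somewhere in (0.8, 1.2): any point inside is a root
    def score(x):
        return np.array([-1.0 if x[0] < 0.8 else (1.0 if x[0] > 1.2 else 0.0)])

    opts = SolverOptions(tol=1e-3, step=0.5, jitter=1.0)
    root, norm, conv, _ = solve_equation(score, np.array([0.5]), opts)
    assert conv and 0.8 <= root[0] <= 1.2


def test_solver_respects_search_box():
    opts = SolverOptions(tol=1e-8, box_halfwidth=2.0, restarts=1)
    root, _, conv, _ = solve_equation(lambda x: x - 100.0, np.array([0.0]), opts)
    assert not conv and np.max(np.abs(root)) <= 2.0 + 1e-6


def test_fit_recovers_parameters_within_mc_error():
    """At n=400 the fitted coefficients sit close to the generating values
    (averaged over a few datasets to damp single-draw noise)."""
    fits = []
    for seed in (70, 71, 72):
        fr = sa.fit(sa.simulate_gamma_frailty(400, 0.0, seed=seed))
        assert fr.all_converged
        fits.append(fr.beta.stacked())
    mean = np.mean(fits, axis=0)
    # coordinate SDs at n=400 are ~0.2; mean of 3 has SD ~0.12
    np.testing.assert_allclose(mean, [1.0, 0.5, 0.5, 1.0, 0.5, 1.0], atol=0.45)


def test_fit_rejects_constant_covariate():
    ds = toy_dataset([0.1, 0.2, 0.3], [0.2, 0.3, 0.4], [1, 1, 1], [1, 1, 1],
                     [[1.0], [1.0], [1.0]])
    with pytest.raises(ValueError, match="non-identifiable"):
        sa.fit(ds)


def test_w1_rows_sum_to_scaled_score(frailty_ds):
    """Σ_i W_i^(1) = n^{1/2} S_n(η) is an algebraic identity at any η."""
    for eta in (np.array([0.0, 0.0]), np.array([1.0, 0.5]), np.array([-0.4, 1.3])):
        fr = sa.FitResult(eta, eta, eta, {}, {}, {}, 0.1)
        pw = sa.perturbation_weights(frailty_ds, fr)
        total = pw.W[:, :2].sum(axis=0)
        expect = np.sqrt(frailty_ds.n) * sa.score_eta(frailty_ds, eta).value
        np.testing.assert_allclose(total, expect, atol=1e-10)


def test_w2_w3_rows_sum_to_scaled_scores(frailty_ds, small_fit):
    pw = sa.perturbation_weights(frailty_ds, small_fit)
    n = frailty_ds.n
    np.testing.assert_allclose(pw.W[:, 2:4].sum(axis=0),
                               np.sqrt(n) * sa.score_theta_L(frailty_ds, small_fit.alpha_L).value,
                               atol=1e-10)
    # Σ_i W_i^(3) = (2/(n-1)) Σ_i Σ_j (Z_i - Z_j) φ_ij = n(n-1)/sqrt(n) * U_n^P / ... identity
    np.testing.assert_allclose(pw.W[:, 4:].sum(axis=0),
                               np.sqrt(n) * 2 * sa.score_theta_P(frailty_ds, small_fit.alpha_P).value,
                               atol=1e-10)


def test_w3_two_subject_symmetric_kernel():
    """(Z_i - Z_j) φ_ij is symmetric in (i, j), so both rows receive it."""
    ds = toy_dataset([1.0, 2.0], [5.0, 6.0], [1, 1], [1, 1], [[0.0], [1.0]])
    eta = np.array([0.0])
    fr = sa.FitResult(eta, eta, eta, {}, {}, {}, 0.1)
    pw = sa.perturbation_weights(ds, fr)
    w3 = pw.W[:, 2 * ds.k:]
    phi12 = 1  # subject 1 fails first, both events
    np.testing.assert_allclose(w3[0], 2 * (ds.Z[0] - ds.Z[1]) * phi12)
    np.testing.assert_allclose(w3[1], w3[0])


def test_omega_hat_matches_loop_and_is_psd():
    rng = np.random.default_rng(0)
    W = rng.normal(size=(40, 6))
    pw = sa.PerturbationWeights(W=W, k=2)
    om = omega_hat(pw)
    loop = sum(np.outer(w, w) for w in W) / 40
    np.testing.assert_allclose(om, loop, atol=1e-12)
    assert np.min(np.linalg.eigvalsh(om)) >= -1e-10


def test_resample_is_deterministic_in_seed(frailty_ds, small_fit):
    a = sa.resample(frailty_ds, small_fit, M=20, seed=7)
    b = sa.resample(frailty_ds, small_fit, M=20, seed=7)
    np.testing.assert_array_equal(a.draws, b.draws)
    np.testing.assert_array_equal(a.Q, b.Q)


def test_zero_perturbation_recovers_fit(frailty_ds, small_fit):
    """Solving the unperturbed system from the warm start returns beta-hat."""
    s_eta, s_L, s_P = _score_closures(frailty_ds)
    tol = default_tolerance(frailty_ds.n, frailty_ds.k)
    opts = SolverOptions(tol=tol, restarts=1, step=0.12, polish=False)
    eta_s, _, ok, _ = solve_equation(s_eta, small_fit.eta_hat, opts)
    assert ok and np.all(np.abs(eta_s - small_fit.eta_hat) < 0.1)
    tL, _, ok, _ = solve_equation(lambda x: s_L(eta_s, x), small_fit.theta_L_hat, opts)
    assert ok and np.all(np.abs(tL - small_fit.theta_L_hat) < 0.1)


def test_draws_center_near_point_estimate(small_fit, small_draws):
    center = small_draws.draws.mean(axis=0)
    spread = small_draws.draws.std(axis=0, ddof=1)
    beta_hat = small_fit.beta.stacked()
    assert np.all(np.abs(center - beta_hat) < 3 * spread / np.sqrt(small_draws.M_success) + 0.15)


def test_covariance_from_known_gaussian_draws():
    rng = np.random.default_rng(1)
    true = np.array([[1.0, 0.3, 0.0], [0.3, 2.0, -0.4], [0.0, -0.4, 0.5]])
    sample = rng.multivariate_normal(np.zeros(3), true, size=4000)
    dr = sa.ResamplingDraws(draws=sample, Q=np.zeros((4000, 1)), M_requested=4000,
                            M_success=4000, seed=0)
    cov = sa.covariance(dr)
    assert np.allclose(cov.sigma, cov.sigma.T)
    np.testing.assert_allclose(cov.sigma, true, atol=0.15)


def test_covariance_identical_draws_is_zero():
    dr = sa.ResamplingDraws(draws=np.ones((2, 3)), Q=np.zeros((2, 1)),
                            M_requested=2, M_success=2, seed=0)
    with pytest.warns(UserWarning):
        cov = sa.covariance(dr)
    assert np.allclose(cov.sigma, 0)


def test_standard_errors_from_diagonal():
    sigma = np.diag([4.0, 9.0, 1.0, 16.0, 25.0, 0.25])
    se = sa.standard_errors(sa.CovarianceEstimate(sigma=sigma, k=2))
    np.testing.assert_allclose(se["eta"], [2, 3])
    np.testing.assert_allclose(se["theta_L"], [1, 4])
    np.testing.assert_allclose(se["theta_P"], [5, 0.5])


def test_resampling_validity_against_replication_sd():
    """Draw SDs track the Monte-Carlo SDs of the estimators (moderate n)."""
    n, reps = 150, 400
    ests = np.empty((reps, 6))
    for r in range(reps):
        ds = sa.simulate_gamma_frailty(n, 0.0, seed=20000 + r)
        fr = sa.fit(ds)
        ests[r] = fr.beta.stacked()
    mc_sd = ests.std(axis=0, ddof=1)
    draw_sd = np.zeros(6)
    n_data = 10
    for s in range(n_data):
        ds = sa.simulate_gamma_frailty(n, 0.0, seed=30000 + s)
        fr = sa.fit(ds)
        dr = sa.resample(ds, fr, M=120, seed=s)
        draw_sd += dr.draws.std(axis=0, ddof=1) / n_data
    rel = np.abs(draw_sd - mc_sd) / mc_sd
    assert np.all(rel < 0.25), (draw_sd, mc_sd)
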