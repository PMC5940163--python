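"""Gibbs samplers for the five whole-genome regression priors."""

import numpy as np
import pytest

from cottongs.data_io import GenotypeMatrix
from cottongs.kinship import vanraden_grm
from cottongs.wgr import (FitResult, MCMCSettings, PriorSpec, build_kernel,
                          compute_dic, fit_wgr, nonnull_proportion,
                          predict_gebv)

FAST = MCMCSettings(6000, 1000, 5, seed=3)
TINY = MCMCSettings(1500, 300, 3, seed=3)


def _toy(rng, n=10, p=20, h2=0.6):
    X = rng.normal(size=(n, p))
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    b = rng.normal(size=p) * np.sqrt(h2 / p)
    y = X @ b + rng.normal(size=n) * np.sqrt(1 - h2)
    return X, y - y.mean()


def test_brr_fixed_variances_matches_ridge(rng):
    """With both variances fixed, BRR's posterior mean is the ridge solution."""
    X, y = _toy(rng)
    s2b, s2e = 0.05, 1.0
    prior = PriorSpec("BRR", fixed_sigma2_b=s2b, fixed_sigma2_e=s2e)
    fit = fit_wgr(y, X, prior, FAST)
    ridge = np.linalg.solve(X.T @ X + (s2e / s2b) * np.eye(X.shape[1]), X.T @ y)
    # Monte-Carlo tolerance: 3 x (analytic posterior SD) x sqrt(1/ESS),
    # with a conservative effective sample size of n_retained / 10
    post_sd = np.sqrt(np.diag(np.linalg.inv(X.T @ X / s2e + np.eye(X.shape[1]) / s2b)))
    tol = 3 * post_sd * np.sqrt(10 / FAST.n_retained)
    assert (np.abs(fit.b_hat - ridge) < tol).all()


def test_rkhs_linear_kernel_matches_gblup(rng):
    """RKHS with G as kernel and fixed variances equals GBLUP from the MME."""
    n = 10
    M = rng.binomial(2, 0.4, size=(n, 30)).astype(float)
    G = vanraden_grm(GenotypeMatrix([f"l{i}" for i in range(n)],
                                    [f"m{k}" for k in range(30)], M,
                                    np.zeros((n, 30), bool))).values
    y = rng.normal(size=n)
    s2u, s2e = 0.8, 0.5
    prior = PriorSpec("RKHS", kernel="linear_G", fixed_sigma2_b=s2u,
                      fixed_sigma2_e=s2e)
    fit = fit_wgr(y, np.zeros((n, 1)), prior, FAST, grm=G)
    V = s2u * G + s2e * np.eye(n)
    Vi = np.linalg.inv(V)
    one = np.ones(n)
    mu = (one @ Vi @ y) / (one @ Vi @ one)
    u_blup = s2u * G @ Vi @ (y - mu * one)
    post_sd = np.sqrt(np.maximum(np.diag(s2u * G - (s2u * G) @ Vi @ (s2u * G)), 1e-12))
    tol = 3 * post_sd * np.sqrt(10 / FAST.n_retained)
    assert (np.abs(fit.u_hat - u_blup) < tol + 1e-3).all()


def test_constant_y_degenerates_to_zero(rng):
    X, _ = _toy(rng, n=12)
    y = np.zeros(12)
    fit = fit_wgr(y, X, PriorSpec("BRR"), TINY)
    assert np.abs(fit.b_hat).max() < 0.05
    assert np.abs(fit.gebv).max() < 0.05
    assert fit.sigma2_e_hat < 0.05


def test_bayesb_ranks_true_qtl_top(rng):
    n, p = 150, 500
    X = rng.normal(size=(n, p))
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    qtl = np.array([10, 100, 250, 400, 490])
    b = np.zeros(p)
    b[qtl] = [1.0, -1.0, 0.8, -0.9, 1.1]
    y = X @ b + rng.normal(size=n) * 0.5
    fit = fit_wgr(y - y.mean(), X, PriorSpec("BayesB", pi0=0.05), FAST)
    top5 = set(np.argsort(fit.inclusion_prob)[-5:])
    assert top5 == set(qtl)


def test_nan_input_rejected(rng):
    X, y = _toy(rng)
    y = y.copy()
    y[0] = np.nan
    with pytest.raises(ValueError, match="NaN"):
        fit_wgr(y, X, PriorSpec("BRR"), TINY)


@pytest.mark.parametrize("chain,dmean,expect", [
    ([10.0, 12.0], 9.0, (13.0, 11.0, 2.0)),
    ([7.0, 7.0, 7.0], 7.0, (7.0, 7.0, 0.0)),
])
def test_dic_arithmetic(chain, dmean, expect):
    dic, d_bar, p_d = compute_dic(np.array(chain), dmean)
    assert (dic, d_bar, p_d) == pytest.approx(expect)


def test_dic_requires_draws():
    with pytest.raises(ValueError):
        compute_dic(np.array([1.0]), 1.0)


def test_nonnull_proportion_refuses_non_mixture(rng):
    X, y = _toy(rng)
    fit = fit_wgr(y, X, PriorSpec("BRR"), TINY)
    with pytest.raises(ValueError, match="BayesB or BayesC"):
        nonnull_proportion(fit)


def test_nonnull_proportion_is_pi_posterior_mean(rng):
    X, y = _toy(rng, n=30, p=40)
    fit = fit_wgr(y, X, PriorSpec("BayesC"), TINY)
    assert nonnull_proportion(fit) == pytest.approx(fit.chains["pi"].mean())
    assert 0.0 <= fit.inclusion_prob.min() <= fit.inclusion_prob.max() <= 1.0


def test_gaussian_kernel_properties(rng):
    X = rng.normal(size=(6, 10))
    X[1] = X[0]  # identical lines
    K = build_kernel(X, "gaussian", bandwidth=1.0)
    assert K[0, 1] == pytest.approx(1.0)
    assert np.allclose(K, K.T)
    K0 = build_kernel(X, "gaussian", bandwidth=1e-9)
    assert np.allclose(K0, 1.0, atol=1e-6)  # h -> 0 limit: all-ones


def test_predict_gebv_identity_and_centering(rng, small_single_site):
    _, X, y, _ = small_single_site
    fit = fit_wgr(y, X, PriorSpec("BayesC"), TINY)
    np.testing.assert_allclose(predict_gebv(fit, X), fit.gebv, atol=1e-10)
    zeros = np.zeros((3, X.n_markers))
    np.testing.assert_allclose(predict_gebv(fit, zeros), 0.0, atol=1e-12)
    dup = np.vstack([X.X[0], X.X[0]])
    pred = predict_gebv(fit, dup)
    assert pred[0] == pred[1]


def test_predict_gebv_marker_mismatch(rng, small_single_site):
    _, X, y, _ = small_single_site
    fit = fit_wgr(y, X, PriorSpec("BRR"), TINY)
    with pytest.raises(ValueError, match="marker"):
        predict_gebv(fit, np.zeros((2, X.n_markers + 1)))


def test_seeded_determinism(small_single_site):
    _, X, y, _ = small_single_site
    f1 = fit_wgr(y, X, PriorSpec("BayesB"), MCMCSettings(1000, 200, 2, seed=9))
    f2 = fit_wgr(y, X, PriorSpec("BayesB"), MCMCSettings(1000, 200, 2, seed=9))
    np.testing.assert_array_equal(f1.b_hat, f2.b_hat)
    np.testing.assert_array_equal(f1.chains["deviance"], f2.chains["deviance"])
    f3 = fit_wgr(y, X, PriorSpec("BayesB"), MCMCSettings(1000, 200, 2, seed=10))
    assert not np.array_equal(f1.b_hat, f3.b_hat)


def test_bayesb_with_pi_one_matches_bayesa(small_single_site):
    """Fixing the inclusion probability at ~1 collapses BayesB onto BayesA."""
    _, X, y, _ = small_single_site
    fa = fit_wgr(y, X, PriorSpec("BayesA"), FAST)
    fb = fit_wgr(y, X, PriorSpec("BayesB", fixed_pi=1.0 - 1e-9), FAST)
    resid = np.abs(fa.b_hat - fb.b_hat)
    assert resid.max() < 0.1
    assert np.corrcoef(fa.b_hat, fb.b_hat)[0, 1] > 0.95


def test_explained_variance_consistency(small_single_site):
    """1 - sigma2_e_hat on unit-variance y is the explained-variance share."""
    _, X, y, _ = small_single_site
    fit = fit_wgr(y, X, PriorSpec("BayesB"), TINY)
    explained = 1.0 - fit.sigma2_e_hat / np.var(y, ddof=1)
    assert 0.0 < explained < 1.0
    assert explained == pytest.approx(1.0 - fit.sigma2_e_hat, abs=1e-6)


@pytest.fixture(scope="module")
def recovery_sim():
    from cottongs.simulate import SimConfig, simulate_dataset
    cfg = SimConfig(n_lines=300, n_markers=1000, n_sites=1, n_families=30,
                    pi_nonnull=0.3, h2_target=0.5, var_site=0.0, seed=104)
    _, phen, truth = simulate_dataset(cfg)
    y = phen.records["mean"].to_numpy()
    y = (y - y.mean()) / y.std(ddof=1)
    return truth.X, y, truth


@pytest.mark.parametrize("model", ["BRR", "BayesA", "BayesB", "BayesC", "RKHS"])
def test_all_priors_recover_moderate_h2(model, recovery_sim):
    """Model-implied h2 lands within +/-0.12 of the simulated truth
    (n=300, p=1000, true h2 = 0.5) under every prior."""
    X, y, truth = recovery_sim
    prior = PriorSpec(model, kernel="gaussian")
    fit = fit_wgr(y, X, prior, FAST)
    assert abs(fit.h2_implied - truth.realized_h2[0]) <= 0.12
    assert np.corrcoef(fit.gebv, truth.tbv[:, 0])[0, 1] > 0.5
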