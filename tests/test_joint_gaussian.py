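"""Low-rank Gaussian conditioning: Woodbury vs dense oracles, calibration, imputation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mvflow.flow_tabular import build_tabular_flow
from mvflow.joint_gaussian import (
    DENSE_THRESHOLD,
    JointGaussian,
    condition,
    dense_covariance_memory_gb,
    fit_joint_gaussian,
    fit_latent_model,
    impute_views,
    latent_dimension,
    lowrank_log_prob,
    mahalanobis_full,
    sample_conditional,
)


def _random_model(rng, D, r, sigma2=None):
    U = np.linalg.qr(rng.standard_normal((D, r)))[0]
    lam = np.sort(rng.uniform(0.5, 4.0, r))[::-1]
    return JointGaussian(mean=rng.standard_normal(D), factors=U,
                         eigenvalues=lam,
                         sigma2=sigma2 if sigma2 is not None else rng.uniform(0.1, 1.0))


def _dense_condition(g, O, zO):
    S = g.dense_covariance()
    Uu = np.setdiff1d(np.arange(g.dim), O)
    A = np.linalg.solve(S[np.ix_(O, O)], zO - g.mean[O])
    mu = g.mean[Uu] + S[np.ix_(Uu, O)] @ A
    cov = S[np.ix_(Uu, Uu)] - S[np.ix_(Uu, O)] @ np.linalg.solve(
        S[np.ix_(O, O)], S[np.ix_(O, Uu)]
    )
    return mu, cov


def test_bivariate_closed_form_conditioning():
    # Sigma = [[1, .8], [.8, 1]] as rank-1 + isotropic: 1.6*uu' + 0.2 I
    u = np.array([[1.0], [1.0]]) / np.sqrt(2)
    g = JointGaussian(mean=np.zeros(2), factors=u, eigenvalues=np.array([1.6]),
                      sigma2=0.2)
    c = condition(g, [0], [1.0])
    assert c.mean[0] == pytest.approx(0.8, abs=1e-12)
    assert c.covariance_dense()[0, 0] == pytest.approx(0.36, abs=1e-12)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_woodbury_matches_dense_oracle(seed):
    rng = np.random.default_rng(seed)
    D = int(rng.integers(5, 50))
    r = int(rng.integers(1, min(D - 1, 8)))
    g = _random_model(rng, D, r)
    n_obs = int(rng.integers(1, D))
    O = rng.choice(D, size=n_obs, replace=False)
    zO = rng.standard_normal(n_obs)
    c = condition(g, O, zO)
    mu_d, cov_d = _dense_condition(g, O, zO)
    assert np.max(np.abs(c.mean - mu_d)) <= 1e-8
    assert np.max(np.abs(c.covariance_dense() - cov_d)) <= 1e-8
    # density and Mahalanobis against dense Cholesky
    z = rng.standard_normal(D)
    S = g.dense_covariance()
    lp_dense = stats.multivariate_normal(g.mean, S).logpdf(z)
    assert abs(lowrank_log_prob(g, z) - lp_dense) <= 1e-8
    d_dense = np.sqrt((z - g.mean) @ np.linalg.solve(S, z - g.mean))
    assert abs(mahalanobis_full(g, z) - d_dense) <= 1e-8


def test_zero_cross_covariance_collapses_to_prior_mean(rng):
    # factors supported only on the observed block: U rows for the unobserved
    # block are zero, so Sigma_UO = 0 and the conditional mean is mu_U
    U = np.zeros((6, 2))
    U[:3] = np.linalg.qr(rng.standard_normal((3, 2)))[0]
    g = JointGaussian(mean=rng.standard_normal(6), factors=U,
                      eigenvalues=np.array([2.0, 1.0]), sigma2=0.3)
    c = condition(g, [0, 1, 2], rng.standard_normal(3))
    assert np.allclose(c.mean, g.mean[3:], atol=1e-12)


def test_rank_zero_reduces_to_diagonal_gaussian(rng):
    g = JointGaussian(mean=np.zeros(4), factors=np.zeros((4, 0)),
                      eigenvalues=np.zeros(0), sigma2=0.5)
    z = rng.standard_normal(4)
    expected = stats.multivariate_normal(np.zeros(4), 0.5 * np.eye(4)).logpdf(z)
    assert lowrank_log_prob(g, z) == pytest.approx(expected, abs=1e-12)


def test_logdet_identity_for_orthonormal_factors(rng):
    g = _random_model(rng, 10, 3)
    from mvflow.joint_gaussian import _woodbury_quad_logdet

    _, logdet = _woodbury_quad_logdet(g, np.zeros((1, 10)))
    expected = np.sum(np.log(g.eigenvalues + g.sigma2)) + 7 * np.log(g.sigma2)
    assert logdet == pytest.approx(expected, abs=1e-10)


def test_mahalanobis_euclidean_reduction():
    g = JointGaussian(mean=np.zeros(5), factors=np.zeros((5, 0)),
                      eigenvalues=np.zeros(0), sigma2=1.0)
    z = np.array([3.0, 4.0, 0.0, 0.0, 0.0])
    assert mahalanobis_full(g, z) == pytest.approx(5.0)
    assert mahalanobis_full(g, g.mean) == pytest.approx(0.0)


class TestFit:
    def test_planted_low_rank_model_recovered(self):
        rng = np.random.default_rng(1)
        D, r, n = 20, 3, 5000
        U = np.linalg.qr(rng.standard_normal((D, r)))[0]
        lam_true = np.array([6.0, 4.0, 2.0])
        L = U * np.sqrt(lam_true)
        z = rng.standard_normal((n, r)) @ L.T + np.sqrt(0.1) * rng.standard_normal((n, D))
        g = fit_joint_gaussian(z, rank=r)
        # fitted eigenvalues approximate lam + sigma^2
        assert np.all(np.abs(g.eigenvalues - (lam_true + 0.1)) / (lam_true + 0.1) < 0.10)
        from scipy.linalg import subspace_angles

        assert np.degrees(subspace_angles(g.factors, U)).max() <= 10.0

    def test_isotropic_data_has_flat_spectrum(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal((5000, 10))
        g = fit_joint_gaussian(z, rank=2)
        assert np.all(g.eigenvalues / g.sigma2 <= 1.5)

    def test_two_identical_rows_degenerate(self):
        row = np.array([1.0, 2.0, 3.0])
        g = fit_joint_gaussian(np.stack([row, row]), rank=1)
        assert np.allclose(g.mean, row)
        assert g.sigma2 == pytest.approx(1e-8)

    def test_rank_bounds_enforced(self, rng):
        z = rng.standard_normal((5, 10))
        with pytest.raises(ValueError):
            fit_joint_gaussian(z, rank=5)


class TestConditionErrors:
    def test_observing_everything_rejected(self, rng):
        g = _random_model(rng, 5, 2)
        with pytest.raises(ValueError):
            condition(g, np.arange(5), rng.standard_normal(5))

    def test_empty_observation_rejected(self, rng):
        g = _random_model(rng, 5, 2)
        with pytest.raises(ValueError):
            condition(g, [], [])

    def test_non_finite_observation_rejected(self, rng):
        g = _random_model(rng, 5, 2)
        with pytest.raises(ValueError):
            condition(g, [0], [np.nan])


class TestSampling:
    def test_monte_carlo_matches_closed_form_bivariate(self):
        u = np.array([[1.0], [1.0]]) / np.sqrt(2)
        g = JointGaussian(np.zeros(2), u, np.array([1.6]), 0.2)
        c = condition(g, [0], [1.0])
        draws = sample_conditional(c, 100_000, seed=0)
        assert draws.mean() == pytest.approx(0.8, abs=0.01)
        assert draws.var() == pytest.approx(0.36, abs=0.01)

    def test_seed_determinism(self, rng):
        g = _random_model(rng, 8, 2)
        c = condition(g, [0, 1], rng.standard_normal(2))
        assert np.array_equal(sample_conditional(c, 10, seed=5),
                              sample_conditional(c, 10, seed=5))

    def test_vanishing_residual_collapses_to_conditional_mean(self, rng):
        g = _random_model(rng, 6, 2, sigma2=1e-10)
        c = condition(g, [0, 1, 2], rng.standard_normal(3))
        draws = sample_conditional(c, 200, seed=1)
        assert np.max(draws.var(axis=0)) <= 1e-6

    def test_nonpositive_n_rejected(self, rng):
        g = _random_model(rng, 6, 2)
        c = condition(g, [0], [0.5])
        with pytest.raises(ValueError):
            sample_conditional(c, 0)


def test_conditional_calibration_chi2():
    """Data drawn from the fitted Gaussian: standardized imputation residuals
    follow the exact conditional, so their chi^2 statistics match the
    reference distribution (KS test)."""
    rng = np.random.default_rng(3)
    D, r, n = 10, 3, 2000
    g = _random_model(rng, D, r)
    S = g.dense_covariance()
    L = np.linalg.cholesky(S)
    z = g.mean + rng.standard_normal((n, D)) @ L.T
    O = np.arange(4)
    Uu = np.arange(4, D)
    stats_chi2 = []
    c0 = condition(g, O, z[0, O])
    cov_chol = np.linalg.cholesky(c0.covariance_dense())
    for i in range(n):
        c = condition(g, O, z[i, O])
        resid = np.linalg.solve(cov_chol, z[i, Uu] - c.mean)
        stats_chi2.append(resid @ resid)
    ks = stats.kstest(stats_chi2, stats.chi2(len(Uu)).cdf)
    assert ks.pvalue > 0.01


def test_memory_guard_blocks_dense_materialization(rng):
    D = DENSE_THRESHOLD + 10
    g = JointGaussian(mean=np.zeros(D), factors=np.zeros((D, 1)),
                      eigenvalues=np.array([1.0]), sigma2=1.0)
    with pytest.raises(MemoryError):
        g.dense_covariance()


def test_large_dimension_operations_avoid_dense_paths(rng):
    # operations succeed above the dense threshold because nothing D x D is formed
    n, D, r = 60, DENSE_THRESHOLD + 200, 4
    z = rng.standard_normal((n, D))
    g = fit_joint_gaussian(z, rank=r)
    lp = lowrank_log_prob(g, z[0])
    assert np.isfinite(lp)
    c = condition(g, np.arange(100), z[0, :100])
    assert c.mean.shape == (D - 100,)
    assert np.isfinite(mahalanobis_full(g, z[1]))


def test_memory_accounting_of_dense_covariance():
    d = latent_dimension((64, 64, 64))
    assert d == 262_144
    assert dense_covariance_memory_gb(d) > 500.0


class TestImputation:
    def test_same_view_as_source_and_target_rejected(self, rng):
        flows = {"a": build_tabular_flow(3, 2, 8, seed=0),
                 "b": build_tabular_flow(3, 2, 8, seed=1)}
        data = {"a": rng.standard_normal((20, 3)), "b": rng.standard_normal((20, 3))}
        g = fit_latent_model(flows, data, rank=2)
        with pytest.raises(ValueError, match="disjoint"):
            impute_views(flows, g, {"a": data["a"]}, ["a"])

    def test_missing_target_flow_rejected(self, rng):
        flows = {"a": build_tabular_flow(3, 2, 8, seed=0),
                 "b": build_tabular_flow(3, 2, 8, seed=1)}
        data = {"a": rng.standard_normal((20, 3)), "b": rng.standard_normal((20, 3))}
        g = fit_latent_model(flows, data, rank=2)
        with pytest.raises(KeyError):
            impute_views(flows, g, {"a": data["a"]}, ["c"])

    def test_identity_flows_reduce_to_gaussian_regression(self, rng):
        # with identity (fresh) flows, imputation is plain Gaussian conditioning
        n = 400
        s = rng.standard_normal((n, 2))
        a = s + 0.05 * rng.standard_normal((n, 2))
        b = s @ np.array([[1.0, -1.0], [0.5, 2.0]]) + 0.05 * rng.standard_normal((n, 2))
        flows = {"a": build_tabular_flow(2, 1, 4, seed=0),
                 "b": build_tabular_flow(2, 1, 4, seed=1)}
        g = fit_latent_model(flows, {"a": a, "b": b}, rank=3)
        rec = impute_views(flows, g, {"a": a[:50]}, ["b"])["b"]
        for j in range(2):
            assert np.corrcoef(rec[:, j], b[:50, j])[0, 1] >= 0.9
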