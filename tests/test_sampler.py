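import numpy as np
import pandas as pd
import pytest
from scipy import stats

from geowaz.design import ModelSpec, SmoothSpec, assemble_design, build_difference_penalty
from geowaz.sampler import (
    HyperPriors,
    MCMCConfig,
    run_gibbs,
    sample_coefficient_block,
    sample_error_variance,
    sample_smoothing_variance,
)
from geowaz.simulate import tiny_scenario, simulate

from conftest import batch_means_se, full_model_spec


class TestCoefficientBlock:
    def test_no_penalty_identity_design(self):
        """K=0, B=I, sigma2=1: the full conditional is N(y_partial, I)."""
        rng = np.random.default_rng(0)
        y = np.array([1.0, -2.0, 0.5])
        draws = np.array([
            sample_coefficient_block(y, np.eye(3), np.zeros((3, 3)), 1.0, 1.0, rng)
            for _ in range(20000)
        ])
        np.testing.assert_allclose(draws.mean(axis=0), y, atol=4 * 1.0 / np.sqrt(20000))
        np.testing.assert_allclose(np.cov(draws.T), np.eye(3), atol=0.05)

    def test_large_tau_limit_is_least_squares(self):
        """As tau2 -> inf the conditional mean approaches the OLS fit."""
        rng = np.random.default_rng(1)
        B = rng.standard_normal((40, 4))
        y = rng.standard_normal(40)
        K = build_difference_penalty(4, 2)
        draws = np.array([
            sample_coefficient_block(y, B, K, 1e12, 1e-6, rng) for _ in range(200)
        ])
        ols, *_ = np.linalg.lstsq(B, y, rcond=None)
        np.testing.assert_allclose(draws.mean(axis=0), ols, atol=1e-2)

    def test_moments_match_dense_oracle(self):
        """5x5 block: sample moments vs an independent dense-matrix (mu, Sigma)."""
        rng = np.random.default_rng(2)
        B = rng.standard_normal((30, 5))
        y = rng.standard_normal(30)
        K = build_difference_penalty(5, 2)
        tau2, sigma2 = 0.7, 1.3
        N = 50000
        gen = np.random.default_rng(3)
        draws = np.array([
            sample_coefficient_block(y, B, K, tau2, sigma2, gen) for _ in range(N)
        ])
        prec = B.T @ B / sigma2 + K / tau2
        Sigma = np.linalg.inv(prec)
        mu = Sigma @ (B.T @ y) / sigma2
        se_mean = np.sqrt(np.diag(Sigma) / N)
        assert np.all(np.abs(draws.mean(axis=0) - mu) < 4 * se_mean)
        S = np.cov(draws.T)
        se_cov = np.sqrt((np.outer(np.diag(Sigma), np.diag(Sigma)) + Sigma**2) / N)
        assert np.all(np.abs(S - Sigma) < 4 * se_cov)

    def test_invalid_variances_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            sample_coefficient_block(np.ones(3), np.eye(3), np.zeros((3, 3)), 0.0, 1.0, rng)


class TestVarianceConditionals:
    def test_null_space_beta_returns_prior_scale(self):
        """beta in the penalty null space: IG(a + rank/2, b) exactly."""
        K = build_difference_penalty(6, 2)
        beta = 2.0 + 0.3 * np.arange(6.0)  # affine -> zero quadratic form
        a, b = 1.5, 2.0
        rng = np.random.default_rng(4)
        draws = np.array([
            sample_smoothing_variance(beta, K, a, b, rng, rank=4) for _ in range(50000)
        ])
        target = stats.invgamma(a + 2.0, scale=b)  # a + rank/2 = a + 2
        assert draws.mean() == pytest.approx(target.mean(), rel=0.03)
        ks = stats.kstest(draws[:10000], target.cdf)
        assert ks.pvalue > 0.01

    def test_moments_match_closed_form(self):
        rng = np.random.default_rng(5)
        K = build_difference_penalty(8, 2)
        beta = rng.standard_normal(8)
        a, b = 0.8, 0.9
        quad = beta @ K @ beta
        shape = a + 6 / 2.0
        scale = b + quad / 2.0
        N = 100000
        draws = np.array([
            sample_smoothing_variance(beta, K, a, b, rng, rank=6) for _ in range(N)
        ])
        mean = scale / (shape - 1)
        sd = mean / np.sqrt(shape - 2)
        assert abs(draws.mean() - mean) < 3 * sd / np.sqrt(N)

    def test_zero_rank_returns_prior(self):
        rng = np.random.default_rng(6)
        draws = np.array([
            sample_smoothing_variance(np.zeros(3), np.zeros((3, 3)), 2.0, 3.0, rng, rank=0)
            for _ in range(50000)
        ])
        prior = stats.invgamma(2.0, scale=3.0)
        assert draws.mean() == pytest.approx(prior.mean(), rel=0.03)

    def test_error_variance_conjugate_update(self):
        """Posterior concentrates at the residual scale (here ~1.35)."""
        rng = np.random.default_rng(7)
        true = 1.3511
        resid = rng.normal(0.0, np.sqrt(true), size=1000)
        a, b = 0.001, 0.001
        draws = np.array([sample_error_variance(resid, a, b, rng) for _ in range(10000)])
        shape = a + 500.0
        scale = b + float(resid @ resid) / 2.0
        post = stats.invgamma(shape, scale=scale)
        assert abs(draws.mean() - true) < 3 * post.std()
        ks = stats.kstest(draws, post.cdf)
        assert ks.pvalue > 0.01

    def test_zero_residuals(self):
        rng = np.random.default_rng(8)
        draws = np.array([sample_error_variance(np.zeros(50), 2.0, 3.0, rng) for _ in range(50000)])
        prior = stats.invgamma(2.0 + 25.0, scale=3.0)
        assert draws.mean() == pytest.approx(prior.mean(), rel=0.03)


class TestGibbs:
    def test_fixed_effects_only_matches_conjugate_posterior(self):
        """No penalized terms: Gibbs must reproduce the normal-inverse-gamma
        posterior (flat prior on gamma) within Monte-Carlo error."""
        rng = np.random.default_rng(9)
        n, q = 300, 4
        W = np.column_stack([np.ones(n), rng.standard_normal((n, q - 1))])
        gamma_true = np.array([0.5, -1.0, 0.3, 0.8])
        y = W @ gamma_true + rng.normal(0, 1.2, n)
        from geowaz.design import DesignBlocks

        design = DesignBlocks(
            y=y, fixed=W, fixed_names=("intercept", "z1", "z2", "z3"),
            smooths=(), spatial=None, region_index=None,
        )
        priors = HyperPriors(a_sigma=2.0, b_sigma=2.0)
        samples = run_gibbs(design, priors, MCMCConfig(iterations=21000, burnin=1000, thin=1, seed=10))
        gamma_hat, *_ = np.linalg.lstsq(W, y, rcond=None)
        rss = float(np.sum((y - W @ gamma_hat) ** 2))
        shape = priors.a_sigma + (n - q) / 2.0
        scale = priors.b_sigma + rss / 2.0
        exp_sigma2 = scale / (shape - 1)
        cov_gamma = exp_sigma2 * np.linalg.inv(W.T @ W)
        for k in range(q):
            se = batch_means_se(samples.gamma[:, k])
            assert abs(samples.gamma[:, k].mean() - gamma_hat[k]) < 3 * se
        emp_cov = np.cov(samples.gamma.T)
        for k in range(q):
            prods = (samples.gamma[:, k] - samples.gamma[:, k].mean()) ** 2
            se = batch_means_se(prods)
            assert abs(emp_cov[k, k] - cov_gamma[k, k]) < 3 * se
        se_s = batch_means_se(samples.sigma2)
        assert abs(samples.sigma2.mean() - exp_sigma2) < 3 * se_s

    def test_determinism_same_seed(self, tiny_fit):
        scen, data, truth, design, samples = tiny_fit
        again = run_gibbs(
            design, HyperPriors(), MCMCConfig(iterations=600, burnin=100, thin=1, seed=4)
        )
        np.testing.assert_array_equal(samples.gamma, again.gamma)
        np.testing.assert_array_equal(samples.sigma2, again.sigma2)
        for b1, b2 in zip(samples.betas, again.betas):
            np.testing.assert_array_equal(b1, b2)

    def test_retained_draw_count_and_positive_variances(self, tiny_fit):
        *_, samples = tiny_fit
        assert samples.n_draws == (600 - 100) // 1
        assert (samples.sigma2 > 0).all()
        for chain in samples.tau2.values():
            assert (chain > 0).all()

    def test_centering_per_draw(self, recovery_fit):
        """Every retained smooth/spatial block has coefficient mean ~0."""
        *_, samples = recovery_fit
        for beta in samples.betas:
            assert np.max(np.abs(beta.mean(axis=1))) < 1e-10
        assert np.max(np.abs(samples.f_spat.mean(axis=1))) < 1e-10

    def test_spatial_recovery_correlation(self, recovery_fit):
        scen, data, truth, design, samples = recovery_fit
        est = samples.f_spat.mean(axis=0)
        assert np.corrcoef(est, truth.f_spat)[0, 1] > 0.8

    def test_smooth_recovery_rmse(self, recovery_fit):
        scen, data, truth, design, samples = recovery_fit
        resp_sd = data["waz"].std()
        for cov in samples.smooth_labels:
            x = data[cov].to_numpy()
            draws = samples.smooth_draws(design, cov, x)
            draws = draws - draws.mean(axis=1, keepdims=True)
            f_true = truth.truth_functions[cov](x)
            f_true = f_true - f_true.mean()
            rmse = np.sqrt(np.mean((draws.mean(axis=0) - f_true) ** 2))
            assert rmse < 0.15 * resp_sd
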