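"""Conditional samplers, the full Gibbs cycle, and chain diagnostics."""

import numpy as np
import pytest

from tvpvarsv import (
    MCMCConfig,
    ModelSpec,
    PriorConfig,
    StatePaths,
    diagnose,
    run_mcmc,
    sample_alpha,
    sample_beta,
    sample_h,
    sample_variances,
)
from tvpvarsv.core import build_design
from tvpvarsv.mcmc import (
    OMORI_MEANS,
    OMORI_PROBS,
    geweke_cd,
    inefficiency_factor,
    sample_log_chi2_mixture,
)

from conftest import constant_parameter_panel, dense_rw_smoother_mean

PRIOR = PriorConfig()


def _small_problem(seed=0, T=31, m=2):
    spec, adjusted, truth = constant_parameter_panel(seed, T=T)
    X = build_design(adjusted.values, spec)
    y = adjusted.values[1:]
    n = T - 1
    return spec, X, y, n


class TestSampleBeta:
    def test_tiny_innovation_variance_freezes_the_path(self):
        spec, X, y, n = _small_problem(T=100)
        rng = np.random.default_rng(0)
        path = sample_beta(y, X, np.zeros((n, 1)), np.zeros((n, 2)),
                           np.full(4, 1e-12), PRIOR, rng)
        assert np.abs(path - path[0]).max() < 1e-3

    def test_smoother_mean_matches_dense_gaussian_oracle(self):
        spec, X, y, n = _small_problem(T=30)
        rng = np.random.default_rng(1)
        alpha_path = 0.1 * rng.standard_normal((n, 1))
        h_path = 0.2 * rng.standard_normal((n, 2))
        v_beta = np.array([0.01, 0.02, 0.015, 0.03])
        mean = sample_beta(y, X, alpha_path, h_path, v_beta, PRIOR,
                           rng=None, sample=False)
        from tvpvarsv.mcmc import _obs_covariances

        H = _obs_covariances(alpha_path, h_path, 2)
        oracle = dense_rw_smoother_mean(y, X, H, v_beta,
                                        np.zeros(4), np.full(4, 10.0))
        assert np.abs(mean - oracle).max() < 1e-8

    def test_draw_average_converges_to_smoother_mean(self):
        spec, X, y, n = _small_problem(T=30)
        alpha_path = np.zeros((n, 1))
        h_path = np.zeros((n, 2))
        v_beta = np.full(4, 0.02)
        mean = sample_beta(y, X, alpha_path, h_path, v_beta, PRIOR,
                           rng=None, sample=False)
        rng = np.random.default_rng(2)
        R = 6000
        acc = np.zeros_like(mean)
        acc2 = np.zeros_like(mean)
        for _ in range(R):
            d = sample_beta(y, X, alpha_path, h_path, v_beta, PRIOR, rng)
            acc += d
            acc2 += d * d
        mc_mean = acc / R
        mc_se = np.sqrt((acc2 / R - mc_mean**2) / R)
        assert np.all(np.abs(mc_mean - mean) < 3.5 * mc_se + 1e-12)


class TestSampleAlpha:
    def test_univariate_model_yields_empty_path(self):
        y = np.random.default_rng(0).standard_normal((50, 1))
        X = y[:-1].reshape(49, 1, 1)
        out = sample_alpha(y[1:], X, np.zeros((49, 1)), np.zeros((49, 1)),
                           np.empty(0), PRIOR, np.random.default_rng(1))
        assert out.shape == (49, 0)

    def test_smoother_mean_matches_dense_gaussian_oracle(self):
        rng = np.random.default_rng(3)
        n, m = 30, 3
        y = rng.standard_normal((n, m))
        X = np.zeros((n, m, m))  # beta contributes nothing
        beta_path = np.zeros((n, m))
        h_path = 0.1 * rng.standard_normal((n, m))
        v_alpha = np.array([0.01, 0.02, 0.03])
        mean = sample_alpha(y, X, beta_path, h_path, v_alpha, PRIOR,
                            rng=None, sample=False)
        from tvpvarsv.mcmc import _alpha_design

        Z = _alpha_design(y, m)
        oracle = dense_rw_smoother_mean(y, Z, np.exp(h_path), v_alpha,
                                        np.zeros(3), np.full(3, 10.0))
        assert np.abs(mean - oracle).max() < 1e-8

    def test_recovers_constant_contemporaneous_relations(self):
        # data generated with fixed alpha = (0.8, 0.3, -0.5), no lag signal
        rng = np.random.default_rng(4)
        n, m = 500, 3
        alpha_true = np.array([0.8, 0.3, -0.5])
        from tvpvarsv.core import alpha_to_A

        A = alpha_to_A(alpha_true, m)
        eps = rng.standard_normal((n, m))
        y = np.linalg.solve(A, eps.T).T
        X = np.zeros((n, m, 1))
        beta_path = np.zeros((n, 1))
        h_path = np.zeros((n, m))
        draws = np.mean(
            [sample_alpha(y, X, beta_path, h_path, np.full(3, 1e-8), PRIOR, rng)
             for _ in range(200)],
            axis=0,
        )
        assert np.abs(draws.mean(axis=0) - alpha_true).max() < 0.1


class TestSampleH:
    def test_mixture_mean_is_log_chi2_mean(self):
        rng = np.random.default_rng(5)
        draws = sample_log_chi2_mixture(200_000, rng)
        assert abs(draws.mean() + 1.2704) < 0.03
        assert abs((OMORI_PROBS * OMORI_MEANS).sum() + 1.2704) < 1e-3

    def test_recovers_constant_zero_log_variance(self):
        rng = np.random.default_rng(6)
        n = 1000
        y = rng.standard_normal((n, 1))  # true h = 0
        X = np.zeros((n, 1, 1))
        beta_path = np.zeros((n, 1))
        h = np.zeros((n, 1))
        acc = np.zeros((n, 1))
        for _ in range(300):
            h = sample_h(y, X, beta_path, np.zeros((n, 0)), np.array([1e-6]),
                         PRIOR, rng, h_current=h)
            acc += h
        assert np.abs(acc / 300).max() < 0.25


class TestSampleVariances:
    def test_zero_increment_closed_form(self):
        n = 101
        paths = StatePaths(np.zeros((n, 2)), np.zeros((n, 1)), np.zeros((n, 1)))
        rng = np.random.default_rng(7)
        draws = np.array([sample_variances(paths, PRIOR, rng).v_beta
                          for _ in range(30_000)])
        # precision ~ Gamma(40 + 50, 0.02): E[1/v] = 90 / 0.02 = 4500
        prec = 1.0 / draws
        shape_post = PRIOR.gamma_beta_shape + (n - 1) / 2  # 90
        expected = shape_post / PRIOR.gamma_beta_rate      # 4500
        se = np.sqrt(shape_post) / PRIOR.gamma_beta_rate / np.sqrt(prec.size)
        assert abs(prec.mean() - expected) < 4 * se

    def test_scaling_increments_by_two_quarters_the_precision(self):
        rng = np.random.default_rng(8)
        walk = np.cumsum(rng.standard_normal((4000, 1)), axis=0)
        def post_mean_precision(path):
            r = np.random.default_rng(9)
            paths = StatePaths(path, np.zeros((path.shape[0], 0)),
                               np.zeros((path.shape[0], 1)))
            return np.mean([1.0 / sample_variances(paths, PRIOR, r).v_beta
                            for _ in range(400)])
        ratio = post_mean_precision(2.0 * walk) / post_mean_precision(walk)
        assert ratio == pytest.approx(0.25, abs=0.02)

    def test_short_path_rejected(self):
        paths = StatePaths(np.zeros((1, 2)), np.zeros((1, 1)), np.zeros((1, 1)))
        with pytest.raises(ValueError):
            sample_variances(paths, PRIOR, np.random.default_rng(0))


class TestRunMcmc:
    def test_retained_draw_bookkeeping(self):
        assert MCMCConfig(n_draws=10_000, burn_in=1_000).n_retained == 9_000
        assert MCMCConfig(n_draws=100, burn_in=20, thin=3).n_retained == 27
        with pytest.raises(ValueError):
            MCMCConfig(n_draws=100, burn_in=100)

    def test_same_seed_reproduces_retained_draws(self):
        spec, adjusted, _ = constant_parameter_panel(seed=10, T=60)
        cfg = MCMCConfig(n_draws=40, burn_in=10, seed=5)
        a = run_mcmc(adjusted, spec, config=cfg)
        b = run_mcmc(adjusted, spec, config=cfg)
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.h, b.h)
        np.testing.assert_array_equal(a.v_beta, b.v_beta)

    def test_all_sampled_variances_strictly_positive(self):
        spec, adjusted, _ = constant_parameter_panel(seed=11, T=60)
        draws = run_mcmc(adjusted, spec,
                         config=MCMCConfig(n_draws=50, burn_in=10, seed=1))
        assert draws.n_retained == 40
        assert (draws.v_beta > 0).all() and (draws.v_alpha > 0).all() \
            and (draws.v_h > 0).all()

    def test_save_load_round_trip(self, tmp_path):
        spec, adjusted, _ = constant_parameter_panel(seed=12, T=40)
        draws = run_mcmc(adjusted, spec,
                         config=MCMCConfig(n_draws=20, burn_in=5, seed=2))
        draws.save(tmp_path / "d")
        from tvpvarsv import PosteriorDraws

        again = PosteriorDraws.load(tmp_path / "d")
        np.testing.assert_allclose(again.beta, draws.beta, rtol=1e-10)
        assert again.config == draws.config
        assert again.spec == draws.spec


class TestDiagnostics:
    def test_geweke_cd_is_standard_normal_for_iid_chains(self):
        rng = np.random.default_rng(13)
        repeats = 400
        inside = sum(abs(geweke_cd(rng.standard_normal(1500))) < 1.96
                     for _ in range(repeats))
        assert inside / repeats >= 0.93

    def test_inefficiency_factor_is_one_for_white_noise(self):
        rng = np.random.default_rng(14)
        chain = rng.standard_normal(20_000)
        assert inefficiency_factor(chain) == pytest.approx(1.0, abs=0.2)

    def test_inefficiency_factor_grows_for_persistent_chains(self):
        rng = np.random.default_rng(15)
        e = rng.standard_normal(20_000)
        ar = np.empty_like(e)
        ar[0] = e[0]
        for t in range(1, e.size):
            ar[t] = 0.9 * ar[t - 1] + e[t]
        # theoretical IF for AR(0.9) = (1+rho)/(1-rho) = 19
        assert inefficiency_factor(ar) > 5.0

    def test_constant_chain_has_unit_acf_everywhere(self):
        diag = diagnose({"c": np.full(1200, 3.0)}, acf_lags=500)
        assert np.all(diag.scalars["c"].acf == 1.0)

    def test_acf_starts_at_one_and_if_bounds(self):
        rng = np.random.default_rng(16)
        diag = diagnose({"x": rng.standard_normal(1200)}, acf_lags=300)
        s = diag.scalars["x"]
        assert s.acf[0] == 1.0
        assert s.inefficiency_factor > 0.5

    def test_window_and_length_validation(self):
        rng = np.random.default_rng(17)
        with pytest.raises(ValueError, match="at least 100"):
            diagnose({"x": rng.standard_normal(50)}, acf_lags=10)
        with pytest.raises(ValueError, match="shorter than ACF window"):
            diagnose({"x": rng.standard_normal(200)}, acf_lags=500)

    def test_default_monitored_covers_each_block(self):
        spec, adjusted, _ = constant_parameter_panel(seed=18, T=60)
        draws = run_mcmc(adjusted, spec,
                         config=MCMCConfig(n_draws=160, burn_in=20, seed=3))
        diag = diagnose(draws, acf_lags=100)
        assert {"beta_mid_1", "alpha_mid_1", "h_mid_1",
                "sd_beta_1", "sd_alpha_1", "sd_h_1"} <= set(diag.scalars)
        summary = diag.summary()
        assert len(summary) == 6
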