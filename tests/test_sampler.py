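"""Sampler blocks: Gibbs mean update, MH kernel, correlation step, sweeps."""

import numpy as np
import pytest
from scipy import stats

import hoirt
from hoirt.errors import ConfigurationError, ParameterError
from hoirt.priors import MCMCConfig, PriorConfig
from hoirt.sampler import (draw_mu, draw_rho_omega, mh_update_block,
                           run_chains)


class TestDrawMu:
    def test_no_data_returns_prior(self):
        priors = PriorConfig()
        rng = np.random.default_rng(0)
        draws = np.array([draw_mu(np.zeros(2), 0, np.eye(2), priors, rng)
                          for _ in range(20000)])
        L0 = priors.mu_prior_cov(2)
        assert np.allclose(draws.mean(axis=0), 0, atol=3 * np.sqrt(1 / 20000) * 1.1)
        assert np.allclose(np.cov(draws.T), L0, atol=0.05)

    def test_large_n_concentrates_at_sample_mean(self):
        priors = PriorConfig()
        rng = np.random.default_rng(1)
        tb = np.array([0.7, -1.2])
        draws = np.array([draw_mu(tb, 10 ** 7, np.eye(2), priors, rng)
                          for _ in range(200)])
        assert np.allclose(draws.mean(axis=0), tb, atol=0.01)
        assert draws.std(axis=0).max() < 0.01

    def test_moments_match_closed_form(self):
        # D=2 toy: sampling moments vs mu1/Sigma1 within 3 Monte-Carlo SEs
        priors = PriorConfig()
        rng = np.random.default_rng(2)
        tb = np.array([0.5, -0.3])
        N, Sigma = 40, np.array([[1.0, 0.3], [0.3, 2.0]])
        L0inv = np.linalg.inv(priors.mu_prior_cov(2))
        Sinv = np.linalg.inv(Sigma)
        Sigma1 = np.linalg.inv(L0inv + N * Sinv)
        mu1 = Sigma1 @ (N * Sinv @ tb)
        n = 10 ** 5
        draws = np.array([draw_mu(tb, N, Sigma, priors, rng)
                          for _ in range(n)])
        se_mean = np.sqrt(np.diag(Sigma1) / n)
        assert np.all(np.abs(draws.mean(axis=0) - mu1) < 3 * se_mean)
        cov = np.cov(draws.T)
        se_var = np.diag(Sigma1) * np.sqrt(2 / (n - 1))
        assert np.all(np.abs(np.diag(cov) - np.diag(Sigma1)) < 3 * se_var)

    def test_singular_covariance_raises(self):
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            draw_mu(np.zeros(2), 5, np.zeros((2, 2)), PriorConfig(),
                    np.random.default_rng(0))


class TestMHUpdateBlock:
    def test_zero_scale_always_accepts_unchanged(self):
        rng = np.random.default_rng(0)
        x = np.array([1.0, -2.0])
        new, acc = mh_update_block(x, lambda v: 0.0, 0.0, rng)
        assert acc and np.array_equal(new, x)

    def test_recovers_standard_normal_target(self):
        rng = np.random.default_rng(3)
        x = np.array(0.0)
        samples = []
        for _ in range(40000):
            x, _ = mh_update_block(x, lambda v: -0.5 * float(v) ** 2, 2.4, rng)
            samples.append(float(x))
        s = np.array(samples[2000:])
        ess = hoirt.effective_sample_size(s)
        assert abs(s.mean()) < 3 / np.sqrt(ess)
        assert abs(s.var() - 1) < 3 * np.sqrt(2 / ess)

    def test_zero_density_region_always_rejected(self):
        rng = np.random.default_rng(4)
        target = lambda v: 0.0 if abs(float(v)) < 1e-9 else -np.inf
        for _ in range(50):
            new, acc = mh_update_block(np.array(0.0), target, 5.0, rng)
            assert not acc and new == 0.0

    def test_nonfinite_current_state_is_an_error(self):
        with pytest.raises(ParameterError):
            mh_update_block(np.array(0.0), lambda v: -np.inf, 1.0,
                            np.random.default_rng(0))


class TestDrawRhoOmega:
    def test_univariate_is_identity(self):
        rho, acc, prop = draw_rho_omega(
            np.random.default_rng(0).normal(size=(50, 1)),
            PriorConfig(), np.ones((1, 1)), np.random.default_rng(1))
        assert rho.shape == (1, 1) and rho[0, 0] == 1.0 and prop == 0

    def test_recovers_true_correlation(self):
        # omega generated with rho=0.5, n=1000; 5000 sweeps must
        # concentrate near the truth
        rng = np.random.default_rng(5)
        R_true = np.array([[1.0, 0.5], [0.5, 1.0]])
        W = rng.standard_normal((1000, 2)) @ np.linalg.cholesky(R_true).T
        priors = PriorConfig()
        R = np.eye(2)
        kept = []
        for it in range(5000):
            R, _, _ = draw_rho_omega(W, priors, R, rng, scale=0.05, nu0=7)
            if it >= 500:
                kept.append(R[0, 1])
        assert abs(np.mean(kept) - 0.5) < 0.05

    def test_identical_columns_give_correlation_near_one(self):
        rng = np.random.default_rng(6)
        col = rng.standard_normal(500)
        W = np.column_stack([col, col])
        R = np.eye(2)
        kept = []
        for it in range(2000):
            R, _, _ = draw_rho_omega(W, PriorConfig(), R, rng, scale=0.05,
                                     nu0=7)
            if it >= 200:
                kept.append(R[0, 1])
        assert np.mean(kept) > 0.98

    def test_returns_valid_correlation_matrix(self):
        rng = np.random.default_rng(7)
        W = rng.standard_normal((200, 3))
        R = np.eye(3)
        for _ in range(200):
            R, _, _ = draw_rho_omega(W, PriorConfig(), R, rng, scale=0.2,
                                     nu0=5)
            assert np.allclose(np.diag(R), 1.0)
            assert np.linalg.eigvalsh(R).min() > 0


class TestGibbsVsMetropolis:
    def test_mu_update_distributionally_equivalent(self):
        """The exact Gibbs mu draw and a long random-walk MH run targeting
        the same full conditional must agree in distribution (KS test)."""
        priors = PriorConfig()
        rng = np.random.default_rng(8)
        tb = np.array([0.4, -0.2])
        N, Sigma = 25, np.array([[1.0, 0.4], [0.4, 1.5]])
        gibbs = np.array([draw_mu(tb, N, Sigma, priors, rng)
                          for _ in range(10 ** 4)])[:, 0]
        L0inv = np.linalg.inv(priors.mu_prior_cov(2))
        Sinv = np.linalg.inv(Sigma)
        A = L0inv + N * Sinv
        bvec = N * Sinv @ tb

        def log_target(mu):
            return float(-0.5 * mu @ A @ mu + bvec @ mu)

        x = tb.copy()
        mh = []
        for _ in range(2 * 10 ** 5):
            x, _ = mh_update_block(x, log_target, 0.3, rng)
            mh.append(x[0])
        mh = np.array(mh[10 ** 4::19])[:10 ** 4]
        assert stats.ks_2samp(gibbs, mh).pvalue > 0.01


class TestSweepAndChains:
    def test_anchor_constraints_hold_every_draw(self, small_fit):
        draws, _ = small_fit
        a = draws.anchor_index
        assert np.all(draws.mu[:, :, a, :] == 0.0)
        assert np.all(draws.sigma2[:, :, a, :] == 1.0)

    def test_cached_likelihood_matches_recomputation(self, tiny_design,
                                                     tiny_dataset):
        from hoirt.sampler import _initial_state, sweep
        data, _ = tiny_dataset
        priors, cfg = PriorConfig(), MCMCConfig(n_iter=20, burn_in=10, seed=9)
        rng = np.random.default_rng(9)
        st = _initial_state(data, tiny_design.items, tiny_design.dims, priors,
                            cfg, 0, rng)
        for _ in range(10):
            sweep(st, data, priors, cfg, rng)
        np.testing.assert_allclose(st.ll_cell, st.recompute_ll_cell(),
                                   rtol=1e-10, atol=1e-10)

    def test_single_retained_draw_bookkeeping(self, tiny_design, tiny_dataset):
        data, _ = tiny_dataset
        cfg = MCMCConfig(n_chains=1, n_iter=60, burn_in=50, thin=10, seed=1)
        draws = run_chains(data, tiny_design.items, tiny_design.dims,
                           config=cfg)
        assert draws.n_kept == 1

    def test_same_seed_bit_identical(self, tiny_design, tiny_dataset):
        data, _ = tiny_dataset
        cfg = MCMCConfig(n_chains=2, n_iter=60, burn_in=30, seed=77)
        d1 = run_chains(data, tiny_design.items, tiny_design.dims, config=cfg)
        d2 = run_chains(data, tiny_design.items, tiny_design.dims, config=cfg)
        for f in ("mu", "sigma2", "lam", "rho", "alpha", "beta", "deviance",
                  "theta_mean", "omega_mean"):
            assert np.array_equal(getattr(d1, f), getattr(d2, f)), f

    def test_no_anchor_group_is_configuration_error(self, tiny_design,
                                                    tiny_dataset):
        data, _ = tiny_dataset
        with pytest.raises(ConfigurationError, match="anchor"):
            run_chains(data, tiny_design.items, tiny_design.dims,
                       anchor_group="no-such-group")

    def test_all_missing_item_is_named(self, tiny_design, tiny_dataset):
        data, _ = tiny_dataset
        obs = data.observed.copy()
        obs[:, 3] = False
        bad = hoirt.ResponseMatrix(X=data.X, observed=obs, group=data.group,
                                   group_labels=data.group_labels,
                                   item_ids=data.item_ids)
        with pytest.raises(ConfigurationError, match=data.item_ids[3]):
            run_chains(bad, tiny_design.items, tiny_design.dims,
                       config=MCMCConfig(n_iter=20, burn_in=10))

    def test_pooled_variant_fixes_all_means(self, tiny_design, tiny_dataset):
        data, _ = tiny_dataset
        cfg = MCMCConfig(n_chains=1, n_iter=80, burn_in=40, seed=3,
                         model_variant="pooled")
        draws = run_chains(data, tiny_design.items, tiny_design.dims,
                           config=cfg)
        assert np.all(draws.mu == 0.0)
        assert np.all(draws.sigma2 == 1.0)
        # shared lam and rho: identical across groups in every draw
        assert np.all(draws.lam == draws.lam[:, :, :1, :])
        assert np.all(draws.rho == draws.rho[:, :, :1])

    def test_complete_deviance_exceeds_conditional(self, small_fit):
        """The complete-data deviance adds the (negative) log prior layers,
        so it is strictly larger than the item-conditional deviance."""
        draws, _ = small_fit
        assert np.all(draws.deviance_complete > draws.deviance)

    def test_deviance_trace_stabilizes(self, small_fit):
        """No monotone drift after burn-in: late-half mean within a few SDs
        of the early-half mean."""
        draws, _ = small_fit
        dev = draws.deviance[0]
        half = len(dev) // 2
        early, late = dev[:half], dev[half:]
        assert abs(late.mean() - early.mean()) < 4 * dev.std(ddof=1)
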