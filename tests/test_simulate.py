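"""Synthetic data generation: benchmark design, traits, responses, sparsity."""

import numpy as np
import pytest
from scipy import stats

import hoirt
from hoirt.errors import ConfigurationError, ParameterError
from hoirt.simulate import (apply_study_sparsity, benchmark_design,
                            dichotomize, replication_study, simulate_dataset,
                            simulate_responses, simulate_traits)


class TestBenchmarkDesign:
    def test_item_bank_values(self):
        d = benchmark_design()
        assert d.items.n_items == 150
        assert d.items.items_per_dimension(5).tolist() == [30] * 5
        # first and last of the 30-item block, repeated per dimension
        assert d.items.discrimination[0] == pytest.approx(1.288)
        assert d.items.difficulty[0] == pytest.approx(0.193)
        assert d.items.discrimination[29] == pytest.approx(1.099)
        assert d.items.difficulty[29] == pytest.approx(-1.162)
        np.testing.assert_array_equal(d.items.discrimination[:30],
                                      d.items.discrimination[30:60])

    def test_structural_truth(self):
        d = benchmark_design()
        assert d.n_per_group == (1000, 1000, 1000)
        assert np.all(d.params.lam == 0.837)
        np.testing.assert_array_equal(d.params.mu[1], [0.3, 0.4, 0.5, 0.6, 0.7])
        np.testing.assert_array_equal(d.params.sigma2[:, 0], [1.0, 0.75, 1.25])
        assert np.all(d.params.rho_omega[:, 0, 1] == 0.5)
        assert d.params.anchor[0] and not d.params.anchor[1:].any()
        assert d.dims.k == 3          # dimensions 1-3 on the first component


class TestSimulateTraits:
    def test_reproducible_given_seed(self):
        d = benchmark_design(50)
        t1, g1 = simulate_traits(d, np.random.default_rng(42))
        t2, g2 = simulate_traits(d, np.random.default_rng(42))
        np.testing.assert_array_equal(t1.theta, t2.theta)
        np.testing.assert_array_equal(g1, g2)

    def test_high_loading_couples_theta_to_omega(self):
        # within one group (fixed mu, sigma), lam -> 1 forces theta ~ omega
        d = benchmark_design(2000)
        d.params.lam[:] = 0.999
        t, g = simulate_traits(d, np.random.default_rng(1))
        sel = g == 0
        r = np.corrcoef(t.theta[sel, 0], t.omega[sel, 0])[0, 1]
        assert r > 0.99

    def test_marginal_variance_matches_sigma2(self):
        n = 10 ** 5
        d = benchmark_design((n, 10, 10))
        t, g = simulate_traits(d, np.random.default_rng(2))
        th = t.theta[g == 0]
        se = 1.0 * np.sqrt(2 / (n - 1))
        for dd in range(5):
            assert abs(th[:, dd].var(ddof=1) - 1.0) < 3 * se


class TestSimulateResponses:
    def test_extreme_traits_give_certain_responses(self):
        d = benchmark_design(10)
        t, g = simulate_traits(d, np.random.default_rng(3))
        t.theta[:] = 50.0
        data = simulate_responses(t, d.items, np.random.default_rng(3), group=g)
        assert np.all(data.X[data.observed] == 1)

    def test_easy_item_endorsed_by_nearly_everyone(self):
        bank = hoirt.ItemBank(item_id=["easy"], dimension=[0],
                              discrimination=[1.0], difficulty=[-10.0])
        t = hoirt.PersonTraits(theta=np.random.default_rng(4).normal(
            size=(2000, 1)), omega=np.zeros((2000, 1)))
        data = simulate_responses(t, bank, np.random.default_rng(4))
        assert data.X.mean() > 0.99

    def test_endorsement_matches_quadrature_oracle(self):
        # per-item endorsement proportion vs integral p(theta) dF(theta)
        # computed by Gauss-Hermite quadrature over the theta marginal
        d = benchmark_design(4000, seed=5)
        rng = np.random.default_rng(5)
        data, traits = simulate_dataset(d, rng)
        nodes, weights = np.polynomial.hermite_e.hermegauss(61)
        weights = weights / weights.sum()
        for j in [0, 8, 29]:          # easy, hard and moderate items
            dd = d.items.dimension[j]
            a, b = d.items.discrimination[j], d.items.difficulty[j]
            expected = 0.0
            for g in range(3):
                mu = d.params.mu[g, dd]
                sd = np.sqrt(d.params.sigma2[g, dd])
                p = 1 / (1 + np.exp(-a * (mu + sd * nodes - b)))
                expected += (p * weights).sum() / 3
            observed = data.X[:, j].mean()
            se = np.sqrt(expected * (1 - expected) / data.n_persons)
            assert abs(observed - expected) < 3 * se


class TestStudySparsity:
    def test_identity_when_nothing_masked(self):
        d = benchmark_design(20)
        data, _ = simulate_dataset(d, np.random.default_rng(6))
        out = apply_study_sparsity(data, {}, 0.0, np.random.default_rng(6))
        np.testing.assert_array_equal(out.observed, data.observed)
        np.testing.assert_array_equal(out.X, data.X)

    def test_within_missing_rate_hits_target_coverage(self):
        d = benchmark_design(300)
        data, _ = simulate_dataset(d, np.random.default_rng(7))
        out = apply_study_sparsity(data, {}, 0.07, np.random.default_rng(7))
        frac = out.observed.mean()
        n = out.observed.size
        se = np.sqrt(0.93 * 0.07 / n)
        assert abs(frac - 0.93) < 3 * se

    def test_group_losing_a_dimension_warns_but_runs(self):
        d = benchmark_design(20)
        data, _ = simulate_dataset(d, np.random.default_rng(8))
        avail = np.ones(150, dtype=bool)
        avail[d.items.dimension == 4] = False   # group 0 loses dimension 5
        with pytest.warns(UserWarning, match="dimension 5"):
            out = apply_study_sparsity(data, {0: avail}, 0.0,
                                       np.random.default_rng(8),
                                       dims=d.dims, items=d.items)
        assert not out.observed[out.group == 0][:, d.items.dimension == 4].any()
        assert out.observed[out.group == 1][:, d.items.dimension == 4].all()

    def test_item_unavailable_everywhere_is_an_error(self):
        d = benchmark_design(10)
        data, _ = simulate_dataset(d, np.random.default_rng(9))
        avail = np.ones(150, dtype=bool)
        avail[0] = False
        with pytest.raises(ConfigurationError, match=data.item_ids[0]):
            apply_study_sparsity(data, {0: avail, 1: avail, 2: avail}, 0.0,
                                 np.random.default_rng(9))


class TestDichotomize:
    def test_binary_input_with_unit_cutpoint_is_identity(self):
        X = np.array([[0.0, 1.0], [1.0, np.nan]])
        out = dichotomize(X, cutpoints=[1, 1])
        np.testing.assert_array_equal(out.X[out.observed],
                                      np.array([0, 1, 1]))
        assert not out.observed[1, 1]

    def test_five_category_uniform_expected_endorsement(self):
        rng = np.random.default_rng(10)
        P = rng.integers(1, 6, size=(20000, 1)).astype(float)
        out = dichotomize(P, cutpoints=[3])
        assert out.X.mean() == pytest.approx(0.6, abs=0.01)

    def test_all_missing_item_stays_missing(self):
        P = np.full((4, 1), np.nan)
        out = dichotomize(P, cutpoints=[2])
        assert not out.observed.any()

    def test_out_of_range_cutpoint_names_item(self):
        P = np.array([[1.0, 2.0], [2.0, 3.0]])
        with pytest.raises(ParameterError, match="itemB"):
            dichotomize(P, cutpoints=[1, 9], item_ids=["itemA", "itemB"])


class TestReplicationStudy:
    def test_smoke_tiny_design_emits_all_sections(self):
        # 2 groups x 50 persons x 10 items, short chains: completes and
        # produces every report section
        dims = hoirt.DimensionMap(D=2, H=2, loading=np.array([0, 1]))
        bank = hoirt.ItemBank(
            item_id=[f"i{k}" for k in range(10)],
            dimension=np.repeat([0, 1], 5),
            discrimination=np.full(10, 1.2), difficulty=np.linspace(-1, 1, 10))
        params = hoirt.GroupParameters(
            mu=np.array([[0.0, 0.0], [0.4, -0.2]]),
            sigma2=np.array([[1.0, 1.0], [0.8, 1.2]]),
            lam=np.full((2, 2), 0.8),
            rho_omega=np.tile(np.array([[1, 0.5], [0.5, 1]]), (2, 1, 1)),
            anchor=np.array([True, False]))
        design = hoirt.SimulationDesign(n_per_group=(50, 50), params=params,
                                        items=bank, dims=dims, seed=1)
        cfg = hoirt.MCMCConfig(n_chains=1, n_iter=500, burn_in=200, seed=2)
        report = replication_study(design, cfg, n_reps=1)
        assert report.n_replications == 1
        assert {"parameter", "group", "true", "estimate",
                "se_replication", "se_posterior"} <= set(report.structural.columns)
        assert "overall" in report.item_recovery["dimension"].tolist()
        assert len(report.trait_correlations) == 4   # 2 theta + 2 omega
        assert len(report.seeds) == 1 and len(report.converged) == 1
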