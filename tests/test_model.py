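"""Core model: item response function, likelihood, hierarchical trait density."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import hoirt
from hoirt.errors import ParameterError, ShapeError
from hoirt.model import (DimensionMap, ItemBank, PersonTraits, ResponseMatrix,
                         log_likelihood, response_probability,
                         theta_conditional_density)

finite = st.floats(-5, 5, allow_nan=False)
pos = st.floats(0.1, 4, allow_nan=False)


class TestResponseProbability:
    def test_theta_equal_beta_gives_half(self):
        assert response_probability(0.193, 1.288, 0.193) == pytest.approx(0.5)

    def test_closed_form_value(self):
        assert response_probability(0.0, 1.288, 0.193) == pytest.approx(
            np.exp(1.288 * -0.193) / (1 + np.exp(1.288 * -0.193)))
        assert response_probability(0.0, 1.288, 0.193) == pytest.approx(
            0.4382, abs=1e-4)

    def test_limits_and_stability(self):
        # extreme logits must neither overflow nor hit exact 0/1 logs later
        with np.errstate(over="raise"):
            assert response_probability(1e4, 2.0, 0.0) == pytest.approx(1.0)
            assert response_probability(-1e4, 2.0, 0.0) == pytest.approx(0.0)

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ParameterError):
            response_probability(0.0, 0.0, 0.0)
        with pytest.raises(ParameterError):
            response_probability(0.0, -1.0, 0.0)

    @given(theta=finite, alpha=pos, beta=finite)
    def test_logistic_symmetry(self, theta, alpha, beta):
        p1 = response_probability(theta, alpha, beta)
        p2 = response_probability(-theta, alpha, -beta)
        assert p1 + p2 == pytest.approx(1.0, abs=1e-12)

    @given(alpha=pos, beta=finite)
    def test_monotone_in_theta(self, alpha, beta):
        grid = np.linspace(-4, 4, 20)
        p = response_probability(grid, alpha, beta)
        assert np.all(np.diff(p) > 0)


def _simple_bank(J=2, dims=(0, 0)):
    return ItemBank(item_id=[f"i{k}" for k in range(J)],
                    dimension=np.array(dims),
                    discrimination=np.ones(J), difficulty=np.zeros(J))


class TestLogLikelihood:
    def test_all_missing_is_zero(self):
        data = ResponseMatrix(X=np.zeros((2, 2), dtype=int),
                              observed=np.zeros((2, 2), dtype=bool),
                              group=np.zeros(2, dtype=int))
        traits = PersonTraits(theta=np.zeros((2, 1)), omega=np.zeros((2, 1)))
        assert log_likelihood(data, traits, _simple_bank()) == 0.0

    def test_single_observed_at_difficulty_gives_log_half(self):
        obs = np.zeros((1, 2), dtype=bool)
        obs[0, 0] = True
        data = ResponseMatrix(X=np.array([[1, 0]]), observed=obs,
                              group=np.zeros(1, dtype=int))
        traits = PersonTraits(theta=np.zeros((1, 1)), omega=np.zeros((1, 1)))
        assert log_likelihood(data, traits, _simple_bank()) == pytest.approx(
            np.log(0.5))

    def test_matches_term_by_term_oracle(self):
        # brute-force sum of the four Bernoulli terms of a 2x2 layout
        rng = np.random.default_rng(0)
        theta = rng.normal(size=(2, 2))
        bank = ItemBank(item_id=["a", "b"], dimension=np.array([0, 1]),
                        discrimination=np.array([1.2, 0.8]),
                        difficulty=np.array([0.3, -0.4]))
        X = np.array([[1, 0], [0, 1]])
        data = ResponseMatrix(X=X, observed=np.ones((2, 2), dtype=bool),
                              group=np.zeros(2, dtype=int))
        traits = PersonTraits(theta=theta, omega=np.zeros((2, 1)))
        expected = 0.0
        for i in range(2):
            for j in range(2):
                p = response_probability(theta[i, bank.dimension[j]],
                                         bank.discrimination[j],
                                         bank.difficulty[j])
                expected += X[i, j] * np.log(p) + (1 - X[i, j]) * np.log(1 - p)
        assert log_likelihood(data, traits, bank) == pytest.approx(expected)

    def test_additive_over_groups_and_dimensions(self):
        rng = np.random.default_rng(1)
        bank = ItemBank(item_id=["a", "b", "c", "d"],
                        dimension=np.array([0, 0, 1, 1]),
                        discrimination=rng.uniform(0.5, 2, 4),
                        difficulty=rng.normal(size=4))
        X = rng.integers(0, 2, (6, 4))
        group = np.array([0, 0, 0, 1, 1, 1])
        data = ResponseMatrix(X=X, observed=np.ones((6, 4), dtype=bool),
                              group=group)
        theta = rng.normal(size=(6, 2))
        traits = PersonTraits(theta=theta, omega=np.zeros((6, 1)))
        total = log_likelihood(data, traits, bank)
        by_group = 0.0
        for g in (0, 1):
            sel = group == g
            sub = ResponseMatrix(X=X[sel], observed=np.ones((3, 4), dtype=bool),
                                 group=np.zeros(3, dtype=int))
            by_group += log_likelihood(
                sub, PersonTraits(theta=theta[sel], omega=np.zeros((3, 1))),
                bank)
        assert total == pytest.approx(by_group)

    def test_shape_mismatch_raises(self):
        data = ResponseMatrix(X=np.zeros((2, 2), dtype=int),
                              observed=np.ones((2, 2), dtype=bool),
                              group=np.zeros(2, dtype=int))
        traits = PersonTraits(theta=np.zeros((3, 1)), omega=np.zeros((3, 1)))
        with pytest.raises(ShapeError):
            log_likelihood(data, traits, _simple_bank())


class TestThetaConditionalDensity:
    def test_lambda_zero_reduces_to_marginal_normal(self):
        x = np.linspace(-2, 2, 9)
        got = theta_conditional_density(x, omega_value=1.7, mu=0.2,
                                        sigma2=1.3, lam=0.0)
        np.testing.assert_allclose(
            got, stats.norm.pdf(x, 0.2, np.sqrt(1.3)))

    def test_closed_form_mean_and_variance(self):
        # mu=0, sigma2=1, lam=0.837, omega=1: mean 0.837, var 1-0.837^2
        mean, var = 0.837, 1 - 0.837 ** 2
        assert var == pytest.approx(0.2995, abs=5e-4)
        got = theta_conditional_density(0.5, 1.0, 0.0, 1.0, 0.837)
        assert got == pytest.approx(stats.norm.pdf(0.5, mean, np.sqrt(var)))

    def test_marginal_variance_recovers_sigma2(self):
        # law of total variance via Monte Carlo: omega ~ N(0,1)
        rng = np.random.default_rng(7)
        n = 10 ** 5
        sigma2, lam, mu = 1.25, 0.837, -0.4
        omega = rng.standard_normal(n)
        theta = (mu + lam * np.sqrt(sigma2) * omega
                 + np.sqrt(sigma2 * (1 - lam ** 2)) * rng.standard_normal(n))
        se = sigma2 * np.sqrt(2 / (n - 1))
        assert abs(theta.var(ddof=1) - sigma2) < 3 * se

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            theta_conditional_density(0, 0, 0, 1.0, 1.0)
        with pytest.raises(ParameterError):
            theta_conditional_density(0, 0, 0, -1.0, 0.5)


class TestDomainTypes:
    def test_item_bank_invariants(self):
        with pytest.raises(ParameterError):
            ItemBank(item_id=["a", "a"], dimension=[0, 0],
                     discrimination=[1, 1], difficulty=[0, 0])
        with pytest.raises(ParameterError):
            ItemBank(item_id=["a", "b"], dimension=[0, 0],
                     discrimination=[1, -0.1], difficulty=[0, 0])
        bank = hoirt.benchmark_design(10).items
        counts = bank.items_per_dimension()
        assert counts.sum() == bank.n_items

    def test_dimension_map_requires_nonempty_components(self):
        with pytest.raises(ParameterError):
            DimensionMap(D=3, H=2, loading=np.array([0, 0, 0]))
        dm = DimensionMap(D=5, H=2, loading=np.array([0, 0, 0, 1, 1]))
        assert dm.k == 3

    def test_response_matrix_validation(self):
        with pytest.raises(ParameterError):
            ResponseMatrix(X=np.array([[2]]), observed=np.array([[True]]),
                           group=np.zeros(1, dtype=int))
        rm = ResponseMatrix(X=np.array([[1], [0], [1]]),
                            observed=np.ones((3, 1), dtype=bool),
                            group=np.array([0, 0, 1]))
        assert rm.N_g.tolist() == [2, 1]
        assert rm.N_g.sum() == rm.n_persons

    def test_group_parameters_anchor_constraint(self):
        mu = np.array([[0.1, 0.0]])
        with pytest.raises(ParameterError):
            hoirt.GroupParameters(mu=mu, sigma2=np.ones((1, 2)),
                                  lam=np.full((1, 2), 0.5),
                                  rho_omega=np.eye(2)[None],
                                  anchor=np.array([True]))
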