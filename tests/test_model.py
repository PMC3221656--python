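"""Log-density oracles: normalization, decomposition, special cases."""

import itertools
import math

import numpy as np
import pytest
from scipy import integrate, stats

import hbcount as hb


def _prefs(rows):
    return hb.IndividualPreferences(np.asarray(rows))


class TestMultinomialLoglik:
    def test_two_way_split(self):
        assert hb.multinomial_loglik([1, 1], [0.5, 0.5]) == pytest.approx(np.log(0.5))

    def test_empty_row_has_probability_one(self):
        assert hb.multinomial_loglik([0, 0, 0], [0.2, 0.3, 0.5]) == 0.0

    def test_matches_scipy(self):
        x, p = [3, 2, 0], [0.5, 0.3, 0.2]
        expect = stats.multinomial.logpmf(x, n=5, p=p)
        assert hb.multinomial_loglik(x, p) == pytest.approx(float(expect), rel=1e-12)

    @pytest.mark.parametrize("n,p", [(5, [0.5, 0.3, 0.2]), (6, [0.1, 0.9]), (4, [0.25, 0.25, 0.5])])
    def test_normalization_by_enumeration(self, n, p):
        """exp(loglik) sums to one over all outcomes with total n."""
        K = len(p)
        total = 0.0
        for combo in itertools.product(range(n + 1), repeat=K):
            if sum(combo) == n:
                total += math.exp(hb.multinomial_loglik(list(combo), p))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            hb.multinomial_loglik([1, 2], [0.2, 0.3, 0.5])


class TestTotalLoglik:
    def test_single_row_reduces(self, rng):
        t = hb.CountTable(np.array([[3, 2, 1]]))
        prefs = _prefs([[0.5, 0.3, 0.2]])
        assert hb.total_loglik(t, prefs) == pytest.approx(
            hb.multinomial_loglik([3, 2, 1], [0.5, 0.3, 0.2])
        )

    def test_additivity_over_rows(self, rng):
        counts = rng.integers(0, 10, size=(5, 3))
        counts[:, 0] += 1
        g = rng.gamma(1.0, size=(5, 3))
        p = g / g.sum(axis=1, keepdims=True)
        t = hb.CountTable(counts)
        prefs = _prefs(p)
        per_row = sum(
            hb.multinomial_loglik(counts[j], p[j]) for j in range(5)
        )
        assert hb.total_loglik(t, prefs) == pytest.approx(per_row, rel=1e-12)

    def test_duplicated_replicate_doubles(self):
        t1 = hb.CountTable(np.array([[4, 1, 2]]))
        t2 = hb.CountTable(np.array([[4, 1, 2], [4, 1, 2]]))
        prefs1 = _prefs([[0.5, 0.2, 0.3]])
        prefs2 = _prefs([[0.5, 0.2, 0.3], [0.5, 0.2, 0.3]])
        assert hb.total_loglik(t2, prefs2) == pytest.approx(
            2 * hb.total_loglik(t1, prefs1)
        )


class TestDirichletLogpdf:
    def test_flat_is_log_gamma_K(self):
        val = hb.dirichlet_logpdf([0.2, 0.3, 0.5], [1.0, 1.0, 1.0])
        assert val == pytest.approx(np.log(2.0))

    def test_beta22_at_half(self):
        assert hb.dirichlet_logpdf([0.5, 0.5], [2.0, 2.0]) == pytest.approx(np.log(1.5))

    def test_matches_beta_for_K2(self, rng):
        """K=2 is the beta special case of the hierarchical model."""
        for _ in range(5):
            a, b = rng.uniform(0.5, 5, size=2)
            x = rng.uniform(0.05, 0.95)
            assert hb.dirichlet_logpdf([x, 1 - x], [a, b]) == pytest.approx(
                stats.beta.logpdf(x, a, b), rel=1e-10
            )

    def test_normalizes_K2_by_quadrature(self):
        alpha = np.array([2.3, 0.8])
        val, _ = integrate.quad(
            lambda t: math.exp(hb.dirichlet_logpdf([t, 1 - t], alpha)), 0, 1
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_normalizes_K3_by_quadrature(self):
        alpha = np.array([1.7, 2.2, 3.1])
        val, _ = integrate.dblquad(
            lambda v, u: math.exp(hb.dirichlet_logpdf([u, v, 1 - u - v], alpha)),
            0.0, 1.0, 0.0, lambda u: 1.0 - u,
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_boundary_handling(self):
        assert hb.dirichlet_logpdf([0.0, 1.0], [2.0, 2.0]) == -np.inf
        with pytest.raises(ValueError, match="boundary"):
            hb.dirichlet_logpdf([0.0, 1.0], [2.0, 2.0], on_boundary="raise")


class TestConditionalPrior:
    def test_flat_population(self):
        prefs = _prefs([[0.2, 0.3, 0.5]] * 4)
        pop = hb.PopulationParams(q=np.array([1 / 3] * 3), w=3.0)  # alpha = (1,1,1)
        assert hb.conditional_prior_loglik(prefs, pop) == pytest.approx(4 * np.log(2.0))

    def test_matches_per_row_sum(self, rng):
        g = rng.gamma(1.0, size=(6, 3))
        p = g / g.sum(axis=1, keepdims=True)
        pop = hb.PopulationParams(q=np.array([0.5, 0.3, 0.2]), w=7.5)
        per_row = sum(hb.dirichlet_logpdf(p[j], pop.alpha) for j in range(6))
        assert hb.conditional_prior_loglik(_prefs(p), pop) == pytest.approx(
            per_row, rel=1e-12
        )


class TestLogPosterior:
    def _setup(self, rng):
        counts = rng.integers(0, 8, size=(4, 3))
        counts[:, 0] += 1
        table = hb.CountTable(counts)
        g = rng.gamma(1.0, size=(4, 3))
        prefs = _prefs(g / g.sum(axis=1, keepdims=True))
        pop = hb.PopulationParams(q=np.array([0.5, 0.3, 0.2]), w=5.0)
        return table, prefs, pop

    def test_flat_prior_constants(self, rng):
        table, prefs, pop = self._setup(rng)
        prior = hb.PriorConfig(w_upper=100.0)
        expect = (
            hb.total_loglik(table, prefs)
            + hb.conditional_prior_loglik(prefs, pop)
            + np.log(2.0)
            - np.log(100.0)
        )
        assert hb.log_posterior(table, prefs, pop, prior) == pytest.approx(expect)

    def test_w_outside_support(self, rng):
        table, prefs, pop = self._setup(rng)
        prior = hb.PriorConfig(w_upper=4.0)  # pop.w = 5 >= u
        assert hb.log_posterior(table, prefs, pop, prior) == -np.inf

    def test_term_by_term_decomposition(self, rng):
        table, prefs, pop = self._setup(rng)
        prior = hb.PriorConfig(q_prior_alpha=[2.0, 1.0, 1.5], w_upper=50.0)
        expect = (
            hb.total_loglik(table, prefs)
            + hb.conditional_prior_loglik(prefs, pop)
            + hb.dirichlet_logpdf(pop.q, np.array([2.0, 1.0, 1.5]))
            - np.log(50.0)
        )
        assert hb.log_posterior(table, prefs, pop, prior) == pytest.approx(expect, rel=1e-12)

    def test_permutation_invariance(self, rng):
        table, prefs, pop = self._setup(rng)
        prior = hb.PriorConfig()
        perm = [2, 0, 1]
        table_p = hb.CountTable(table.counts[:, perm])
        prefs_p = _prefs(prefs.probs[:, perm])
        pop_p = hb.PopulationParams(q=pop.q[perm], w=pop.w)
        assert hb.log_posterior(table, prefs, pop, prior) == pytest.approx(
            hb.log_posterior(table_p, prefs_p, pop_p, prior), rel=1e-12
        )


class TestDeviance:
    def test_zero_for_empty_flat_case(self):
        with pytest.warns(UserWarning, match="zero total"):
            table = hb.CountTable(np.array([[0, 0]]))
        prefs = _prefs([[0.5, 0.5]])
        pop = hb.PopulationParams(q=np.array([0.5, 0.5]), w=2.0)  # alpha=(1,1)
        assert hb.deviance(table, prefs, pop) == pytest.approx(0.0)

    def test_decomposition(self, rng):
        counts = rng.integers(1, 9, size=(5, 3))
        table = hb.CountTable(counts)
        g = rng.gamma(1.0, size=(5, 3))
        prefs = _prefs(g / g.sum(axis=1, keepdims=True))
        pop = hb.PopulationParams(q=np.array([0.4, 0.35, 0.25]), w=12.0)
        assert hb.deviance(table, prefs, pop) == pytest.approx(
            -2 * (hb.total_loglik(table, prefs) + hb.conditional_prior_loglik(prefs, pop)),
            rel=1e-12,
        )

    def test_concentrated_preferences_give_negative_deviance(self):
        # tight individuals around q with large w: conditional prior density >> 1
        q = np.array([0.6, 0.3, 0.1])
        p = np.tile(q, (10, 1))
        table = hb.CountTable(np.tile([6, 3, 1], (10, 1)))
        pop = hb.PopulationParams(q=q, w=500.0)
        assert hb.deviance(table, _prefs(p), pop) < 0.0
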