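"""Sampler correctness: conjugacy, MH stationarity, reproducibility.

The strongest checks here are independent-oracle comparisons: the Gibbs
update against analytic Dirichlet moments, each Metropolis-Hastings
update against its grid-normalized target density, and the whole sampler
against a two-dimensional quadrature of the exact (p-integrated)
Dirichlet-multinomial posterior in the K=2 beta-binomial special case.
"""

import numpy as np
import pytest
from scipy.special import betaln, gammaln
from scipy.stats import kstest

import hbcount as hb


def _empirical_vs_grid_cdf(draws, grid, log_density):
    """Max |ECDF - grid-CDF| between MCMC draws and a normalized target."""
    logd = log_density - log_density.max()
    dens = np.exp(logd)
    cdf = np.cumsum(dens)
    cdf /= cdf[-1]
    ecdf = np.searchsorted(np.sort(draws), grid, side="right") / draws.size
    return float(np.abs(ecdf - cdf).max())


class TestGibbsUpdate:
    def test_no_data_draws_from_conditional_prior(self, rng):
        with pytest.warns(UserWarning, match="zero total"):
            table = hb.CountTable(np.zeros((2000, 3), dtype=int))
        pop = hb.PopulationParams(q=np.array([0.5, 0.3, 0.2]), w=10.0)
        prefs = hb.gibbs_update_individuals(table, pop, rng)
        mean = prefs.probs.mean(axis=0)
        se = np.sqrt(pop.q * (1 - pop.q) / (pop.w + 1) / 2000)
        assert np.all(np.abs(mean - pop.q) < 4 * se)

    def test_posterior_moments(self, rng):
        """Row means match (x_j + w q)/(n_j + w), the Dirichlet posterior mean."""
        x = np.array([[2, 1]])
        pop = hb.PopulationParams(q=np.array([0.5, 0.5]), w=2.0)  # w q = (1,1)
        table = hb.CountTable(x)
        draws = np.array(
            [hb.gibbs_update_individuals(table, pop, rng).probs[0, 0] for _ in range(20_000)]
        )
        # full conditional is Beta(3, 2): mean 0.6, var 0.04
        se = np.sqrt(0.6 * 0.4 / 6 / 20_000)
        assert abs(draws.mean() - 0.6) < 4 * se

    def test_distribution_matches_conjugate_beta(self, rng):
        x = np.array([[2, 1]], dtype=np.int64)
        pop = hb.PopulationParams(q=np.array([0.5, 0.5]), w=2.0)
        table = hb.CountTable(x)
        draws = np.array(
            [hb.gibbs_update_individuals(table, pop, rng).probs[0, 0] for _ in range(20_000)]
        )
        assert kstest(draws, "beta", args=(3, 2)).pvalue > 0.01


class TestMHUpdates:
    def test_q_update_targets_full_conditional(self, rng):
        """Stationary law of repeated q-updates matches the grid-normalized target."""
        g = rng.gamma(1.0, size=(25, 2))
        prefs = hb.IndividualPreferences(g / g.sum(axis=1, keepdims=True))
        prior = hb.PriorConfig()
        w = 4.0
        pop = hb.PopulationParams(q=np.array([0.5, 0.5]), w=w)
        draws = np.empty(30_000)
        for i in range(30_000):
            pop = hb.mh_update_q(pop, prefs, prior, rng)
            draws[i] = pop.q[0]
        grid = np.linspace(1e-4, 1 - 1e-4, 2000)
        S = np.log(prefs.probs).sum(axis=0)
        logd = np.empty_like(grid)
        for i, q1 in enumerate(grid):
            a = w * np.array([q1, 1 - q1])
            logd[i] = (
                25 * (gammaln(w) - gammaln(a).sum()) + ((a - 1) * S).sum()
            )
        assert _empirical_vs_grid_cdf(draws[2000:], grid, logd) < 0.02

    def test_w_update_targets_full_conditional(self, rng):
        g = rng.gamma(2.0, size=(15, 3))
        prefs = hb.IndividualPreferences(g / g.sum(axis=1, keepdims=True))
        prior = hb.PriorConfig(w_upper=200.0)
        q = np.array([0.4, 0.35, 0.25])
        pop = hb.PopulationParams(q=q, w=3.0)
        draws = np.empty(40_000)
        for i in range(40_000):
            pop = hb.mh_update_w(pop, prefs, prior, rng)
            draws[i] = pop.w
        grid = np.linspace(1e-3, 60.0, 4000)
        S = np.log(prefs.probs).sum(axis=0)
        logd = np.array(
            [
                15 * (gammaln(w) - gammaln(w * q).sum()) + ((w * q - 1) * S).sum()
                for w in grid
            ]
        )
        assert _empirical_vs_grid_cdf(draws[4000:], grid, logd) < 0.02

    def test_w_proposals_beyond_upper_bound_rejected(self, rng):
        prefs = hb.IndividualPreferences(np.array([[0.5, 0.5]]))
        prior = hb.PriorConfig(w_upper=3.0)
        pop = hb.PopulationParams(q=np.array([0.5, 0.5]), w=2.9)
        for _ in range(500):
            pop = hb.mh_update_w(pop, prefs, prior, rng)
            assert pop.w < 3.0


class TestRunChain:
    def test_same_seed_bit_identical(self, null_table):
        cfg = hb.MCMCConfig(n_steps=300, burnin=100, seed=7)
        c1 = hb.run_chain(null_table, config=cfg)
        c2 = hb.run_chain(null_table, config=cfg)
        np.testing.assert_array_equal(c1.p_draws, c2.p_draws)
        np.testing.assert_array_equal(c1.q_draws, c2.q_draws)
        np.testing.assert_array_equal(c1.w_draws, c2.w_draws)

    def test_thinning_and_draw_count(self, null_table):
        cfg = hb.MCMCConfig(n_steps=1000, burnin=100, thin=3, seed=7)
        chain = hb.run_chain(null_table, config=cfg)
        assert chain.n_draws == 1000 // 3

    def test_constrained_model_fixes_q(self, null_table):
        cfg = hb.MCMCConfig(n_steps=200, burnin=50, seed=7)
        chain = hb.run_chain(null_table, config=cfg, constrain_q=True)
        np.testing.assert_allclose(chain.q_draws, 1.0 / 3.0)

    def test_q_concentrates_on_common_preference(self, rng):
        """Strong shared preference in the data pulls q toward it."""
        v = np.array([0.7, 0.2, 0.1])
        counts = rng.multinomial(200, v, size=40)
        table = hb.CountTable(counts)
        cfg = hb.MCMCConfig(n_steps=3000, burnin=1000, seed=11)
        chain = hb.run_chain(table, config=cfg)
        assert np.all(np.abs(chain.q_draws.mean(axis=0) - v) < 0.05)

    def test_k2_matches_exact_marginal_posterior(self):
        """Whole-sampler oracle: in the K=2 (beta-binomial) case, the
        p-integrated posterior of (q, w) is exactly a product of
        Dirichlet-multinomial likelihoods; quadrature on a fine 2-D grid
        gives the exact posterior mean of q_1."""
        gen = np.random.default_rng(5)
        x = np.array([gen.multinomial(int(n), [0.65, 0.35]) for n in gen.integers(5, 41, 10)])
        table = hb.CountTable(x)
        u = 60.0
        prior = hb.PriorConfig(w_upper=u)
        cfg = hb.MCMCConfig(n_steps=40_000, burnin=4000, seed=17)
        chain = hb.run_chain(table, prior, cfg)

        n = x.sum(axis=1)
        q_grid = np.linspace(0.002, 0.998, 400)
        w_grid = np.linspace(0.05, u - 0.05, 400)
        Q, W = np.meshgrid(q_grid, w_grid, indexing="ij")
        a, b = W * Q, W * (1 - Q)
        logpost = np.zeros_like(Q)
        for j in range(x.shape[0]):
            logpost += (
                betaln(x[j, 0] + a, x[j, 1] + b)
                - betaln(a, b)
            )
        logpost -= logpost.max()
        post = np.exp(logpost)
        q_mean_exact = (post * Q).sum() / post.sum()
        assert chain.q_draws[:, 0].mean() == pytest.approx(q_mean_exact, abs=0.01)

    def test_label_equivariance_distributional(self, rng):
        """Permuting choice columns permutes the q posterior (within MC error)."""
        counts = rng.multinomial(30, [0.55, 0.3, 0.15], size=25)
        perm = [2, 0, 1]
        cfg = hb.MCMCConfig(n_steps=6000, burnin=1500, seed=3)
        m1 = hb.run_chain(hb.CountTable(counts), config=cfg).q_draws.mean(axis=0)
        m2 = hb.run_chain(hb.CountTable(counts[:, perm]), config=cfg).q_draws.mean(axis=0)
        np.testing.assert_allclose(m2, m1[perm], atol=0.02)

    def test_geweke_stationarity(self, fitted_chain):
        """First/last-segment z-scores of the q and w traces are small."""
        for trace in [fitted_chain.q_draws[:, 0], fitted_chain.w_draws]:
            n = trace.size
            a, b = trace[: n // 10], trace[n // 2 :]

            def batch_se(x, nb=20):
                means = np.array_split(x, nb)
                means = np.array([m.mean() for m in means])
                return means.std(ddof=1) / np.sqrt(nb)

            z = (a.mean() - b.mean()) / np.hypot(batch_se(a), batch_se(b))
            assert abs(z) < 3.0

    def test_w_direction_tracks_dispersion(self, rng):
        """Homogeneous individuals push w up; polarized ones push it down."""
        n = np.full(20, 30)
        tight = np.array([rng.multinomial(30, [0.5, 0.5]) for _ in range(20)])
        gp = rng.beta(0.3, 0.3, size=20)  # polarized true preferences
        loose = np.array([rng.multinomial(30, [g, 1 - g]) for g in gp])
        cfg = hb.MCMCConfig(n_steps=3000, burnin=1000, seed=5)
        w_tight = hb.run_chain(hb.CountTable(tight), config=cfg).w_draws.mean()
        w_loose = hb.run_chain(hb.CountTable(loose), config=cfg).w_draws.mean()
        assert w_tight > w_loose
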