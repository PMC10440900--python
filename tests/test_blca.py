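import numpy as np
import pytest

from nbblca.blca import (
    BLCAParams,
    GibbsChain,
    blca_em,
    blca_gibbs,
    chain_diagnostics,
    component_loglik,
    log_posterior,
    mixture_loglik,
    posterior_z,
    relabel_chain,
)
from nbblca.data_model import PriorConfig, RunConfig


class TestLikelihoods:
    def test_fair_coin(self):
        assert component_loglik([0.5, 0.5], [1, 0]) == pytest.approx(np.log(0.25))

    def test_degenerate_certainty(self):
        assert component_loglik([1.0, 0.0], [1, 0]) == pytest.approx(0.0)

    def test_direct_product(self):
        assert component_loglik([0.9, 0.2], [1, 1]) == pytest.approx(np.log(0.18))

    def test_impossible_observation_is_minus_inf(self):
        assert component_loglik([0.0], [1]) == -np.inf

    def test_mixture_single_component_reduces(self, rng):
        X = rng.integers(0, 2, (10, 3))
        theta = rng.uniform(0.1, 0.9, (1, 3))
        p = BLCAParams([1.0], theta)
        direct = sum(component_loglik(theta[0], x) for x in X)
        assert mixture_loglik(p, X) == pytest.approx(direct)

    def test_mixture_degenerate_weights(self, rng):
        X = rng.integers(0, 2, (6, 3))
        theta = rng.uniform(0.1, 0.9, (2, 3))
        full = BLCAParams([1.0, 0.0], theta)
        only1 = BLCAParams([1.0], theta[:1])
        assert mixture_loglik(full, X) == pytest.approx(mixture_loglik(only1, X))

    def test_mixture_hand_sum(self):
        p = BLCAParams([0.5, 0.5], [[0.2], [0.8]])
        assert mixture_loglik(p, [[1]]) == pytest.approx(np.log(0.5))


class TestPosteriorZ:
    def test_identical_components_return_tau(self, rng):
        theta = np.tile(rng.uniform(0.2, 0.8, 4), (2, 1))
        p = BLCAParams([0.3, 0.7], theta)
        Z = posterior_z(p, rng.integers(0, 2, (8, 4))).Z
        assert np.allclose(Z, [0.3, 0.7])

    def test_hand_bayes(self):
        p = BLCAParams([0.5, 0.5], [[0.2], [0.8]])
        Z = posterior_z(p, [[1]]).Z
        assert Z[0] == pytest.approx([0.2, 0.8])

    def test_rows_normalized(self, rng):
        p = BLCAParams(rng.dirichlet(np.ones(3)), rng.uniform(0.05, 0.95, (3, 5)))
        Z = posterior_z(p, rng.integers(0, 2, (50, 5))).Z
        assert Z.sum(axis=1) == pytest.approx(np.ones(50), abs=1e-12)


class TestEM:
    def test_single_component_is_column_mean(self, rng):
        X = rng.integers(0, 2, (30, 4)).astype(float)
        params, resp, _ = blca_em(X, 1, run=RunConfig(seed=0, n_restarts=1, max_iter=5))
        assert params.tau == pytest.approx([1.0])
        assert params.theta[0] == pytest.approx(X.mean(axis=0), abs=1e-9)

    def test_m_step_is_weighted_mean_under_flat_priors(self, rng):
        from nbblca.blca import _m_step

        X = rng.integers(0, 2, (40, 3)).astype(float)
        Z = rng.dirichlet(np.ones(2), size=40)
        params = _m_step(X, Z, PriorConfig.uniform(2, 3))
        oracle = (Z.T @ X) / Z.sum(axis=0)[:, None]
        assert params.theta == pytest.approx(oracle, abs=1e-9)
        assert params.tau == pytest.approx(Z.mean(axis=0), abs=1e-9)

    def test_objective_monotone(self, sep2, quick_run):
        _, _, trace = blca_em(sep2.X, 2, run=quick_run)
        diffs = np.diff(trace)
        assert (diffs >= -1e-10 * np.abs(trace[:-1])).all()

    def test_generative_truth_recovery(self, rng):
        z = rng.integers(0, 2, 200)
        truth = np.where(z[:, None] == 0, 0.9, 0.1)
        X = (rng.random((200, 10)) < truth).astype(float)
        params, resp, _ = blca_em(X, 2, run=RunConfig(seed=1, n_restarts=10))
        th = params.theta
        if abs(th[0].mean() - 0.9) > abs(th[1].mean() - 0.9):
            th = th[::-1]
        assert np.abs(th - np.array([[0.9] * 10, [0.1] * 10])).max() < 0.08
        hard = params.tau is not None and resp.labels()
        agreement = max((hard == z).mean(), (hard != z).mean())
        assert agreement >= 0.95

    def test_rejects_alpha_below_one(self, sep2):
        with pytest.raises(ValueError):
            blca_em(sep2.X, 2, priors=PriorConfig.uniform(2, 6, a=0.5))

    def test_rejects_more_components_than_rows(self):
        with pytest.raises(ValueError):
            blca_em(np.array([[1.0]]), 2)

    def test_grid_maximizer_matches_em_stationary_point(self):
        """On a tiny M=1 instance the EM optimum matches a brute-force grid
        search of the log posterior over (tau, theta) at 0.01 resolution."""
        rng = np.random.default_rng(99)
        X = (rng.random((16, 1)) < 0.3).astype(float)
        k, n = float(X.sum()), 16
        priors = PriorConfig.uniform(2, 1)
        params, _, _ = blca_em(X, 2, priors, RunConfig(seed=3, n_restarts=8))
        grid = np.arange(0.01, 1.0, 0.01)
        tau, t0, t1 = np.meshgrid(grid, grid, grid, indexing="ij")
        p = tau * t0 + (1 - tau) * t1  # mixture marginal of a single Bernoulli
        best = float((k * np.log(p) + (n - k) * np.log(1 - p)).max())
        em_val = log_posterior(params, X, priors)
        assert em_val >= best - 1e-6
        assert em_val <= best + 0.05  # grid resolution slack


class TestGibbs:
    def test_prior_sampling_with_empty_data(self):
        run = RunConfig(seed=4, gibbs_iters=3000, burn_in=0, thin=1)
        priors = PriorConfig(np.full((1, 1), 2.0), np.full((1, 1), 5.0), np.ones(1))
        chain = blca_gibbs(np.zeros((0, 1)), 1, priors, run)
        # theta draws marginally Beta(2, 5): mean 2/7
        assert chain.theta[:, 0, 0].mean() == pytest.approx(2 / 7, abs=0.02)

    def test_fixed_membership_conditional_mean(self, rng):
        """Holding Z fixed, theta draws have the closed-form Beta posterior mean."""
        X = rng.integers(0, 2, (50, 1)).astype(float)
        Z = np.ones((50, 1))
        a, b = 2.0, 3.0
        ones = float(X.sum())
        draws = rng.beta(ones + a, 50 - ones + b, size=10_000)
        assert draws.mean() == pytest.approx((ones + a) / (50 + a + b), abs=0.01)

    def test_generative_truth_recovery(self, quick_run, rng):
        z = rng.integers(0, 2, 300)
        truth = np.where(z[:, None] == 0, 0.9, 0.1)
        X = (rng.random((300, 8)) < truth).astype(float)
        chain = blca_gibbs(X, 2, run=quick_run.with_(gibbs_iters=1200, burn_in=400))
        pm = chain.posterior_mean()
        th = pm.theta
        if abs(th[0].mean() - 0.9) > abs(th[1].mean() - 0.9):
            th = th[::-1]
        assert np.abs(th - np.array([[0.9] * 8, [0.1] * 8])).max() < 0.05

    def test_retained_count_contract(self, sep2):
        run = RunConfig(seed=0, gibbs_iters=100, burn_in=20, thin=7)
        chain = blca_gibbs(sep2.X, 2, run=run)
        assert chain.n_draws == len(range(20, 100, 7))
        assert np.allclose(chain.tau.sum(axis=1), 1.0)

    def test_single_component_conjugate_posterior_distribution(self, rng):
        """With G=1 and flat priors the sampler reproduces the exact
        Beta-binomial conjugate posterior (KS test)."""
        from scipy import stats

        X = rng.integers(0, 2, (40, 1)).astype(float)
        run = RunConfig(seed=11, gibbs_iters=10_500, burn_in=500, thin=1)
        chain = blca_gibbs(X, 1, PriorConfig.uniform(1, 1), run)
        ones = float(X.sum())
        ks = stats.kstest(chain.theta[:, 0, 0], stats.beta(ones + 1, 40 - ones + 1).cdf)
        assert ks.pvalue > 0.01


class TestRelabel:
    def _swapped_chain(self):
        rng = np.random.default_rng(0)
        base_theta = np.array([[0.9, 0.9, 0.9], [0.1, 0.1, 0.1]])
        D = 60
        theta = np.tile(base_theta, (D, 1, 1)) + rng.normal(0, 0.01, (D, 2, 3))
        tau = np.tile([0.6, 0.4], (D, 1))
        z = np.zeros((D, 5), dtype=np.int64)
        for d in range(1, D, 2):  # swap labels on odd draws
            theta[d] = theta[d, ::-1]
            tau[d] = tau[d, ::-1]
            z[d] = 1 - z[d]
        return GibbsChain(tau, theta, z, np.arange(D), 0, 1)

    def test_swap_discontinuities_removed(self):
        chain = relabel_chain(self._swapped_chain())
        # after relabeling the per-component trace variance collapses
        assert chain.theta[:, 0, 0].std() < 0.05
        assert chain.tau[:, 0].mean() == pytest.approx(0.6, abs=0.02)
        assert (chain.z == chain.z[0]).all()

    def test_idempotent(self):
        once = relabel_chain(self._swapped_chain())
        twice = relabel_chain(once)
        assert np.array_equal(once.theta, twice.theta)
        assert np.array_equal(once.z, twice.z)

    def test_single_component_identity(self, rng):
        D = 10
        chain = GibbsChain(
            np.ones((D, 1)), rng.uniform(0.2, 0.8, (D, 1, 2)),
            np.zeros((D, 3), dtype=np.int64), np.arange(D), 0, 1,
        )
        out = relabel_chain(chain)
        assert np.array_equal(out.theta, chain.theta)


class TestDiagnostics:
    def _chain_from_traces(self, tau_trace):
        D = tau_trace.shape[0]
        theta = np.stack([tau_trace[:, :1], 1 - tau_trace[:, :1]], axis=1)  # (D, 2, 1)
        return GibbsChain(
            np.column_stack([tau_trace[:, 0], 1 - tau_trace[:, 0]]),
            theta, np.zeros((D, 2), dtype=np.int64), np.arange(D), 0, 1,
        )

    def test_iid_draws_rhat_near_one(self, rng):
        chain = self._chain_from_traces(rng.uniform(0.4, 0.6, (800, 1)))
        table = chain_diagnostics(chain)
        assert abs(table.loc["tau[0]", "rhat"] - 1.0) < 0.05
        assert not table.loc["tau[0]", "flagged"]

    def test_duplicated_draws_have_tiny_ess(self, rng):
        vals = np.repeat(rng.uniform(0.3, 0.7, 40), 20)[:, None]
        table = chain_diagnostics(self._chain_from_traces(vals))
        assert table.loc["tau[0]", "ess"] < 200

    def test_constant_chain_reports_nan_without_crash(self):
        table = chain_diagnostics(self._chain_from_traces(np.full((50, 1), 0.5)))
        assert np.isnan(table.loc["tau[0]", "rhat"])

    def test_too_short_chain_raises(self):
        with pytest.raises(ValueError):
            chain_diagnostics(self._chain_from_traces(np.full((1, 1), 0.5)))
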