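"""Hierarchical Bernoulli-beta model: sampler correctness and diagnostics.

The heavy oracles (conjugate KS at 20k draws, recovery, calibration) live in
the acceptance suite; here each component is checked against small analytic
or constructed cases, plus arviz as an independent diagnostic cross-check.
"""

import math

import numpy as np
import pytest
from scipy import stats

from dreadchoice import (
    McmcConfig,
    beta_shape_params,
    ess,
    hdi,
    log_posterior,
    posterior_summary,
    rhat,
    sample_posterior,
)

QUICK = McmcConfig(n_chains=2, n_iter=2_000, n_warmup=500, seed=0)


class TestBetaShapeParams:
    @pytest.mark.parametrize(
        "mu,kappa,expected",
        [(0.5, 2.0, (1.0, 1.0)), (0.6, 102.0, (61.0, 41.0)), (0.55, 22.0, (12.0, 10.0))],
    )
    def test_formula(self, mu, kappa, expected):
        assert beta_shape_params(mu, kappa) == pytest.approx(expected)

    def test_shapes_never_below_one(self):
        for mu in (0.01, 0.5, 0.99):
            for kappa in (2.0, 5.0, 500.0):
                a, b = beta_shape_params(mu, kappa)
                assert a >= 1.0 and b >= 1.0

    def test_kappa_below_floor_rejected(self):
        with pytest.raises(ValueError):
            beta_shape_params(0.5, 1.9)


class TestLogPosterior:
    def test_zero_subjects_is_prior_only(self):
        lp = log_posterior(0.5, 3.0, [], [])
        # Beta(1,1) contributes 0; gamma prior on kappa-2=1 contributes -rate
        expected = (0.01 - 1.0) * math.log(1.0) - 0.01 * 1.0
        assert lp == pytest.approx(expected)

    def test_conjugacy_in_theta(self):
        """With mu, kappa fixed, the theta kernel is Beta(a+k, b+n-k) up to a constant."""
        mu, kappa, k, n = 0.5, 3.0, 7, 10
        a, b = beta_shape_params(mu, kappa)
        post = stats.beta(a + k, b + n - k)
        t1, t2 = 0.3, 0.8
        diff_model = log_posterior(mu, kappa, [t1], [(k, n)]) - log_posterior(
            mu, kappa, [t2], [(k, n)]
        )
        diff_conj = post.logpdf(t1) - post.logpdf(t2)
        assert diff_model == pytest.approx(diff_conj, abs=1e-10)

    def test_boundary_theta_is_minus_inf(self):
        assert log_posterior(0.5, 3.0, [0.0], [(3, 10)]) == -math.inf
        assert log_posterior(0.5, 3.0, [1.0], [(3, 10)]) == -math.inf

    def test_mismatched_subjects_rejected(self):
        with pytest.raises(ValueError):
            log_posterior(0.5, 3.0, [0.5], [(3, 10), (4, 10)])


class TestHdi:
    def test_symmetric_beta_centers_on_half(self, rng):
        lo, hi = hdi(rng.beta(2, 2, 200_000))
        assert (lo + hi) / 2 == pytest.approx(0.5, abs=0.01)

    def test_normal_quantiles(self, rng):
        lo, hi = hdi(rng.standard_normal(20_000))
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_matches_density_threshold_oracle(self, rng):
        """Brute-force oracle: lower the density cutoff of Beta(61,41) until the
        enclosed mass reaches 95%, then compare interval endpoints."""
        dist = stats.beta(61, 41)
        grid = np.linspace(1e-6, 1 - 1e-6, 200_001)
        pdf = dist.pdf(grid)
        order = np.argsort(pdf)[::-1]
        mass = np.cumsum(pdf[order]) * (grid[1] - grid[0])
        sel = order[: np.searchsorted(mass, 0.95) + 1]
        oracle = grid[sel].min(), grid[sel].max()
        sampled = hdi(dist.rvs(400_000, random_state=rng))
        assert sampled[0] == pytest.approx(oracle[0], abs=0.01)
        assert sampled[1] == pytest.approx(oracle[1], abs=0.01)

    def test_degenerate_draws(self):
        assert hdi(np.full(200, 0.7)) == (0.7, 0.7)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            hdi(np.arange(50))

    def test_agrees_with_arviz(self, rng):
        az = pytest.importorskip("arviz")
        draws = rng.gamma(3.0, 1.0, 50_000)
        ours = hdi(draws)
        theirs = az.hdi(draws, hdi_prob=0.95)
        assert ours[0] == pytest.approx(theirs[0], abs=0.02)
        assert ours[1] == pytest.approx(theirs[1], abs=0.02)


class TestRhat:
    def test_iid_chains_near_one(self, rng):
        chains = rng.standard_normal((4, 20_000))
        assert rhat(chains) == pytest.approx(1.0, abs=0.01)

    def test_separated_chains_flagged(self, rng):
        chains = np.stack([rng.standard_normal(1_000), 10 + rng.standard_normal(1_000)])
        assert rhat(chains) > 1.5

    def test_single_trending_chain_detected(self, rng):
        drift = np.linspace(0, 3, 2_000) + rng.standard_normal(2_000)
        assert rhat(drift) > 1.1

    def test_constant_chains_undefined(self):
        assert math.isnan(rhat(np.ones((2, 200))))


class TestEss:
    def test_iid_draws_near_n(self, rng):
        x = rng.standard_normal((4, 5_000))
        assert ess(x) == pytest.approx(20_000, rel=0.10)

    def test_ar1_matches_analytic(self, rng):
        phi, n = 0.9, 50_000
        eps = rng.standard_normal(n)
        x = np.empty(n)
        x[0] = eps[0]
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        expected = n * (1 - phi) / (1 + phi)
        assert ess(x[None, :]) == pytest.approx(expected, rel=0.25)

    def test_scales_with_chain_count(self, rng):
        phi, n = 0.7, 8_000
        def make_chain(seed):
            r = np.random.default_rng(seed)
            e = r.standard_normal(n)
            c = np.empty(n)
            c[0] = e[0]
            for i in range(1, n):
                c[i] = phi * c[i - 1] + e[i]
            return c
        two = np.stack([make_chain(s) for s in (1, 2)])
        four = np.stack([make_chain(s) for s in (1, 2, 3, 4)])
        assert ess(four) == pytest.approx(2 * ess(two), rel=0.25)

    def test_constant_chains_zero(self):
        assert ess(np.ones((2, 200))) == 0.0

    def test_agrees_with_arviz_on_autocorrelated_chains(self, rng):
        az = pytest.importorskip("arviz")
        phi, n = 0.8, 10_000
        chains = np.empty((2, n))
        for c in range(2):
            e = rng.standard_normal(n)
            chains[c, 0] = e[0]
            for i in range(1, n):
                chains[c, i] = phi * chains[c, i - 1] + e[i]
        theirs = float(az.ess(az.convert_to_dataset(chains[:, :, None]))["x"].values.item())
        assert ess(chains) == pytest.approx(theirs, rel=0.30)


class TestSampler:
    def test_identical_seed_identical_draws(self):
        data = [(7, 10), (5, 10), (9, 12)]
        d1 = sample_posterior(data, mcmc=QUICK)
        d2 = sample_posterior(data, mcmc=QUICK)
        assert np.array_equal(d1.mu, d2.mu)
        assert np.array_equal(d1.theta, d2.theta)

    def test_draws_stay_in_support(self):
        draws = sample_posterior([(0, 10), (10, 10), (5, 10)], mcmc=QUICK).post
        assert np.all((draws.mu > 0) & (draws.mu < 1))
        assert np.all(draws.kappa >= 2.0)
        assert np.all((draws.theta > 0) & (draws.theta < 1))

    def test_conjugate_mean_with_clamped_hyperparams(self):
        """mu=0.5, kappa=2 clamped: theta posterior is Beta(8, 4), mean 2/3."""
        draws = sample_posterior(
            [(7, 10)],
            mcmc=McmcConfig(n_chains=4, n_iter=3_000, n_warmup=500, seed=3),
            fix_mu=0.5,
            fix_kappa=2.0,
        ).post
        assert draws.theta.mean() == pytest.approx(8.0 / 12.0, abs=0.01)

    def test_monotone_shrinkage_in_kappa(self):
        """With mu clamped and kappa clamped at increasing values, the spread of
        per-subject theta means contracts toward mu."""
        data = [(2, 20), (10, 20), (18, 20)]
        spreads = []
        for kappa in (2.0, 50.0, 500.0):
            draws = sample_posterior(
                data,
                mcmc=McmcConfig(n_chains=2, n_iter=2_000, n_warmup=500, seed=5),
                fix_mu=0.5,
                fix_kappa=kappa,
            ).post
            means = draws.theta.reshape(-1, 3).mean(axis=0)
            spreads.append(np.std(means))
        assert spreads[0] > spreads[1] > spreads[2]

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            sample_posterior([(0, 0), (0, 0)], mcmc=QUICK)
        with pytest.raises(ValueError):
            sample_posterior([], mcmc=QUICK)

    def test_summary_fields_and_convergence(self):
        data = [(90, 160)] * 5 + [(100, 160)] * 5
        draws = sample_posterior(data, mcmc=McmcConfig(n_chains=4, n_iter=2_500, n_warmup=500, seed=9))
        summary = posterior_summary(draws)
        assert summary.converged
        assert summary.mu.rhat < 1.05
        assert summary.mu.hdi[0] < summary.mu.mean < summary.mu.hdi[1]
        assert len(summary.theta) == 10
        # group mean sits near the pooled fraction
        assert summary.mu.mean == pytest.approx(950 / 1600, abs=0.03)
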