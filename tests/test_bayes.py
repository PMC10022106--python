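"""Truncated denominator sampling and coverage posteriors."""

import numpy as np
import pytest
from scipy import stats

from hybridcov import (
    DenominatorEstimate,
    coverage_posterior,
    district_seed,
    sample_denominators,
    truncated_normal_ppf,
)


def _pred(point, variance):
    return DenominatorEstimate(point, variance, "predicted")


class TestTruncatedNormalSampler:
    def test_degenerate_distribution(self):
        draws = sample_denominators(_pred(100.0, 0.0), n=50, draws=1000, seed=0)
        assert np.all(draws == 100.0)

    def test_degenerate_below_bound_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            sample_denominators(_pred(40.0, 0.0), n=50, draws=10, seed=0)

    def test_untruncated_limit(self):
        """Truncation 12 SDs below the mean: moments match the plain normal."""
        d, sd, n_draws = 1000.0, 50.0, 200_000
        draws = sample_denominators(_pred(d, sd**2), n=400, draws=n_draws, seed=1)
        mc_se = sd / np.sqrt(n_draws)
        assert abs(draws.mean() - d) < 3 * mc_se
        assert draws.std() == pytest.approx(sd, rel=0.02)

    def test_truncation_at_the_mean_matches_closed_form(self):
        """Bound at the mean (alpha = 0): E[X] = mu + sd * phi(0)/(1-Phi(0))."""
        mu, sd, n_draws = 100.0, 30.0, 200_000
        draws = sample_denominators(_pred(mu, sd**2), n=100, draws=n_draws, seed=2)
        assert np.all(draws >= 100.0)
        expected = mu + sd * stats.norm.pdf(0) / stats.norm.sf(0)
        trunc_sd = sd * np.sqrt(1 - 2 / np.pi)
        assert abs(draws.mean() - expected) < 3 * trunc_sd / np.sqrt(n_draws)

    def test_empirical_cdf_matches_analytic(self):
        """KS distance to the analytic truncated-normal CDF < 0.01 at 1e5 draws."""
        mu, sd, lower = 100.0, 30.0, 90.0
        draws = sample_denominators(_pred(mu, sd**2), n=90, draws=10**5, seed=3)
        alpha = (lower - mu) / sd
        ks = stats.kstest(
            draws, lambda x: stats.truncnorm.cdf(x, alpha, np.inf, loc=mu, scale=sd)
        )
        assert ks.statistic < 0.01

    def test_far_tail_truncation_is_stable(self):
        """Bound 8 SDs above the mean: draws finite, ordered, above the bound."""
        u = np.linspace(1e-9, 1 - 1e-9, 1001)
        x = truncated_normal_ppf(u, mean=0.0, sd=1.0, lower=8.0)
        assert np.all(np.isfinite(x))
        assert np.all(x >= 8.0)
        assert np.all(np.diff(x) >= 0)  # monotone in u
        # conditional tail mass beyond the bound concentrates just above it
        assert x[500] < 8.2

    def test_reproducible_for_fixed_seed(self):
        a = sample_denominators(_pred(100.0, 9.0), n=95, draws=100, seed=42)
        b = sample_denominators(_pred(100.0, 9.0), n=95, draws=100, seed=42)
        assert np.array_equal(a, b)


class TestNegativeBinomialSampler:
    def test_moments_match_before_truncation(self):
        mean, var = 2000.0, 8000.0
        draws = sample_denominators(_pred(mean, var), n=1, draws=10**6, seed=5, model="negbin")
        assert draws.mean() == pytest.approx(mean, rel=0.02)
        assert draws.var() == pytest.approx(var, rel=0.02)
        assert np.all(draws == np.round(draws))  # integer support

    def test_truncation_respected(self):
        draws = sample_denominators(_pred(100.0, 400.0), n=110, draws=10_000, seed=6, model="negbin")
        assert np.all(draws >= 110)

    def test_underdispersion_rejected_with_fallback_hint(self):
        with pytest.raises(ValueError, match="normal"):
            sample_denominators(_pred(100.0, 50.0), n=10, draws=10, seed=0, model="negbin")


class TestCoveragePosterior:
    def test_point_mass(self):
        post = coverage_posterior(50, np.full(1000, 100.0), "d001")
        assert post.median == pytest.approx(0.5)
        assert (post.ci_low, post.ci_high) == (pytest.approx(0.5), pytest.approx(0.5))

    def test_median_maps_through_monotone_transform(self):
        rng = np.random.default_rng(8)
        d = rng.normal(200.0, 5.0, size=100_001)
        d = np.maximum(d, 50)  # truncation far below: never binds
        post = coverage_posterior(50, d, "d001")
        assert post.median == pytest.approx(50 / np.median(d), rel=1e-12)

    def test_bound_at_the_mean_keeps_all_draws_below_one(self):
        draws = sample_denominators(_pred(100.0, 900.0), n=100, draws=50_000, seed=9)
        post = coverage_posterior(100, draws, "d001")
        assert post.draws.max() <= 1.0
        assert post.ci_high <= 1.0
        assert post.draws.max() == pytest.approx(1.0, abs=1e-3)  # boundary approached

    def test_draw_below_bound_rejected(self):
        with pytest.raises(ValueError, match="truncation contract"):
            coverage_posterior(100, np.array([99.0, 150.0]), "d001")

    def test_frequentist_limit_far_from_bound(self):
        """With the bound far below, the Bayesian interval width approaches the
        delta-method interval width."""
        from hybridcov import frequentist_coverage

        n, mu, sd = 500, 1000.0, 30.0
        draws = sample_denominators(_pred(mu, sd**2), n=n, draws=400_000, seed=10)
        post = coverage_posterior(n, draws, "d001")
        freq = frequentist_coverage(n, _pred(mu, sd**2))
        bayes_width = post.ci_high - post.ci_low
        freq_width = freq.interval_high - freq.interval_low
        assert post.median == pytest.approx(freq.point, rel=0.01)
        assert bayes_width == pytest.approx(freq_width, rel=0.10)


def test_district_seed_is_stable_and_order_free():
    s1 = district_seed(20150101, "d001/polio")
    assert s1 == district_seed(20150101, "d001/polio")
    assert s1 != district_seed(20150101, "d002/polio")
    assert 0 <= s1 < 2**31
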