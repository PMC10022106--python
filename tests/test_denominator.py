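"""Ratio denominators, delta-method variance and inverse-variance pooling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridcov import DenominatorEstimate, pool_denominators, ratio_denominator

from conftest import exact_prevalence


class TestRatioDenominator:
    def test_zero_variance_prevalence(self):
        est = ratio_denominator(80, exact_prevalence(0.8))
        assert est.point == pytest.approx(100.0)
        assert est.variance == 0.0
        assert est.source == "ratio"

    def test_full_coverage_gives_tally(self):
        est = ratio_denominator(120, exact_prevalence(1.0))
        assert est.point == pytest.approx(120.0)

    def test_delta_variance_formula(self):
        est = ratio_denominator(100, exact_prevalence(0.5, variance=0.0025))
        assert est.point == pytest.approx(200.0)
        assert est.variance == pytest.approx(100**2 * 0.0025 / 0.5**4)

    def test_delta_variance_matches_monte_carlo(self):
        """Empirical variance of n/p* over p* ~ N(p, var) agrees with the
        delta formula up to the second-order term, which is ~8 CV^2 (so a
        ~8% gap at CV = 0.1 and ~1% in the design-realistic regime)."""
        rng = np.random.default_rng(42)
        for p, cv, tol in [(0.85, 0.04, 0.03), (0.8, 0.06, 0.05), (0.5, 0.10, 0.11)]:
            var = (cv * p) ** 2
            est = ratio_denominator(100, exact_prevalence(p, variance=var))
            draws = rng.normal(p, np.sqrt(var), size=10**6)
            mc_var = np.var(100 / draws)
            assert est.variance == pytest.approx(mc_var, rel=tol)
            # and the gap is explained by the known second-order term
            assert mc_var / est.variance == pytest.approx(1 + 8 * cv**2, abs=0.03)

    def test_inversion_recovers_prevalence(self):
        p_hat = exact_prevalence(0.83, variance=0.001)
        est = ratio_denominator(977, p_hat)
        assert 977 / est.point == pytest.approx(p_hat.point, rel=1e-14)

    def test_zero_prevalence_rejected(self):
        with pytest.raises(ValueError, match="zero prevalence"):
            ratio_denominator(100, exact_prevalence(0.0))

    def test_zero_tally_rejected(self):
        with pytest.raises(ValueError, match="tally"):
            ratio_denominator(0, exact_prevalence(0.5))

    @pytest.mark.parametrize("p,cv", [(0.3, 0.07), (0.5, 0.05), (0.85, 0.05)])
    def test_delta_variance_reliable_for_small_cv(self, p, cv):
        """Delta variance within 5% of Monte Carlo when CV(p) is small
        (second-order term 8 CV^2 below 5%); the stratified design used
        here (95 children, coverage ~0.85) has CV ~ 0.04."""
        var = (cv * p) ** 2
        est = ratio_denominator(1000, exact_prevalence(p, variance=var))
        rng = np.random.default_rng(1)
        draws = rng.normal(p, cv * p, size=10**6)
        assert est.variance == pytest.approx(np.var(1000 / draws), rel=0.05)


class TestPooling:
    def test_equal_variances_give_plain_mean(self):
        pooled = pool_denominators(
            [
                DenominatorEstimate(100.0, 4.0, "ratio"),
                DenominatorEstimate(120.0, 4.0, "ratio"),
            ]
        )
        assert pooled.point == pytest.approx(110.0)
        assert pooled.variance == pytest.approx(2.0)
        assert pooled.source == "pooled"

    def test_huge_variance_component_is_ignored(self):
        pooled = pool_denominators(
            [
                DenominatorEstimate(100.0, 1.0, "ratio"),
                DenominatorEstimate(200.0, 1e12, "ratio"),
            ]
        )
        assert pooled.point == pytest.approx(100.0, abs=1e-6)
        assert pooled.variance == pytest.approx(1.0, rel=1e-6)

    def test_weighted_mean_recomputed_independently(self):
        pooled = pool_denominators(
            [
                DenominatorEstimate(100.0, 2.0, "ratio"),
                DenominatorEstimate(130.0, 6.0, "ratio"),
            ]
        )
        expected = (0.5 * 100 + (1 / 6) * 130) / (0.5 + 1 / 6)
        assert pooled.point == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_component_dominates(self):
        pooled = pool_denominators(
            [
                DenominatorEstimate(150.0, 0.0, "ratio"),
                DenominatorEstimate(120.0, 5.0, "ratio"),
            ]
        )
        assert pooled.point == 150.0
        assert pooled.variance == 0.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            pool_denominators([])

    @given(
        data=st.lists(
            st.tuples(
                st.floats(min_value=50, max_value=5e5),
                st.floats(min_value=1e-3, max_value=1e8),
            ),
            min_size=1,
            max_size=6,
        )
    )
    @settings(deadline=None, derandomize=True)
    def test_pooling_order_invariant_and_variance_dominated(self, data):
        estimates = [DenominatorEstimate(p, v, "ratio") for p, v in data]
        pooled = pool_denominators(estimates)
        reversed_pooled = pool_denominators(list(reversed(estimates)))
        assert pooled.point == pytest.approx(reversed_pooled.point, rel=1e-9)
        min_var = min(e.variance for e in estimates)
        assert pooled.variance <= min_var * (1 + 1e-9)
        if len(estimates) >= 2:
            assert pooled.variance < min_var
        low = min(e.point for e in estimates)
        high = max(e.point for e in estimates)
        assert low - 1e-9 <= pooled.point <= high + 1e-9
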