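"""Denominator regression, out-of-sample prediction and frequentist coverage."""

import numpy as np
import pytest

from hybridcov import (
    DenominatorEstimate,
    fit_denominator_model,
    frequentist_coverage,
    predict_denominator,
    prediction_leverage,
)

from conftest import make_district


def _perfect_fixture():
    """Denominators exactly 2x the census population: a noiseless fit."""
    districts = [
        make_district(f"d{j}", census=1000 * (j + 1), prior=500, tally=900, surveyed=True)
        for j in range(6)
    ]
    outcomes = {
        d.district_id: DenominatorEstimate(2.0 * d.census_population, 1.0, "pooled")
        for d in districts
    }
    return districts, outcomes


def _noisy_fixture():
    rng = np.random.default_rng(3)
    districts = []
    outcomes = {}
    for j in range(8):
        census = float(rng.integers(50_000, 150_000))
        prior = float(rng.integers(8_000, 25_000))
        d = make_district(f"d{j}", census=int(census), prior=int(prior), tally=1, surveyed=True)
        districts.append(d)
        outcome = 0.15 * census + 0.4 * prior + rng.normal(0, 500)
        outcomes[d.district_id] = DenominatorEstimate(outcome, 1.0, "pooled")
    return districts, outcomes


class TestFit:
    def test_perfect_fit(self):
        districts, outcomes = _perfect_fixture()
        fit = fit_denominator_model(outcomes, districts, covariates=["census_population"])
        assert fit.coefficients == pytest.approx([0.0, 2.0], abs=1e-8)
        assert fit.residual_variance == pytest.approx(0.0, abs=1e-12)
        assert fit.adjusted_r2 == pytest.approx(1.0)

    def test_coefficients_match_normal_equations_oracle(self):
        districts, outcomes = _noisy_fixture()
        fit = fit_denominator_model(
            outcomes, districts, covariates=["census_population", "prior_tally"]
        )
        # hand-rolled (X'X)^{-1} X'y
        X = np.array(
            [[1.0, d.census_population, d.prior_tally] for d in districts]
        )
        y = np.array([outcomes[d.district_id].point for d in districts])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.coefficients == pytest.approx(beta, rel=1e-8)
        rss = float(((y - X @ beta) ** 2).sum())
        assert fit.residual_variance == pytest.approx(rss / (8 - 3), rel=1e-8)
        # adjusted R^2 from first principles
        tss = float(((y - y.mean()) ** 2).sum())
        r2 = 1 - rss / tss
        assert fit.adjusted_r2 == pytest.approx(1 - (1 - r2) * (8 - 1) / (8 - 3), rel=1e-8)

    def test_residuals_orthogonal_to_design(self):
        districts, outcomes = _noisy_fixture()
        fit = fit_denominator_model(
            outcomes, districts, covariates=["census_population", "prior_tally"]
        )
        X = np.array([[1.0, d.census_population, d.prior_tally] for d in districts])
        y = np.array([outcomes[d.district_id].point for d in districts])
        r = y - X @ fit.coefficients
        assert np.max(np.abs(X.T @ r)) < 1e-8 * np.abs(X.T @ y).max()

    def test_too_few_districts_rejected(self):
        districts, outcomes = _perfect_fixture()
        few = {k: outcomes[k] for k in list(outcomes)[:3]}
        with pytest.raises(ValueError, match="parameters"):
            fit_denominator_model(
                few, districts, covariates=["census_population", "prior_tally"]
            )

    def test_collinear_columns_named(self):
        districts, outcomes = _perfect_fixture()
        for d in districts:
            d.extra["census_copy"] = float(d.census_population)
        with pytest.raises(ValueError, match="census"):
            fit_denominator_model(
                outcomes, districts, covariates=["census_population", "census_copy"]
            )

    def test_weighted_fit_runs_and_differs(self):
        districts, outcomes = _noisy_fixture()
        # unequal outcome variances make WLS differ from OLS
        for i, key in enumerate(outcomes):
            est = outcomes[key]
            outcomes[key] = DenominatorEstimate(est.point, float(1 + 10 * i), "pooled")
        ols = fit_denominator_model(outcomes, districts, covariates=["census_population"])
        wls = fit_denominator_model(
            outcomes, districts, covariates=["census_population"], weighted=True
        )
        assert not np.allclose(ols.coefficients, wls.coefficients)


class TestPredict:
    def test_perfect_fit_predicts_exactly(self):
        districts, outcomes = _perfect_fixture()
        fit = fit_denominator_model(outcomes, districts, covariates=["census_population"])
        pred = predict_denominator(fit, {"census_population": 12_345.0})
        assert pred.point == pytest.approx(2 * 12_345.0, rel=1e-9)
        assert pred.variance == pytest.approx(0.0, abs=1e-6)
        assert pred.source == "predicted"

    def test_leverage_at_centroid_is_one_over_n(self):
        districts, outcomes = _noisy_fixture()
        fit = fit_denominator_model(
            outcomes, districts, covariates=["census_population", "prior_tally"]
        )
        means = {
            "census_population": np.mean([d.census_population for d in districts]),
            "prior_tally": np.mean([d.prior_tally for d in districts]),
        }
        h = prediction_leverage(fit, means)
        assert h == pytest.approx(1 / 8, rel=1e-9)
        pred = predict_denominator(fit, means)
        assert pred.variance == pytest.approx(fit.residual_variance * (1 + 1 / 8), rel=1e-9)

    def test_prediction_variance_matches_matrix_arithmetic(self):
        districts, outcomes = _noisy_fixture()
        fit = fit_denominator_model(
            outcomes, districts, covariates=["census_population", "prior_tally"]
        )
        x = {"census_population": 90_000.0, "prior_tally": 30_000.0}
        X = np.array([[1.0, d.census_population, d.prior_tally] for d in districts])
        vec = np.array([1.0, 90_000.0, 30_000.0])
        expected = fit.residual_variance * (
            1.0 + vec @ np.linalg.inv(X.T @ X) @ vec
        )
        pred = predict_denominator(fit, x)
        assert pred.variance == pytest.approx(expected, rel=1e-9)

    def test_dimension_mismatch_rejected(self):
        districts, outcomes = _perfect_fixture()
        fit = fit_denominator_model(outcomes, districts, covariates=["census_population"])
        with pytest.raises(ValueError, match="missing values"):
            predict_denominator(fit, {"prior_tally": 1.0})
        with pytest.raises(ValueError, match="expects 1"):
            predict_denominator(fit, [1.0, 2.0])


class TestFrequentistCoverage:
    def test_certain_denominator(self):
        est = frequentist_coverage(50, DenominatorEstimate(100.0, 0.0, "predicted"))
        assert est.point == pytest.approx(0.5)
        assert est.variance == 0.0
        assert est.method == "frequentist_extrapolated"

    def test_cap_engages_above_one(self):
        est = frequentist_coverage(120, DenominatorEstimate(100.0, 25.0, "predicted"), cap=True)
        assert est.point == 1.0
        assert est.capped

    def test_uncapped_estimate_can_exceed_one(self):
        # the defect motivating the Bayesian layer
        est = frequentist_coverage(120, DenominatorEstimate(100.0, 25.0, "predicted"), cap=False)
        assert est.point > 1.0
        assert not est.capped

    def test_delta_variance_matches_monte_carlo(self):
        n, d, var = 90, 100.0, 25.0
        est = frequentist_coverage(n, DenominatorEstimate(d, var, "predicted"))
        rng = np.random.default_rng(11)
        draws = rng.normal(d, np.sqrt(var), size=10**6)
        assert est.variance == pytest.approx(np.var(n / draws), rel=0.03)

    def test_nonpositive_denominator_unrepresentable(self):
        # the denominator type itself refuses nonpositive points
        with pytest.raises(ValueError, match="positive"):
            DenominatorEstimate(0.0, 1.0, "predicted")
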