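"""Linear denominator model on surveyed districts and out-of-sample prediction.

The estimated denominators d_hat_j of the surveyed districts are
regressed on covariates available in every district (census population
and the previous campaign's tally, by default):

    d_hat_j = X_j beta + eps_j,

fitted by ordinary least squares.  Because the covariates exist in all
districts, the fitted model predicts denominators for the unsurveyed
ones, with new-observation (prediction-interval) variance

    Var(d_pred) = sigma^2 (1 + x' (X'X)^{-1} x),

which includes the residual term since the target is a new district's
denominator, not the conditional mean.  Dividing the known numerators by
the predicted denominators yields frequentist extrapolated coverage
estimates — which nothing constrains to stay below 1; that defect
motivates the truncated Bayesian layer in :mod:`hybridcov.bayes`.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Optional, Sequence

import numpy as np
import statsmodels.api as sm

from .types import DenominatorEstimate, DistrictRecord, PrevalenceEstimate, RegressionFit

logger = logging.getLogger("hybridcov")

Z95 = 1.959963984540054


def _design_row(record: DistrictRecord, covariates: Sequence[str]) -> Optional[list[float]]:
    row = []
    for name in covariates:
        value = record.covariate_value(name)
        if value is None:
            return None
        row.append(value)
    return row


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    null = vt[-1]
    scale = np.max(np.abs(null))
    return [name for name, v in zip(names, null) if abs(v) > 1e-8 * scale]


def fit_denominator_model(
    outcomes: Mapping[str, DenominatorEstimate],
    districts: Sequence[DistrictRecord],
    covariates: Sequence[str] = ("census_population", "prior_tally"),
    intercept: bool = True,
    weighted: bool = False,
) -> RegressionFit:
    """Fit the linear denominator model on districts with estimated denominators.

    Parameters
    ----------
    outcomes
        district_id -> denominator estimate (the regression outcome).
    districts
        District records supplying the covariate values.
    covariates
        Ordered covariate names; ``census_population``, ``prior_tally``
        or any extra column of the districts table.
    intercept
        Prepend a constant column.
    weighted
        Weight observations by 1/Var(d_hat_j) (WLS) instead of plain OLS.

    Raises
    ------
    ValueError
        If the design matrix is rank deficient (names the collinear
        columns) or there are not more districts than parameters.
    """
    by_id = {d.district_id: d for d in districts}
    unknown = sorted(set(outcomes) - set(by_id))
    if unknown:
        raise ValueError(f"outcomes reference unknown districts: {unknown}")

    ids, rows, y, w = [], [], [], []
    for district_id in outcomes:
        record = by_id[district_id]
        row = _design_row(record, covariates)
        if row is None:
            logger.warning(
                "district %s: missing covariate value, excluded from regression fit",
                district_id,
            )
            continue
        ids.append(district_id)
        rows.append(row)
        y.append(outcomes[district_id].point)
        w.append(outcomes[district_id].variance)

    X = np.asarray(rows, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    names: tuple[str, ...] = tuple(covariates)
    if intercept:
        X = np.column_stack([np.ones(len(X)), X]) if len(X) else X
        names = ("intercept",) + names
    n_fit, p = X.shape if X.ndim == 2 and len(X) else (len(X), len(names))
    if n_fit <= p:
        raise ValueError(
            f"cannot fit {p} parameters with only {n_fit} districts; "
            "need n_fit > number of parameters"
        )
    if np.linalg.matrix_rank(X) < p:
        raise ValueError(
            f"design matrix is rank deficient; collinear columns: {_collinear_columns(X, names)}"
        )

    if weighted:
        variances = np.asarray(w, dtype=float)
        if np.any(variances <= 0):
            raise ValueError("weighted fit requires strictly positive outcome variances")
        model = sm.WLS(y_arr, X, weights=1.0 / variances)
    else:
        model = sm.OLS(y_arr, X)
    res = model.fit()

    xtx_inv = np.asarray(res.normalized_cov_params, dtype=float)
    xtx_inv = (xtx_inv + xtx_inv.T) / 2.0  # enforce exact symmetry
    leverages = np.einsum("ij,jk,ik->i", X, xtx_inv, X)
    fit = RegressionFit(
        coefficients=np.asarray(res.params, dtype=float),
        residual_variance=float(res.mse_resid),
        xtx_inverse=xtx_inv,
        n_fit=int(n_fit),
        adjusted_r2=float(res.rsquared_adj),
        covariate_names=tuple(covariates),
        intercept=intercept,
        max_leverage=float(np.max(leverages)),
        district_ids=tuple(ids),
    )
    logger.info(
        "denominator model fit on %d districts, %d parameters, adjusted R^2 = %.4f",
        n_fit, p, fit.adjusted_r2,
    )
    return fit


def _covariate_vector(
    fit: RegressionFit, x: Mapping[str, float] | Sequence[float]
) -> np.ndarray:
    if isinstance(x, Mapping):
        missing = [name for name in fit.covariate_names if name not in x]
        if missing:
            raise ValueError(f"covariate row missing values for {missing}")
        values = [float(x[name]) for name in fit.covariate_names]
    else:
        values = [float(v) for v in x]
        if len(values) != len(fit.covariate_names):
            raise ValueError(
                f"covariate row has {len(values)} values; "
                f"model expects {len(fit.covariate_names)} ({list(fit.covariate_names)})"
            )
    if fit.intercept:
        values = [1.0] + values
    return np.asarray(values, dtype=float)


def predict_denominator(
    fit: RegressionFit, x: Mapping[str, float] | Sequence[float]
) -> DenominatorEstimate:
    """Predict a new district's denominator with new-observation variance.

    A leverage x'(X'X)^{-1}x above the maximum in-sample leverage means
    the covariates lie outside the fitted range; the prediction is an
    extrapolation and is logged as such.
    """
    vec = _covariate_vector(fit, x)
    point = float(vec @ fit.coefficients)
    leverage = float(vec @ fit.xtx_inverse @ vec)
    if leverage > fit.max_leverage:
        logger.warning(
            "prediction leverage %.3f exceeds max in-sample leverage %.3f: "
            "extrapolation beyond fitted range",
            leverage, fit.max_leverage,
        )
    variance = fit.residual_variance * (1.0 + leverage)
    if point <= 0:
        raise ValueError(
            f"predicted denominator is nonpositive ({point:.1f}); "
            "model unusable for this covariate row"
        )
    return DenominatorEstimate(point=point, variance=variance, source="predicted")


def prediction_leverage(fit: RegressionFit, x: Mapping[str, float] | Sequence[float]) -> float:
    vec = _covariate_vector(fit, x)
    return float(vec @ fit.xtx_inverse @ vec)


def prediction_interval(
    fit: RegressionFit, d: DenominatorEstimate, level: float = 0.95
) -> tuple[float, float]:
    """Prediction interval for a new district's denominator.

    Uses the Student-t quantile with ``n_fit - P`` degrees of freedom, as
    the residual variance is estimated from few districts; with 16
    residual df the 95% multiplier is 2.12 rather than 1.96.
    """
    from scipy import stats

    df = fit.n_fit - fit.n_parameters
    multiplier = float(stats.t.ppf(0.5 + level / 2.0, df))
    half = multiplier * math.sqrt(d.variance)
    return d.point - half, d.point + half


def frequentist_coverage(
    n: int, d: DenominatorEstimate, cap: bool = False
) -> PrevalenceEstimate:
    """Coverage estimate n / d_hat with delta-method variance.

    Without the cap the point estimate (and interval) can exceed 1 —
    the known defect of the frequentist extrapolation.  With ``cap=True``
    a point above 1 is set to 1 and flagged ``capped`` (an ad hoc fix
    with no other justification than respecting the upper bound).
    """
    if d.point <= 0:
        raise ValueError("denominator estimate must be positive")
    point = n / d.point
    variance = n**2 * d.variance / d.point**4
    se = math.sqrt(variance)
    low = max(0.0, point - Z95 * se)
    high = point + Z95 * se
    capped = False
    if cap and point > 1.0:
        point = 1.0
        capped = True
        low = min(low, point)
    return PrevalenceEstimate(
        point=point,
        variance=variance,
        n_respondents=n,
        method="frequentist_extrapolated",
        interval_low=low,
        interval_high=high,
        capped=capped,
    )
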