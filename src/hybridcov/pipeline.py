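"""End-to-end orchestration: survey estimates -> denominators -> regression
-> frequentist and Bayesian extrapolation, with full provenance."""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import bayes
from .config import AnalysisConfig
from .denominator import pool_denominators, ratio_denominator, ratio_reliable
from .extrapolation import fit_denominator_model, frequentist_coverage, predict_denominator
from .survey import estimate_prevalence
from .types import (
    CoveragePosterior,
    DenominatorEstimate,
    DistrictRecord,
    EstimateRow,
    PrevalenceEstimate,
    RegressionFit,
    SurveyResponse,
    as_estimate_row,
)

logger = logging.getLogger("hybridcov")


@dataclass
class PipelineResult:
    """Everything the pipeline produced, keyed by district and indicator."""

    rows: list[EstimateRow]
    survey_estimates: dict[tuple[str, str], PrevalenceEstimate]
    ratio_denominators: dict[tuple[str, str], DenominatorEstimate]
    pooled_denominators: dict[str, DenominatorEstimate]
    fit: RegressionFit
    predictions: dict[str, DenominatorEstimate]
    posteriors: dict[tuple[str, str], CoveragePosterior]
    districts: list[DistrictRecord]
    config: AnalysisConfig


def _group_survey(
    survey: Sequence[SurveyResponse],
) -> dict[tuple[str, str], list[SurveyResponse]]:
    grouped: dict[tuple[str, str], list[SurveyResponse]] = defaultdict(list)
    for response in survey:
        grouped[(response.district_id, response.indicator)].append(response)
    return grouped


def surveyed_denominators(
    districts: Sequence[DistrictRecord],
    survey: Sequence[SurveyResponse],
    config: AnalysisConfig,
    numerators: Optional[dict[tuple[str, str], int]] = None,
) -> tuple[
    dict[tuple[str, str], PrevalenceEstimate],
    dict[tuple[str, str], DenominatorEstimate],
    dict[str, DenominatorEstimate],
]:
    """Survey prevalences, per-indicator ratio denominators and the pooled
    regression outcome for every surveyed district.

    ``numerators`` optionally overrides the tallies (used by the
    sensitivity analysis when numerator shifts are propagated into the
    denominator model).
    """
    grouped = _group_survey(survey)
    surveyed_ids = {d.district_id for d in districts if d.surveyed}
    for district_id, _ in grouped:
        if district_id not in surveyed_ids:
            raise ValueError(
                f"survey responses for district {district_id!r}, which is not "
                "flagged as surveyed in the districts table"
            )

    prevalences: dict[tuple[str, str], PrevalenceEstimate] = {}
    ratios: dict[tuple[str, str], DenominatorEstimate] = {}
    pooled: dict[str, DenominatorEstimate] = {}
    for district in districts:
        if not district.surveyed:
            continue
        components: list[DenominatorEstimate] = []
        for indicator in config.indicators:
            key = (district.district_id, indicator)
            responses = grouped.get(key)
            if not responses:
                logger.warning(
                    "surveyed district %s has no responses for indicator %s",
                    district.district_id, indicator,
                )
                continue
            try:
                p_hat = estimate_prevalence(responses)
            except ValueError as exc:
                raise ValueError(f"district {district.district_id}: {exc}") from exc
            prevalences[key] = p_hat
            n = numerators.get(key) if numerators else district.tallies.get(indicator)
            if n is None:
                n = district.tallies.get(indicator, 0)
            if n <= 0 or p_hat.point <= 0:
                logger.warning(
                    "district %s indicator %s: tally %s, prevalence %.3f — "
                    "no ratio denominator possible",
                    district.district_id, indicator, n, p_hat.point,
                )
                continue
            if not ratio_reliable(p_hat, config.min_ratio_successes):
                logger.warning(
                    "district %s indicator %s: prevalence %.3f too close to zero "
                    "for a reliable ratio denominator; excluded from the regression",
                    district.district_id, indicator, p_hat.point,
                )
                continue
            estimate = ratio_denominator(n, _regularize_degenerate(p_hat))
            ratios[key] = estimate
            if config.denominator_indicator is None or indicator == config.denominator_indicator:
                components.append(estimate)
        if components:
            pooled[district.district_id] = (
                pool_denominators(components) if len(components) > 1 else components[0]
            )
    logger.info(
        "surveyed-district denominators: %d districts with a regression outcome",
        len(pooled),
    )
    return prevalences, ratios, pooled


def _regularize_degenerate(p_hat: PrevalenceEstimate) -> PrevalenceEstimate:
    """Floor the variance of a degenerate (all-ones) survey estimate.

    p_hat = 1 with variance 0 would make the ratio denominator exactly n
    with infinite pooling weight, and two indicators then clash.  Using
    the shrunk proportion (x + 1/2)/(m + 1) for the variance keeps the
    point estimate while acknowledging the small-sample uncertainty.
    """
    if p_hat.variance > 0 or p_hat.point < 1.0:
        return p_hat
    m = p_hat.n_respondents
    p_shrunk = (m + 0.5) / (m + 1.0)
    variance = p_shrunk * (1.0 - p_shrunk) / m
    return PrevalenceEstimate(
        point=p_hat.point,
        variance=variance,
        n_respondents=m,
        method=p_hat.method,
        interval_low=p_hat.interval_low,
        interval_high=p_hat.interval_high,
        capped=p_hat.capped,
    )


def _bayes_estimate(
    district_id: str,
    indicator: str,
    n: int,
    prediction: DenominatorEstimate,
    config: AnalysisConfig,
) -> tuple[PrevalenceEstimate, CoveragePosterior]:
    seed = bayes.district_seed(config.seed, f"{district_id}/{indicator}")
    model = config.denominator_model
    try:
        draws = bayes.sample_denominators(prediction, n, config.draws, seed, model=model)
    except ValueError as exc:
        if model == "negbin" and prediction.variance <= prediction.point:
            logger.warning(
                "district %s indicator %s: %s — using the normal model instead",
                district_id, indicator, exc,
            )
            model = "normal"
            draws = bayes.sample_denominators(prediction, n, config.draws, seed, model=model)
        else:
            raise ValueError(f"district {district_id}: {exc}") from exc
    posterior = bayes.coverage_posterior(
        n, draws, district_id, denominator_model=model, indicator=indicator
    )
    estimate = PrevalenceEstimate(
        point=posterior.median,
        variance=float(np.var(posterior.draws)),
        n_respondents=n,
        method="bayesian",
        interval_low=posterior.ci_low,
        interval_high=posterior.ci_high,
    )
    return estimate, posterior


def run_pipeline(
    districts: Sequence[DistrictRecord],
    survey: Sequence[SurveyResponse],
    config: Optional[AnalysisConfig] = None,
) -> PipelineResult:
    """Run the full hybrid extrapolation pipeline.

    Surveyed districts receive their design-based survey estimates (with
    ratio denominators); unsurveyed districts receive both the frequentist
    extrapolated estimate (which may exceed 1) and the truncated Bayesian
    estimate (which cannot).
    """
    config = config or AnalysisConfig()
    districts = list(districts)
    for district in districts:
        missing = [i for i in config.indicators if i not in district.tallies]
        if missing:
            raise ValueError(
                f"district {district.district_id}: missing tallies for indicators {missing}"
            )

    prevalences, ratios, pooled = surveyed_denominators(districts, survey, config)
    fit = fit_denominator_model(
        pooled,
        districts,
        covariates=config.covariates,
        intercept=config.intercept,
        weighted=config.weighted_fit,
    )

    rows: list[EstimateRow] = []
    predictions: dict[str, DenominatorEstimate] = {}
    posteriors: dict[tuple[str, str], CoveragePosterior] = {}
    n_skipped = 0
    for district in districts:
        if district.surveyed:
            for indicator in config.indicators:
                key = (district.district_id, indicator)
                if key not in prevalences:
                    continue
                rows.append(
                    as_estimate_row(
                        district.district_id, indicator, prevalences[key], ratios.get(key)
                    )
                )
            continue

        x = {name: district.covariate_value(name) for name in config.covariates}
        if any(v is None for v in x.values()):
            logger.warning(
                "district %s: missing covariates %s — no extrapolated estimate",
                district.district_id,
                [k for k, v in x.items() if v is None],
            )
            n_skipped += 1
            continue
        try:
            prediction = predict_denominator(fit, x)
        except ValueError as exc:
            raise ValueError(f"district {district.district_id}: {exc}") from exc
        predictions[district.district_id] = prediction

        for indicator in config.indicators:
            n = district.tallies[indicator]
            if n <= 0:
                logger.warning(
                    "district %s indicator %s: zero tally — coverage reported as 0 "
                    "(frequentist only)", district.district_id, indicator,
                )
                rows.append(
                    as_estimate_row(
                        district.district_id,
                        indicator,
                        PrevalenceEstimate(
                            point=0.0, variance=0.0, n_respondents=0,
                            method="frequentist_extrapolated",
                            interval_low=0.0, interval_high=0.0,
                        ),
                        prediction,
                    )
                )
                continue
            freq = frequentist_coverage(n, prediction, cap=config.cap_frequentist)
            rows.append(as_estimate_row(district.district_id, indicator, freq, prediction))
            estimate, posterior = _bayes_estimate(
                district.district_id, indicator, n, prediction, config
            )
            posteriors[(district.district_id, indicator)] = posterior
            rows.append(as_estimate_row(district.district_id, indicator, estimate, prediction))

    logger.info(
        "pipeline: %d districts (%d surveyed, %d predicted, %d skipped), %d estimate rows",
        len(districts), sum(d.surveyed for d in districts), len(predictions), n_skipped, len(rows),
    )
    return PipelineResult(
        rows=rows,
        survey_estimates=prevalences,
        ratio_denominators=ratios,
        pooled_denominators=pooled,
        fit=fit,
        predictions=predictions,
        posteriors=posteriors,
        districts=districts,
        config=config,
    )
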