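"""Sensitivity of Bayesian coverage estimates to bias in the tallies.

Administrative numerators may be systematically over- or under-counted.
For each signed fraction delta, the numerators are shifted to
n' = round((1 + delta) n) and the coverage posteriors recomputed with
common random numbers: the same per-district uniforms are pushed through
the denominator distribution re-truncated at n', so the change in the
posterior medians reflects the numerator shift alone, not Monte Carlo
noise.  Where the truncation never binds this makes the shift an exact
monotone rescaling of the coverage draws.

Because coverage is bounded above by 1, an upward numerator bias moves
the medians less than the corresponding downward bias — the asymmetry is
the signature of the truncation.

By default the fitted denominator model is held fixed and only the
coverage-step numerators are shifted.  With ``propagate=True`` the
surveyed-district ratio denominators are also recomputed from the
shifted tallies and the model refitted, shifting the predictions
themselves.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import bayes
from .extrapolation import fit_denominator_model, predict_denominator
from .pipeline import PipelineResult, surveyed_denominators

logger = logging.getLogger("hybridcov")

SENSITIVITY_COLUMNS = (
    "district_id", "indicator", "delta", "median", "low95", "high95",
    "change_vs_baseline",
)


def sensitivity_analysis(
    result: PipelineResult,
    deltas: Optional[Sequence[float]] = None,
    draws: Optional[int] = None,
    seed: Optional[int] = None,
    propagate: Optional[bool] = None,
    survey=None,
) -> pd.DataFrame:
    """Recompute Bayesian coverage under shifted numerators.

    Returns a table with one row per unsurveyed district x indicator x
    delta (delta = 0 is the baseline), with the posterior median, 95%
    credible limits and the change in median versus baseline.
    """
    config = result.config
    deltas = config.sensitivity_deltas if deltas is None else tuple(float(d) for d in deltas)
    draws = config.draws if draws is None else int(draws)
    seed = config.seed if seed is None else int(seed)
    propagate = config.propagate_sensitivity if propagate is None else bool(propagate)
    for delta in deltas:
        if delta <= -1.0:
            raise ValueError(f"delta must exceed -1, got {delta}")
    all_deltas = (0.0,) + tuple(d for d in deltas if d != 0.0)

    by_id = {d.district_id: d for d in result.districts}
    targets = [
        (district_id, indicator)
        for district_id in result.predictions
        for indicator in config.indicators
        if by_id[district_id].tallies.get(indicator, 0) > 0
    ]

    # one uniform stream per district x indicator, shared across deltas
    uniforms = {
        key: np.random.default_rng(bayes.district_seed(seed, f"{key[0]}/{key[1]}")).random(draws)
        for key in targets
    }

    records = []
    baseline: dict[tuple[str, str], float] = {}
    for delta in all_deltas:
        if propagate and delta != 0.0:
            if survey is None:
                raise ValueError(
                    "propagate=True requires the survey responses; pass survey="
                )
            numerators = {
                (d.district_id, i): int(round((1.0 + delta) * d.tallies[i]))
                for d in result.districts
                if d.surveyed
                for i in config.indicators
            }
            _, _, pooled = surveyed_denominators(
                result.districts, survey, config, numerators=numerators
            )
            fit = fit_denominator_model(
                pooled, result.districts, covariates=config.covariates,
                intercept=config.intercept, weighted=config.weighted_fit,
            )
            predictions = {
                district_id: predict_denominator(
                    fit,
                    {
                        name: by_id[district_id].covariate_value(name)
                        for name in config.covariates
                    },
                )
                for district_id, _ in dict.fromkeys(targets)
            }
        else:
            predictions = result.predictions

        for district_id, indicator in targets:
            n_shifted = int(round((1.0 + delta) * by_id[district_id].tallies[indicator]))
            if n_shifted <= 0:
                logger.warning(
                    "district %s indicator %s: shifted numerator is zero at delta %.2f",
                    district_id, indicator, delta,
                )
                continue
            prediction = predictions[district_id]
            model = config.denominator_model
            if model == "negbin" and prediction.variance <= prediction.point:
                model = "normal"
            denom_draws = bayes.sample_denominators(
                prediction, n_shifted, draws, seed=0, model=model,
                uniforms=uniforms[(district_id, indicator)],
            )
            posterior = bayes.coverage_posterior(
                n_shifted, denom_draws, district_id,
                denominator_model=model, indicator=indicator,
            )
            key = (district_id, indicator)
            if delta == 0.0:
                baseline[key] = posterior.median
            records.append(
                {
                    "district_id": district_id,
                    "indicator": indicator,
                    "delta": delta,
                    "median": posterior.median,
                    "low95": posterior.ci_low,
                    "high95": posterior.ci_high,
                    "change_vs_baseline": posterior.median - baseline[key],
                }
            )
    return pd.DataFrame.from_records(records, columns=list(SENSITIVITY_COLUMNS))


def summarize_sensitivity(table: pd.DataFrame) -> pd.DataFrame:
    """Average change in median coverage per delta, across districts."""
    nonzero = table[table["delta"] != 0.0]
    summary = (
        nonzero.groupby("delta")["change_vs_baseline"]
        .agg(mean_change="mean", mean_abs_change=lambda s: s.abs().mean())
        .reset_index()
    )
    return summary
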