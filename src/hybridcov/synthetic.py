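"""Synthetic-country generator with known ground truth.

The real campaign and survey data this methodology was developed on are
not publicly deposited, so validation rests on simulated countries that
reproduce their statistical structure: 77 districts of which 19 carry a
stratified survey (five supervision areas of 19 children each, one
district with only four), high true coverage (mean about 0.87, SD about
0.09), and census/prior-tally covariates strongly correlated with the
true eligible-child populations.

Generation model, per district j:

* true denominator d*_j ~ lognormal (median about 17,000 eligible
  children, matching a median district population of about 100,000 with
  a 0.17 child share);
* true coverage p*_{jk} ~ Beta per indicator k, and a prior-campaign
  coverage q_j from the same Beta;
* recorded numerator n_{jk} = round(tally_bias * Binomial(d*_j, p*_{jk}));
* census_j = round(d*_j / under5_fraction * (1 + eps)),
  prior_tally_j = round(d*_j * q_j * (1 + eps')), with eps, eps' centered
  normal measurement noise whose coefficients of variation control how
  predictive the covariates are;
* for surveyed districts, each child's response is Bernoulli(p*_{jk}),
  i.i.d. within the district by default (``sa_sigma`` adds a logit-scale
  supervision-area random effect).

Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import DistrictRecord, EstimateRow, SurveyResponse


@dataclass
class SimulationConfig:
    """Parameters of the synthetic country.

    The defaults mirror the study design the package targets: 77
    districts, 19 surveyed with 5 supervision areas x 19 children (one
    district with 4 SAs, hence 1786 respondents in total), coverage
    centered at 0.87 with SD 0.09, and covariates that predict the true
    denominators with correlation above 0.9.
    """

    n_districts: int = 77
    n_surveyed: int = 19
    sas_per_district: int = 5
    children_per_sa: int = 19
    irregular_district: bool = True  # one surveyed district has one fewer SA
    population_log_mean: float = 9.743  # median ~17,000 eligible children
    population_log_sd: float = 0.394  # matches an IQR ratio of ~1.7 in district size
    coverage_alpha: float = 11.28  # Beta(11.28, 1.69): mean 0.871, SD 0.090
    coverage_beta: float = 1.69
    under5_fraction: float = 0.17
    census_noise_cv: float = 0.08
    prior_tally_noise_cv: float = 0.08
    tally_bias: float = 1.0
    sa_sigma: float = 0.0
    indicators: tuple[str, ...] = ("polio", "vas")
    seed: int = 20150101

    def __post_init__(self) -> None:
        self.indicators = tuple(self.indicators)
        if self.n_surveyed > self.n_districts:
            raise ValueError("n_surveyed cannot exceed n_districts")
        for name in ("n_districts", "n_surveyed", "sas_per_district", "children_per_sa"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.coverage_alpha <= 0 or self.coverage_beta <= 0:
            raise ValueError("Beta coverage parameters must be positive")
        if self.population_log_sd < 0:
            raise ValueError("population_log_sd must be nonnegative")
        if not 0 < self.under5_fraction <= 1:
            raise ValueError("under5_fraction must be in (0, 1]")
        if self.tally_bias <= 0:
            raise ValueError("tally_bias must be positive")


@dataclass
class GroundTruth:
    """The unobservable quantities the estimators target, for one district."""

    district_id: str
    true_denominator: int
    true_coverage: dict[str, float]
    surveyed: bool


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_country(
    config: Optional[SimulationConfig] = None,
) -> tuple[list[DistrictRecord], list[SurveyResponse], list[GroundTruth]]:
    """Generate one synthetic country: districts, survey responses, truth."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_districts
    indicators = config.indicators

    d_star = np.maximum(
        1, np.round(rng.lognormal(config.population_log_mean, config.population_log_sd, n))
    ).astype(np.int64)
    p_true = rng.beta(config.coverage_alpha, config.coverage_beta, size=(n, len(indicators)))
    q_prior = rng.beta(config.coverage_alpha, config.coverage_beta, size=n)

    tallies = np.round(
        config.tally_bias * rng.binomial(d_star[:, None], p_true)
    ).astype(np.int64)
    census = np.maximum(
        1,
        np.round(
            d_star / config.under5_fraction
            * (1.0 + config.census_noise_cv * rng.standard_normal(n))
        ),
    ).astype(np.int64)
    prior_tally = np.maximum(
        0,
        np.round(
            d_star * q_prior
            * (1.0 + config.prior_tally_noise_cv * rng.standard_normal(n))
        ),
    ).astype(np.int64)

    surveyed_idx = np.sort(rng.choice(n, size=config.n_surveyed, replace=False))
    surveyed = np.zeros(n, dtype=bool)
    surveyed[surveyed_idx] = True
    # the irregular (one-SA-short) district is the last surveyed one
    irregular_id = surveyed_idx[-1] if config.irregular_district else -1

    width = max(3, len(str(n)))
    ids = [f"d{j + 1:0{width}d}" for j in range(n)]

    districts = [
        DistrictRecord(
            district_id=ids[j],
            census_population=int(census[j]),
            prior_tally=int(prior_tally[j]),
            tallies={ind: int(tallies[j, k]) for k, ind in enumerate(indicators)},
            surveyed=bool(surveyed[j]),
        )
        for j in range(n)
    ]

    responses: list[SurveyResponse] = []
    for j in surveyed_idx:
        n_sas = config.sas_per_district - (1 if j == irregular_id else 0)
        for k, indicator in enumerate(indicators):
            p_district = p_true[j, k]
            for sa in range(1, n_sas + 1):
                if config.sa_sigma > 0:
                    logit = np.log(p_district / (1 - p_district))
                    p_sa = float(_logistic(logit + config.sa_sigma * rng.standard_normal()))
                else:
                    p_sa = float(p_district)
                values = rng.binomial(1, p_sa, size=config.children_per_sa)
                responses.extend(
                    SurveyResponse(
                        district_id=ids[j],
                        sa_id=f"sa{sa}",
                        indicator=indicator,
                        response=int(v),
                    )
                    for v in values
                )

    truth = [
        GroundTruth(
            district_id=ids[j],
            true_denominator=int(d_star[j]),
            true_coverage={ind: float(p_true[j, k]) for k, ind in enumerate(indicators)},
            surveyed=bool(surveyed[j]),
        )
        for j in range(n)
    ]
    return districts, responses, truth


def truth_frame(truth: Sequence[GroundTruth]) -> pd.DataFrame:
    indicators = sorted({ind for t in truth for ind in t.true_coverage})
    return pd.DataFrame(
        [
            {
                "district_id": t.district_id,
                "true_denominator": t.true_denominator,
                "surveyed": t.surveyed,
                **{f"true_coverage_{ind}": t.true_coverage[ind] for ind in indicators},
            }
            for t in truth
        ]
    )


def write_truth(truth: Sequence[GroundTruth], path: str | Path) -> None:
    truth_frame(truth).to_csv(path, index=False)


def evaluate_recovery(
    estimates: Sequence[EstimateRow] | pd.DataFrame,
    truth: Sequence[GroundTruth],
) -> pd.DataFrame:
    """Compare estimates against ground truth, per estimation method.

    Returns one row per method with: number of estimates, mean coverage
    bias (estimate minus truth), mean absolute error, relative RMSE,
    empirical 95%-interval coverage of the truth, fraction of point
    estimates above 1, and — where a denominator accompanies the row —
    the denominator's relative bias and relative RMSE.
    """
    if isinstance(estimates, pd.DataFrame):
        frame = estimates.copy()
    else:
        frame = pd.DataFrame(
            [
                {
                    "district_id": r.district_id,
                    "indicator": r.indicator,
                    "method": r.method,
                    "point": r.point,
                    "low95": r.low95,
                    "high95": r.high95,
                    "denominator": r.denominator,
                }
                for r in estimates
            ]
        )
    truth_by_id = {t.district_id: t for t in truth}
    unknown = sorted(set(frame["district_id"]) - set(truth_by_id))
    if unknown:
        raise ValueError(f"estimates reference districts absent from truth: {unknown}")

    frame["true_coverage"] = [
        truth_by_id[row.district_id].true_coverage[row.indicator]
        for row in frame.itertuples()
    ]
    frame["true_denominator"] = [
        truth_by_id[row.district_id].true_denominator for row in frame.itertuples()
    ]

    records = []
    for method, group in frame.groupby("method"):
        error = group["point"] - group["true_coverage"]
        covered = (group["low95"] <= group["true_coverage"]) & (
            group["true_coverage"] <= group["high95"]
        )
        record = {
            "method": method,
            "n": len(group),
            "coverage_bias": float(error.mean()),
            "coverage_mae": float(error.abs().mean()),
            "coverage_rel_rmse": float(
                np.sqrt(np.mean((error / group["true_coverage"]) ** 2))
            ),
            "interval_coverage": float(covered.mean()),
            "frac_above_one": float((group["point"] > 1.0).mean()),
        }
        with_denominator = group.dropna(subset=["denominator"])
        if len(with_denominator):
            rel = (
                with_denominator["denominator"] - with_denominator["true_denominator"]
            ) / with_denominator["true_denominator"]
            record["denominator_rel_bias"] = float(rel.mean())
            record["denominator_rel_rmse"] = float(np.sqrt(np.mean(rel**2)))
        else:
            record["denominator_rel_bias"] = np.nan
            record["denominator_rel_rmse"] = np.nan
        records.append(record)
    return pd.DataFrame.from_records(records).set_index("method")
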