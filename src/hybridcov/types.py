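"""Core domain types shared by every stage of the pipeline.

The estimation problem has three kinds of quantities: prevalences
(coverage proportions), denominators (eligible-population sizes), and
the administrative records they are computed from.  Each estimate
carries its variance and a provenance tag so that downstream stages —
and final output files — always know how a number was obtained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np


class SchemaError(ValueError):
    """An input table is missing a required column."""


class ValidationError(ValueError):
    """A row of an input table violates a type invariant."""


#: provenance tags for prevalence estimates
PREVALENCE_METHODS = ("survey", "frequentist_extrapolated", "bayesian")

#: provenance tags for denominator estimates
DENOMINATOR_SOURCES = ("ratio", "pooled", "predicted")


@dataclass
class DistrictRecord:
    """Administrative data for one district.

    ``tallies`` maps indicator name (e.g. ``"polio"``) to the number of
    children recorded as served at the current campaign.  ``census_population``
    is the total population from the most recent census and ``prior_tally``
    the count served at the campaign six months earlier; both serve as
    covariates when extrapolating denominators.  Either may be ``None``
    (missing), which excludes the district from the regression stage.
    """

    district_id: str
    census_population: Optional[int]
    prior_tally: Optional[int]
    tallies: dict[str, int]
    surveyed: bool
    department: Optional[str] = None
    extra: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in self.tallies.items():
            if value < 0:
                raise ValidationError(
                    f"district {self.district_id!r}: tally {name!r} is negative ({value})"
                )
        for label, value in (
            ("census_population", self.census_population),
            ("prior_tally", self.prior_tally),
        ):
            if value is not None and value < 0:
                raise ValidationError(
                    f"district {self.district_id!r}: {label} is negative ({value})"
                )

    def covariate_value(self, name: str) -> Optional[float]:
        """Look up a covariate by name (built-in field or extra column)."""
        if name == "census_population":
            return None if self.census_population is None else float(self.census_population)
        if name == "prior_tally":
            return None if self.prior_tally is None else float(self.prior_tally)
        value = self.extra.get(name)
        return None if value is None or (isinstance(value, float) and np.isnan(value)) else float(value)


@dataclass
class SurveyResponse:
    """One child's binary response for one indicator.

    ``sa_id`` identifies the supervision area (sampling stratum) within
    the district.
    """

    district_id: str
    sa_id: str
    indicator: str
    response: int

    def __post_init__(self) -> None:
        if self.response not in (0, 1):
            raise ValidationError(
                f"district {self.district_id!r} SA {self.sa_id!r}: "
                f"response must be 0 or 1, got {self.response}"
            )


@dataclass
class PrevalenceEstimate:
    """A coverage proportion with its variance and 95% interval."""

    point: float
    variance: float
    n_respondents: int
    method: str
    interval_low: float
    interval_high: float
    capped: bool = False

    def __post_init__(self) -> None:
        if self.method not in PREVALENCE_METHODS:
            raise ValueError(f"unknown prevalence method {self.method!r}")
        if self.variance < 0:
            raise ValueError("variance must be nonnegative")
        if not (self.interval_low <= self.point <= self.interval_high):
            raise ValueError(
                f"interval [{self.interval_low}, {self.interval_high}] "
                f"does not bracket point {self.point}"
            )
        if self.method == "bayesian" and self.interval_high > 1.0:
            raise ValueError("Bayesian interval upper limit exceeds 1")


@dataclass
class DenominatorEstimate:
    """An eligible-population size with variance and provenance."""

    point: float
    variance: float
    source: str

    def __post_init__(self) -> None:
        if self.source not in DENOMINATOR_SOURCES:
            raise ValueError(f"unknown denominator source {self.source!r}")
        if self.point <= 0:
            raise ValueError("denominator point estimate must be positive")
        if self.variance < 0:
            raise ValueError("denominator variance must be nonnegative")


@dataclass
class RegressionFit:
    """A fitted linear denominator model with everything needed for
    out-of-sample prediction variance.

    ``xtx_inverse`` is :math:`(X'X)^{-1}` (or :math:`(X'WX)^{-1}` for a
    weighted fit), so that the prediction variance at a new covariate row
    ``x`` is ``residual_variance * (1 + x' xtx_inverse x)``.
    """

    coefficients: np.ndarray
    residual_variance: float
    xtx_inverse: np.ndarray
    n_fit: int
    adjusted_r2: float
    covariate_names: tuple[str, ...]
    intercept: bool
    max_leverage: float
    district_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.xtx_inverse = np.asarray(self.xtx_inverse, dtype=float)
        p = self.coefficients.shape[0]
        if self.xtx_inverse.shape != (p, p):
            raise ValueError("xtx_inverse shape does not match coefficients")
        if self.n_fit <= p:
            raise ValueError("n_fit must exceed the number of parameters")
        if not np.allclose(self.xtx_inverse, self.xtx_inverse.T, rtol=1e-8, atol=1e-12):
            raise ValueError("xtx_inverse must be symmetric")

    @property
    def n_parameters(self) -> int:
        return int(self.coefficients.shape[0])

    @property
    def parameter_names(self) -> tuple[str, ...]:
        names = ("intercept",) if self.intercept else ()
        return names + tuple(self.covariate_names)


@dataclass
class CoveragePosterior:
    """Monte Carlo draws of coverage for one district, with summaries.

    Every draw lies in (0, 1] by construction: the denominator draws are
    truncated below at the numerator ``truncation_bound``.
    """

    district_id: str
    draws: np.ndarray
    truncation_bound: int
    median: float
    ci_low: float
    ci_high: float
    denominator_model: str
    indicator: Optional[str] = None

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.denominator_model not in ("normal", "negbin"):
            raise ValueError(f"unknown denominator model {self.denominator_model!r}")
        if not (self.ci_low <= self.median <= self.ci_high <= 1.0):
            raise ValueError("posterior summaries must satisfy ci_low <= median <= ci_high <= 1")


@dataclass
class EstimateRow:
    """One output row: a district x indicator x method estimate with its
    denominator, ready for serialization."""

    district_id: str
    indicator: str
    method: str
    point: float
    variance: float
    low95: float
    high95: float
    capped: bool
    denominator: Optional[float]
    denominator_variance: Optional[float]
    denominator_source: Optional[str]


def as_estimate_row(
    district_id: str,
    indicator: str,
    prevalence: PrevalenceEstimate,
    denominator: Optional[DenominatorEstimate],
) -> EstimateRow:
    return EstimateRow(
        district_id=district_id,
        indicator=indicator,
        method=prevalence.method,
        point=prevalence.point,
        variance=prevalence.variance,
        low95=prevalence.interval_low,
        high95=prevalence.interval_high,
        capped=prevalence.capped,
        denominator=None if denominator is None else denominator.point,
        denominator_variance=None if denominator is None else denominator.variance,
        denominator_source=None if denominator is None else denominator.source,
    )
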