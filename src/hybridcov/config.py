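"""Analysis configuration: indicators, covariates, Monte Carlo settings."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import yaml


@dataclass
class AnalysisConfig:
    """Settings for a full pipeline run.

    Parameters
    ----------
    indicators
        Indicator names; each district table must carry a ``tally_<name>``
        column and the survey table responses for each.
    covariates
        Covariate columns for the denominator regression.  A single-entry
        list (e.g. census only) gives the reduced single-covariate model.
    intercept
        Include an intercept in the regression (default True).
    draws
        Monte Carlo draws per district for the Bayesian layer.
    seed
        Master seed; each district receives an independent substream
        derived from (seed, district_id), so results do not depend on
        district ordering.
    denominator_model
        ``"normal"`` (truncated normal denominators) or ``"negbin"``
        (truncated negative binomial; requires variance > mean).
    sensitivity_deltas
        Signed fractional shifts applied to the numerators in the
        sensitivity analysis.
    cap_frequentist
        If True, frequentist extrapolated coverage above 1 is capped at 1
        (an ad hoc fix; the Bayesian layer is the principled one).
    denominator_indicator
        If set, the regression outcome uses only this indicator's ratio
        denominator instead of the inverse-variance pooled one.
    weighted_fit
        Fit the regression by WLS with weights 1/Var(d_hat_j) instead of
        plain OLS.
    propagate_sensitivity
        If True the sensitivity analysis also refits the denominator model
        with shifted numerators; by default only the coverage-step
        numerators are shifted.
    min_ratio_successes
        Guard for the ratio denominator: a survey prevalence below
        ``min_ratio_successes / n_respondents`` is considered too close to
        zero for the delta method and the district is excluded from the
        regression fit for that indicator.
    """

    indicators: tuple[str, ...] = ("polio", "vas")
    covariates: tuple[str, ...] = ("census_population", "prior_tally")
    intercept: bool = True
    draws: int = 10_000
    seed: int = 20150101
    denominator_model: str = "normal"
    sensitivity_deltas: tuple[float, ...] = (-0.10, -0.05, 0.05, 0.10)
    cap_frequentist: bool = False
    denominator_indicator: Optional[str] = None
    weighted_fit: bool = False
    propagate_sensitivity: bool = False
    min_ratio_successes: float = 5.0

    def __post_init__(self) -> None:
        self.indicators = tuple(self.indicators)
        self.covariates = tuple(self.covariates)
        self.sensitivity_deltas = tuple(float(d) for d in self.sensitivity_deltas)
        if not self.indicators:
            raise ValueError("at least one indicator is required")
        if self.denominator_model not in ("normal", "negbin"):
            raise ValueError(f"unknown denominator model {self.denominator_model!r}")
        if self.draws < 1:
            raise ValueError("draws must be >= 1")
        for d in self.sensitivity_deltas:
            if d <= -1:
                raise ValueError("sensitivity deltas must exceed -1")
        if self.denominator_indicator is not None and self.denominator_indicator not in self.indicators:
            raise ValueError(
                f"denominator_indicator {self.denominator_indicator!r} not among indicators"
            )

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = set(AnalysisConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**raw)


def save_config(config: AnalysisConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in config.to_dict().items()},
            fh,
            sort_keys=False,
        )
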