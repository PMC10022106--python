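import logging

import pytest

from hybridcov import (
    AnalysisConfig,
    DistrictRecord,
    PrevalenceEstimate,
    SurveyResponse,
)
from hybridcov.synthetic import SimulationConfig, generate_country


@pytest.fixture(autouse=True)
def _quiet_logs(caplog):
    # warnings (extrapolation leverage etc.) are expected on synthetic data
    logging.getLogger("hybridcov").setLevel(logging.ERROR)
    yield


@pytest.fixture(scope="session")
def default_country():
    """One synthetic country at the default design (77 districts, 19 surveyed)."""
    return generate_country(SimulationConfig(seed=20150101))


@pytest.fixture(scope="session")
def small_pipeline_result(default_country):
    from hybridcov import run_pipeline

    districts, survey, _ = default_country
    return run_pipeline(districts, survey, AnalysisConfig(draws=2000))


def make_survey_district(district_id, sa_successes, sa_size=19, indicator="polio"):
    """Responses for one district given per-SA success counts."""
    responses = []
    for h, successes in enumerate(sa_successes, start=1):
        values = [1] * successes + [0] * (sa_size - successes)
        responses.extend(
            SurveyResponse(district_id, f"sa{h}", indicator, v) for v in values
        )
    return responses


def make_district(district_id, census, prior, tally, surveyed, indicator="polio"):
    return DistrictRecord(
        district_id=district_id,
        census_population=census,
        prior_tally=prior,
        tallies={indicator: tally},
        surveyed=surveyed,
    )


def exact_prevalence(point, variance=0.0, n=95, method="survey"):
    import math

    se = math.sqrt(variance)
    return PrevalenceEstimate(
        point=point,
        variance=variance,
        n_respondents=n,
        method=method,
        interval_low=max(0.0, point - 1.96 * se),
        interval_high=min(1.0, point + 1.96 * se) if method != "frequentist_extrapolated" else point + 1.96 * se,
    )
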