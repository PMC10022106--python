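"""Design-based prevalence estimation from stratified small-sample surveys.

Districts are surveyed through a stratified design: each district is
partitioned into supervision areas (SAs) and a fixed number of children
is sampled at random within each SA.  The SAs are the strata; with
equal-size strata of similar populations the default stratum weights are
equal.

For stratum h with m_h respondents and stratum proportion p_h, the
district estimate is

    p = sum_h W_h p_h,        Var(p) = sum_h W_h^2 s_h^2 / m_h,

with s_h^2 = m_h/(m_h - 1) * p_h (1 - p_h) the unbiased within-stratum
variance and W_h the normalized stratum weights.  No finite-population
correction is applied: stratum populations are far larger than the
sample of 19 children.
"""

from __future__ import annotations

import math
from collections import defaultdict
from typing import Iterable, Mapping, Optional

from .types import PrevalenceEstimate, SurveyResponse

Z95 = 1.959963984540054  # standard normal 97.5% quantile


def estimate_prevalence(
    responses: Iterable[SurveyResponse],
    sa_weights: Optional[Mapping[str, float]] = None,
) -> PrevalenceEstimate:
    """Stratified prevalence estimate for one district and one indicator.

    Parameters
    ----------
    responses
        Survey responses, all from a single district and indicator.
    sa_weights
        Optional population weights per supervision area; normalized
        internally.  Default: equal weights.

    Raises
    ------
    ValueError
        On empty input, mixed districts/indicators, or a stratum with
        fewer than two responses (the within-stratum variance needs
        m_h >= 2).
    """
    responses = list(responses)
    if not responses:
        raise ValueError("no survey responses supplied")
    districts = {r.district_id for r in responses}
    indicators = {r.indicator for r in responses}
    if len(districts) > 1 or len(indicators) > 1:
        raise ValueError(
            f"responses must come from one district and one indicator, "
            f"got districts {sorted(districts)} indicators {sorted(indicators)}"
        )

    by_sa: dict[str, list[int]] = defaultdict(list)
    for r in responses:
        by_sa[r.sa_id].append(r.response)

    strata = sorted(by_sa)
    if sa_weights is None:
        weights = {h: 1.0 for h in strata}
    else:
        missing = [h for h in strata if h not in sa_weights]
        if missing:
            raise ValueError(f"sa_weights missing strata {missing}")
        weights = {h: float(sa_weights[h]) for h in strata}
        if any(w <= 0 for w in weights.values()):
            raise ValueError("stratum weights must be positive")
    total_weight = sum(weights.values())

    point = 0.0
    variance = 0.0
    n_total = 0
    for h in strata:
        values = by_sa[h]
        m_h = len(values)
        if m_h < 2:
            raise ValueError(
                f"stratum {h!r} has {m_h} response(s); at least 2 are required "
                "for the within-stratum variance"
            )
        w_h = weights[h] / total_weight
        p_h = sum(values) / m_h
        s2_h = m_h / (m_h - 1) * p_h * (1.0 - p_h)
        point += w_h * p_h
        variance += w_h**2 * s2_h / m_h
        n_total += m_h

    se = math.sqrt(variance)
    return PrevalenceEstimate(
        point=point,
        variance=variance,
        n_respondents=n_total,
        method="survey",
        interval_low=max(0.0, min(point, point - Z95 * se)),
        interval_high=min(1.0, max(point, point + Z95 * se)),
    )


def survey_sample_sizes(
    responses: Iterable[SurveyResponse], indicator: Optional[str] = None
) -> dict[str, int]:
    """Respondent counts per district.

    When the table contains several indicators the same children answer
    each, so counts are computed per indicator; they must agree across
    indicators unless a specific one is requested.
    """
    counts: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for r in responses:
        counts[r.indicator][r.district_id] += 1
    if not counts:
        return {}
    if indicator is not None:
        if indicator not in counts:
            raise ValueError(f"indicator {indicator!r} not present in survey table")
        return dict(counts[indicator])
    per_indicator = [dict(c) for c in counts.values()]
    first = per_indicator[0]
    for other in per_indicator[1:]:
        if other != first:
            raise ValueError(
                "respondent counts differ across indicators; "
                "pass indicator= to disambiguate"
            )
    return first
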