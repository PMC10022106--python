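"""Ratio estimation of district denominators and pooling across indicators.

In a surveyed district the campaign tally n (children served) and the
survey prevalence estimate p relate to the unknown eligible population d
through p = n/d, so d is estimated by the ratio d_hat = n / p_hat.  The
delta method for g(p) = n/p gives

    Var(d_hat) = n^2 Var(p_hat) / p_hat^4.

When several indicators (e.g. polio vaccination and vitamin A) are
measured on the same children they share one denominator, so their ratio
estimates are pooled by inverse-variance weighting:

    d_hat = sum_k w_k d_hat_k / sum_k w_k,   w_k = 1 / Var(d_hat_k),

with pooled variance 1 / sum_k w_k.  Correlation between indicators
measured on the same children is ignored — a known simplification.
"""

from __future__ import annotations

from typing import Sequence

from .types import DenominatorEstimate, PrevalenceEstimate


def ratio_denominator(n: int, p_hat: PrevalenceEstimate) -> DenominatorEstimate:
    """Ratio estimate of the denominator from tally ``n`` and survey prevalence.

    Raises
    ------
    ValueError
        If the prevalence is zero or negative (denominator undefined) or
        the tally is zero (no information about d).
    """
    if n <= 0:
        raise ValueError("tally n must be positive: a zero tally carries no information about d")
    if p_hat.point <= 0:
        raise ValueError("denominator undefined at zero prevalence")
    point = n / p_hat.point
    variance = n**2 * p_hat.variance / p_hat.point**4
    return DenominatorEstimate(point=point, variance=variance, source="ratio")


def ratio_reliable(p_hat: PrevalenceEstimate, min_successes: float = 5.0) -> bool:
    """Whether the delta-method ratio estimate is trustworthy.

    The expansion of 1/p breaks down as p approaches zero; require the
    implied number of survey successes (p * n_respondents) to reach
    ``min_successes``.
    """
    return p_hat.point * p_hat.n_respondents >= min_successes


def pool_denominators(estimates: Sequence[DenominatorEstimate]) -> DenominatorEstimate:
    """Inverse-variance weighted pooling of denominator estimates.

    A zero-variance component carries infinite weight: the pooled result
    is that component (components with exactly zero variance must agree).
    """
    estimates = list(estimates)
    if not estimates:
        raise ValueError("no denominator estimates to pool")
    exact = [e for e in estimates if e.variance == 0.0]
    if exact:
        points = {e.point for e in exact}
        if len(points) > 1:
            raise ValueError(
                f"conflicting zero-variance denominator estimates: {sorted(points)}"
            )
        return DenominatorEstimate(point=exact[0].point, variance=0.0, source="pooled")
    total_weight = sum(1.0 / e.variance for e in estimates)
    point = sum(e.point / e.variance for e in estimates) / total_weight
    return DenominatorEstimate(point=point, variance=1.0 / total_weight, source="pooled")
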