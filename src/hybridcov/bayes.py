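"""Truncated Bayesian coverage layer.

The predicted denominator of an unsurveyed district is treated as a
random variable centered at the regression prediction with the
out-of-sample prediction variance,

    d_j ~ N(d_hat_j, sigma_pred_j^2),

truncated below at the observed numerator n_j — "truncation by reality":
the eligible population cannot be smaller than the number of children
actually served.  Coverage draws p_j = n_j / d_j therefore lie in (0, 1]
by construction, and so do their posterior medians and equal-tailed 95%
credible intervals.  A negative binomial denominator model (integer
support, mean/variance matched) is available when the prediction
variance exceeds the mean.

Sampling goes through the inverse CDF applied to uniforms, parameterized
through the upper tail so it stays accurate however far the truncation
point sits in either tail.  Keeping the uniforms explicit also enables
common-random-number sensitivity analysis: the same uniforms re-mapped
through a re-truncated CDF give coverage changes driven purely by the
numerator shift.
"""

from __future__ import annotations

import hashlib
from typing import Optional

import numpy as np
from scipy import stats
from scipy.special import ndtr, ndtri

from .types import CoveragePosterior, DenominatorEstimate

DENOMINATOR_MODELS = ("normal", "negbin")


def district_seed(seed: int, district_id: str) -> int:
    """Independent substream seed for one district.

    Derived by hashing (seed, district_id) so results are invariant to
    district ordering.
    """
    digest = hashlib.sha256(f"{seed}:{district_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def truncated_normal_ppf(
    u: np.ndarray, mean: float, sd: float, lower: float
) -> np.ndarray:
    """Quantile function of N(mean, sd^2) truncated to [lower, inf).

    Evaluated through the survival function: for the truncated variable,
    P(X > x) = S((x-mean)/sd) / S(alpha) with alpha the standardized
    bound, so x(u) = mean + sd * ndtri(1 - S(alpha)(1-u)) computed as
    -ndtri(S(alpha)(1-u)).  This stays monotone in u and numerically
    stable even when the bound lies many standard deviations into either
    tail, where the naive form F(alpha) + u(1-F(alpha)) loses all
    precision.
    """
    u = np.asarray(u, dtype=float)
    alpha = (lower - mean) / sd
    tail = ndtr(-alpha)  # survival at the bound, stable for alpha >> 0
    if tail == 0.0:
        raise ValueError(
            f"truncation bound {lower} is unreachable for N({mean}, {sd}^2)"
        )
    q = tail * (1.0 - u)
    # ndtri(1 - q) via symmetry; q can be denormal-small without harm
    x = -ndtri(np.clip(q, np.finfo(float).tiny, 1.0))
    return np.maximum(mean + sd * x, lower)


def _negbin_params(mean: float, variance: float) -> tuple[float, float]:
    if variance <= mean:
        raise ValueError(
            "negative binomial denominator model requires variance > mean "
            f"(got mean {mean:.1f}, variance {variance:.1f}); fall back to the normal model"
        )
    size = mean**2 / (variance - mean)
    prob = size / (size + mean)
    return size, prob


def truncated_negbin_ppf(u: np.ndarray, mean: float, variance: float, lower: int) -> np.ndarray:
    """Quantile function of a mean/variance-matched negative binomial
    truncated to {lower, lower+1, ...}."""
    size, prob = _negbin_params(mean, variance)
    u = np.asarray(u, dtype=float)
    tail = stats.nbinom.sf(lower - 1, size, prob)
    if tail == 0.0:
        raise ValueError(
            f"truncation bound {lower} is unreachable for the negative binomial model"
        )
    q = tail * (1.0 - u)
    draws = stats.nbinom.isf(np.clip(q, np.finfo(float).tiny, 1.0), size, prob)
    return np.maximum(draws, lower)


def sample_denominators(
    d: DenominatorEstimate,
    n: int,
    draws: int,
    seed: int,
    model: str = "normal",
    uniforms: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Draw denominators from the truncated predictive distribution.

    Parameters
    ----------
    d
        Denominator estimate supplying the center and variance.
    n
        Observed numerator; the lower truncation bound.
    draws
        Number of Monte Carlo draws (ignored when ``uniforms`` given).
    seed
        Seed for the uniform stream.
    model
        ``"normal"`` or ``"negbin"``.
    uniforms
        Optional pre-drawn uniforms in [0, 1); passing the same array
        with different bounds implements common random numbers.
    """
    if model not in DENOMINATOR_MODELS:
        raise ValueError(f"unknown denominator model {model!r}")
    if draws < 1 and uniforms is None:
        raise ValueError("draws must be >= 1")
    if d.point <= 0:
        raise ValueError("denominator center must be positive")
    if uniforms is None:
        rng = np.random.default_rng(seed)
        uniforms = rng.random(draws)

    if d.variance == 0.0:
        if d.point < n:
            raise ValueError(
                f"prediction inconsistent with observed numerator: "
                f"degenerate denominator {d.point} < n = {n}"
            )
        return np.full(len(uniforms), d.point)

    if model == "normal":
        return truncated_normal_ppf(uniforms, d.point, float(np.sqrt(d.variance)), float(n))
    return truncated_negbin_ppf(uniforms, d.point, d.variance, int(n))


def coverage_posterior(
    n: int,
    denominator_draws: np.ndarray,
    district_id: str,
    denominator_model: str = "normal",
    indicator: Optional[str] = None,
) -> CoveragePosterior:
    """Coverage draws p = n/d with posterior median and equal-tailed 95% CI.

    Every denominator draw must respect the truncation bound n; a draw
    below it means the upstream sampler violated its contract.
    """
    if n <= 0:
        raise ValueError("numerator must be positive")
    d = np.asarray(denominator_draws, dtype=float)
    if d.size == 0:
        raise ValueError("no denominator draws")
    if np.any(d < n):
        raise ValueError(
            f"district {district_id}: denominator draw below the truncation "
            f"bound {n} — truncation contract violated upstream"
        )
    p = n / d
    low, med, high = np.percentile(p, [2.5, 50.0, 97.5])
    return CoveragePosterior(
        district_id=district_id,
        draws=p,
        truncation_bound=int(n),
        median=float(med),
        ci_low=float(low),
        ci_high=float(high),
        denominator_model=denominator_model,
        indicator=indicator,
    )
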