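"""Truncation by reality: Bayesian coverage bounded above by 1.

The predicted denominator becomes a normal random variable truncated
below at the observed numerator, so every coverage draw n/d lies in
(0, 1] — even when the frequentist point estimate exceeds 1.
"""

from hybridcov import (
    DenominatorEstimate,
    coverage_posterior,
    frequentist_coverage,
    sample_denominators,
)

n = 16_500  # children served per the tally
prediction = DenominatorEstimate(point=16_000.0, variance=1_200.0**2, source="predicted")

freq = frequentist_coverage(n, prediction)
print(f"frequentist estimate: {freq.point:.3f}  "
      f"[{freq.interval_low:.3f}, {freq.interval_high:.3f}]   <-- exceeds 1")

draws = sample_denominators(prediction, n=n, draws=10_000, seed=20150101)
post = coverage_posterior(n, draws, "commune-X")
print(f"Bayesian posterior:   median {post.median:.3f}  "
      f"95% CrI [{post.ci_low:.3f}, {post.ci_high:.3f}]   <-- bounded by 1")
print(f"largest coverage draw: {post.draws.max():.6f}")
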