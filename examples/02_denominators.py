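"""Ratio denominators from tallies + survey prevalence, pooled across
indicators.

A campaign tally n and a survey coverage estimate p imply an eligible
population d = n/p.  Two indicators measured on the same children share
one denominator, so their ratio estimates are pooled by inverse variance.
"""

from hybridcov import (
    PrevalenceEstimate,
    pool_denominators,
    ratio_denominator,
)


def survey_estimate(p, var):
    se = var**0.5
    return PrevalenceEstimate(
        point=p, variance=var, n_respondents=95, method="survey",
        interval_low=p - 1.96 * se, interval_high=min(1.0, p + 1.96 * se),
    )


polio = ratio_denominator(15_800, survey_estimate(0.89, 0.0011))
vas = ratio_denominator(16_400, survey_estimate(0.93, 0.0008))

print(f"polio ratio denominator: {polio.point:,.0f}  (SE {polio.variance**0.5:,.0f})")
print(f"VAS   ratio denominator: {vas.point:,.0f}  (SE {vas.variance**0.5:,.0f})")

pooled = pool_denominators([polio, vas])
print(f"pooled denominator:      {pooled.point:,.0f}  (SE {pooled.variance**0.5:,.0f})")
# The pooled SE is smaller than either component's: inverse-variance
# weighting always tightens the estimate.
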