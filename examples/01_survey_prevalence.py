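"""Design-based prevalence from one district's stratified survey.

Five supervision areas of 19 children each; the stratified estimator
averages the SA proportions and sums the within-SA sampling variances.
"""

from hybridcov import SurveyResponse, estimate_prevalence

successes_per_sa = {"sa1": 17, "sa2": 18, "sa3": 15, "sa4": 19, "sa5": 16}

responses = [
    SurveyResponse("commune-A", sa, "polio", 1 if i < hits else 0)
    for sa, hits in successes_per_sa.items()
    for i in range(19)
]

est = estimate_prevalence(responses)
print(f"respondents:        {est.n_respondents}")
print(f"coverage estimate:  {est.point:.4f}")
print(f"variance:           {est.variance:.6f}")
print(f"95% interval:       [{est.interval_low:.4f}, {est.interval_high:.4f}]")
# The point estimate is the equal-weight mean of the five SA proportions;
# the interval is the normal-approximation 95% CI, clipped to [0, 1].
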