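# Methods

This note records the statistical model the package implements, the
defaults and why they were chosen, the numerical decisions, and what the
synthetic validation does and does not demonstrate.

## Estimation model

**Survey stage.** Each surveyed district is sampled through a stratified
design: supervision areas (SAs) as strata, a fixed number of children
(19 by default) sampled in each. The estimator is the stratified mean
`p̂ = Σ_h W_h p̂_h` with variance `Σ_h W_h² s_h²/m_h`, where
`s_h² = m_h/(m_h−1) p̂_h(1−p̂_h)` is the unbiased within-stratum
variance. Stratum weights default to equal (`W_h = 1/H`): SAs partition
a district into administratively similar units and the design places
equal samples in each; user-supplied population weights are accepted.
No finite-population correction is applied — catchment populations are
three orders of magnitude larger than the per-SA sample. Note the sharp
variance bound under equal weights is `0.25/(min_h m_h − 1)`, not
`0.25/m_h`, because of the Bessel factor in `s_h²`.

**Ratio denominators.** `d̂ = n/p̂` with delta-method variance
`n² Var(p̂)/p̂⁴`. The first-order delta approximation is accurate in
this design's regime (CV(p̂) ≈ 0.04 at p ≈ 0.87, n = 95): the
second-order relative error is ≈ `8·CV(p̂)²`, i.e. ~1% here, but ~8% at
CV = 0.1 and ~18% at CV = 0.15 — the test suite verifies this law
directly against Monte Carlo. Two guards apply: a prevalence implying
fewer than `min_ratio_successes` (default 5) survey successes is deemed
too close to zero for the expansion and the district is excluded from
the regression for that indicator; a degenerate all-ones estimate
(p̂ = 1, variance 0) would carry infinite pooling weight, so its variance
is floored using the shrunk proportion `(x + ½)/(m + 1)` before the
ratio is formed — without this, two indicators that both observed 95/95
successes but have different tallies produce irreconcilable
zero-variance denominators.

**Pooling.** Indicators measured on the same children share one
denominator; their ratio estimates are combined by inverse-variance
weighting (`w_k = 1/σ̂²_dk`), generalized to K indicators. Correlation
between indicators measured on the same children is ignored, a known
simplification: it makes the pooled variance somewhat optimistic but
does not bias the point estimate.

**Extrapolation.** Pooled denominators are regressed by OLS on
covariates available everywhere — census population and the previous
campaign's tally by default; a single-covariate (census-only) model and
a WLS variant weighted by `1/Var(d̂_j)` are config options. Outcomes
carry heteroscedastic measurement variance, but plain OLS is the
default: it is the simplest defensible model and the measurement
variance is small relative to the structural residual. Prediction for a
new district uses the new-observation variance `σ̂²(1 + h)` with
leverage `h = x'(X'X)⁻¹x` — the residual term is included because the
target is an actual district denominator, not a conditional mean. A
leverage above the maximum in-sample leverage is logged as
extrapolation beyond the fitted range, and districts below the lower
quartile of fitted census sizes are the typical culprits.

**Prediction intervals** use the Student-t quantile with `n_fit − P`
degrees of freedom (2.12 at 16 df), since `σ̂²` is estimated from ~19
districts; the z-based interval measurably undercovers in simulation
(~92.7% vs ~94.3% at nominal 95%). The delta-method intervals for
coverage proportions use the conventional ±1.96 SE.

**Truncated Bayesian layer.** The predicted denominator becomes a
random variable `d_j ~ N(d̂_j, σ²_pred)` truncated to `[n_j, ∞)` —
"truncation by reality": the eligible population cannot be below the
number of children actually served. This is a predictive distribution,
not a posterior under an explicit hyperprior; truncation is implemented
by renormalization. Coverage draws `p_j = n_j/d_j` lie in (0, 1]; the
point estimate is the posterior median and the interval the equal-tailed
2.5–97.5 percentile range (not HPD). The optional negative binomial
model uses the mean/variance-matched parameterization
(`r = d̂²/(σ²−d̂)`, `p = r/(r+d̂)`) on integer support, truncated the
same way; it requires overdispersion (`σ² > d̂`) and the pipeline falls
back to the normal model with a per-district warning when that fails —
the posterior records which model produced it.

## Sampling and reproducibility

Truncated sampling is inverse-CDF on explicit uniforms, parameterized
through the survival function: `x(u) = μ − σ·ndtri(S(α)·(1−u))` with
`S(α)` the normal survival at the standardized bound. This form is
monotone in `u` and keeps full precision however deep the bound sits in
either tail, where the naive `F(α) + u(1−F(α))` form loses all
resolution. The Kolmogorov–Smirnov distance to the analytic truncated
CDF is < 0.01 at 10⁵ draws (tested).

Each district × indicator gets an independent substream seeded by
`sha256(seed, district_id/indicator)` (reduced below 2³¹), so results
are invariant to district ordering and byte-identical across runs at a
fixed seed. Default 10,000 draws per district; the master seed defaults
to 20150101 and is mandatory in the config.

**Sensitivity analysis** reuses each district's uniforms across
numerator shifts `n'_j = round((1+δ)·n_j)` (common random numbers): the
uniforms are pushed through the distribution re-truncated at `n'_j`, so
draws below a raised bound are consistently "redrawn" and, where the
truncation never binds, the medians rescale exactly by `n'_j/n_j`.
Changes in the medians are therefore monotone in δ, and the asymmetry
(+10% moving estimates less than −10%) is driven solely by the upper
bound at 1. By default only the coverage-step numerators shift; with
`propagate_sensitivity` the surveyed-district denominators are also
recomputed and the model refitted, which largely cancels the shift
(numerators and denominators scale together) — both modes are offered
because either reading of "numerator bias" is defensible.

## Synthetic countries

The generator emulates the structure of the motivating campaign data:
77 districts, 19 surveyed (chosen at random — the real selection was
not random, but random selection is what makes parameter-recovery rates
interpretable), five SAs × 19 children each with one four-SA district
(1786 respondents). True denominators are lognormal (median ≈ 17,000
eligible children ≈ 0.17 × a median district population of ~100,000;
log-SD 0.394 reproduces a realistic interquartile ratio). True coverage
per indicator is Beta(11.28, 1.69) — mean 0.87, SD 0.09. Numerators are
`round(tally_bias·Binomial(d*, p*))`; `tally_bias` defaults to 1
(honest tallies) and values above 1 model systematic overcounting.
Census and prior-tally covariates are the truth times multiplicative
normal noise with CV 0.08 each; the prior tally additionally carries a
district-specific prior coverage drawn from the same Beta. The CV
defaults were fixed by a one-time calibration so the generator fulfils
its own contract — covariate–truth correlation > 0.9, near-nominal
prediction-interval coverage, regression adjusted R² ≈ 0.95 (matching
the near-1 fit quality such campaign covariates show in practice) —
and were frozen thereafter.

What the generator does **not** emulate: spatial correlation between
districts, non-random survey placement, SA-level heterogeneity (off by
default; `sa_sigma` adds a logit-normal SA random effect), within-child
correlation between indicators, and non-multiplicative (e.g.
district-size-dependent) tally errors. Passing recovery tests therefore
demonstrates internal validity of the estimators under the stated
model, not robustness to informative missingness of surveys or to
structured tally error — the sensitivity analysis is the tool offered
for the latter.

Test and acceptance problem sizes (200 replicates at 1,000 draws for
recovery; 50 countries at 10,000 draws for the truncation scan; three
countries at 4,000 draws for the asymmetry check) were chosen as the
smallest that leave Monte Carlo error well inside the tolerances being
asserted.

## Degenerate inputs and tie-breaks

* p̂ = 0 (or below the success guard): no ratio denominator; district
  excluded from the fit for that indicator, logged.
* p̂ = 1 with variance 0: variance floored as above; `d̂ = n` survives
  as a valid (if optimistic) estimate.
* Zero tally in an unsurveyed district: coverage reported as 0
  (frequentist row only — the truncated model needs n > 0).
* σ²_pred = 0 with d̂ < n: rejected as inconsistent with the observed
  numerator.
* Rank-deficient design: error naming the collinear columns (via the
  null-space vector of the SVD).
* Pooling with a zero-variance component: that component is returned;
  conflicting zero-variance components are an error upstream of the
  floor described above.

## Known limitations

The pooled variance ignores between-indicator correlation; the OLS
residual variance conflates covariate noise with survey measurement
error, making truth-directed prediction intervals mildly conservative
in principle (heteroscedasticity pushes the other way — net coverage is
~94–95% in simulation); the Bayesian layer quantifies denominator
uncertainty only, taking the numerators as known except through the
sensitivity analysis; and extrapolation is only as good as the linear
covariate relationship — districts far outside the fitted covariate
range get wide (and honest) intervals, but no model criticism beyond
the leverage warning is automated.
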