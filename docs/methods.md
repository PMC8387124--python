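# Methods

## The quantity being modelled

For one population and cause group, the age trajectory of mortality
(ATM) is the set of age-specific rates mu_i = D_i / L_i: deaths D_i and
person-years L_i summed within each category of a demographic age grid.
The grid subdivides the first year of life into "0 days" [0, 1) day,
"1–6 days" [1, 7), "7–27 days" [7, 28) and "28–365 days" [28, 365)
days, then uses (1, 5) and five-year bands. All ages are carried in
years with 365 days per year (the convention the "28–365 days" label
itself implies; not 365.25). Each category is represented by the
arithmetic mean of its endpoints, and bounds are half-open so the four
infant bands tile the first year exactly.

## Halley pooling and exposure

Deaths and exposures are summed over an explicit selection of
(country, calendar-year) pairs before any rate is formed; pooling is
exactly additive, associative and order-independent, and rates are
invariant under splitting a period into sub-periods and re-merging.
Mismatched calendar coverage across countries is never intersected
silently — a per-country year list must be given.

Exposure uses the stationary-population reading of census counts: a
mean count over a calendar year contributes that many person-years to
its whole-year band, and a sub-year infant band receives the under-1
count times the band width in years. This is an approximation (it
assumes deaths and births are spread evenly within the first year); the
frailty simulator, which accounts exposure exactly per individual, can
be used to audit it. Categories with zero pooled deaths are retained
and flagged rather than dropped; log-scale fitting refuses them, which
is precisely the situation pooling exists to remove.

Pre-aggregated counts tables (per-population, per-chapter D_i and L_i)
can be loaded directly, in which case the published L_i are used as
denominators as given.

## Model selection in log–log coordinates

All inference happens on (ln x_i, ln mu_i), where the regression
working assumptions (approximately Gaussian, additive errors) are
reasonable for rates estimated from hundreds of deaths per cell.
Significance is 0.05 throughout.

1. **Curvature.** OLS of ln mu on {1, ln x, (ln x)²}; the two-sided
   t-test of the quadratic coefficient decides whether a line is an
   adequate description. Needs n ≥ 4.
2. **Two-parameter line.** OLS slope γ and intercept ln(mu1) (the log
   rate at age 1 year), se(γ), and a t-based interval, by default 95%
   (the interval level is configurable since a bracketing convention,
   not a stated level, is being reproduced). Adjusted
   R̄² = 1 − (1 − R²)(n − 1)/(n − 2).
3. **Inverse proportion.** The nested one-parameter model fixes γ = −1;
   its single parameter has the closed form
   ln mu1 = mean(ln mu_i + ln x_i). The F statistic
   (RSS_inv − RSS_lin)/(RSS_lin/(n − 2)) is referred to F(1, n − 2) and
   equals the squared t statistic for (γ + 1)/se(γ). Rb² is defined as
   1 − RSS_inv/TSS in log–log scale with no degrees-of-freedom
   adjustment — this is the definition under which the one-parameter
   model can score slightly above or below the adjusted R̄² of the free
   line, matching how the two columns behave in practice. A perfect
   two-parameter fit (RSS_lin = 0) is guarded: F = 0, p = 1 when the
   inverse fit is also perfect, otherwise p = 0.

**Zero-slope test.** Age independence (used for neoplasms after the
first year) is the two-sided t-test of γ = 0 in the free line.

**Residual age trend.** No specific residual test is canonical here; a
Spearman rank correlation between residuals and ln x was chosen for
robustness at n = 6, with the p-value computed by full permutation
enumeration for n ≤ 8 (the asymptotic null is unreliable that small;
the exact test is conservative at these n). A perfect fit returns
p = 1.

**Minimum detection.** The category with minimal rate, ties broken
toward the younger category.

**Reporting scale.** Internally all rates are per person-year. The
reported mu1 level is scaled per 1000 person-years by default and is
configurable (per 100,000 person-years makes levels land in the tens,
which is where realistic all-cause child mortality levels sit); the
scale shifts only ln mu1 and never affects γ, R̄², Rb² or any p-value.

## The bending hazard and congenital frailty

Under the theory of congenital individual risks each newborn carries a
constant lifelong risk r (individual ageing over childhood is assumed
negligible relative to between-individual differences). The population
hazard is then the mixture hazard E[r | T > x], which declines with age
purely through depletion. Two objects operationalise this:

* **Closed form.** With maximal congenital risk r_max and level mu1,
  the bending hazard mu(x) = (mu1/x)(1 − e^(−r_max x)) is
  non-increasing, approaches mu1·r_max as x → 0 and mu1/x as
  r_max·x → ∞ (the inverse proportion is its nested limit). Fitting
  minimises squared residuals of ln mu (variance stabilisation across
  four orders of magnitude), with parameters log-transformed for
  positivity, Levenberg–Marquardt, iteration cap 500, tolerance 1e-10,
  and initial values taken from the linear fit (mu1 from the intercept,
  r_max = 2/x_min). On exactly-inverse data the r_max estimate runs
  away upward while the fitted curve converges to mu1/x; the optimiser
  still reports convergence because the residuals do. The convergence
  flag is always the optimiser's own status.

* **Simulator + oracle.** The individual-based simulator draws risks
  (reciprocal density ∝ 1/r truncated to (r_min, r_max), sampled by
  inverse CDF r = r_min·(r_max/r_min)^U; or a point mass; or a user
  table), exponential death times, and bins deaths and *exact*
  exposures into the grid. The independent oracle computes the exact
  mixture hazard by quadrature in log-risk space. Because the hazard
  varies within a bin, binned empirical hazards are compared with the
  bin-averaged oracle (expected deaths over expected exposure), not the
  midpoint hazard. With risks spanning (1e-18, 1e4)/yr the mixture
  hazard has local log-slope within (−1.05, −0.95) across the whole
  childhood window and the simulated trajectory fits with slope −1 to
  within a few hundredths.

## Synthetic count data

The generator mimics the input layout: for each country, year, cause
and category, expected deaths are lambda = profile(x_i) · L_i and
observed deaths are Poisson(lambda). Poisson noise is appropriate since
rates are far below 1/person-year everywhere except arguably the first
day of life; a binomial option exists for that band. An all-cause
trajectory is never drawn directly — it is the sum of the cause
components, so partition/conservation holds by construction. A truth
record (every lambda, every profile parameter, the seed) is emitted
beside the data and is what oracle tests consume.

Default conditions were fixed once, on demographic grounds: band
populations are stationary (N persons per year of age, so a five-year
band holds 5N), with N = 1e6 for a mid-sized country; the all-cause
level is about 6e-4 per person-year at age one (≈ 60 per 100,000
person-years, a realistic childhood level); the study-like mixture puts
most infant deaths in an inverse congenital component with small
bending, flat-neoplasm and constant-external components, which makes
its noiseless all-cause slope ≈ −0.96 — close to, but knowingly
shallower than, −1, since flat components necessarily lift the oldest
categories.

Replication experiments (generate → pool → fit → test) measure slope
bias and RMSE, interval coverage, and rejection rates of the inverse
test. At these conditions the slope estimator is unbiased to well under
0.01 and nominal 95% intervals cover the truth at close to 95%. The
nested F-test's type-I error is near, and structurally slightly above,
5% (≈ 6%): per-category log-rate variances 1/lambda_i differ by a
factor of about three across the grid, and OLS assumes them equal. This
mild size inflation is a property of the procedure under Poisson
sampling, not of the implementation.

**What the generator does not emulate:** secular trends, seasonality,
migration, cohort effects, between-country heterogeneity in levels or
cause-classification practice, and overdispersion relative to Poisson.
Passing tests therefore certify the machinery (bookkeeping,
estimators, calibration under the stated noise model), not the
behaviour of real mortality registers.

## Ranges, degenerate inputs and tie-breaks

An age range selects categories by midpoint. The inverse-proportion
assessment of all-cause mortality uses birth to 10 years (six
categories); above-infancy checks use 1–15 years, the narrowest range
with the three categories needed for a residual degree of freedom. Log
fits require n ≥ 3 and every in-range category to have at least one
death; curvature and residual tests require one more point. Identical
abscissae, all-zero rates, overlapping pooling selections, and missing
population records are hard errors with named offenders.

## Known limitations

* Fitting treats the six log-rates as homoskedastic; a weighted or
  count-likelihood (Poisson GLM) variant would remove the mild F-test
  size inflation but would no longer be the procedure under study.
* The stationary exposure rule biases infant-band denominators when
  births trend within the pooling period.
* The bending fit's r_max is weakly identified when no category lies in
  the bending region (r_max·x ≳ 1 for all x), and diverges on exactly
  inverse data by design.
* Single-year input ages are folded into (1, 5); finer childhood grids
  are not modelled.
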