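# Methods

`saeval` implements a small-area measurement strategy for binary survey
outcomes together with the validation machinery needed to choose among
competing model specifications. This note records the models, the numerical
choices, what the synthetic-data generator does and does not emulate, and
the known limitations.

## The measurement models

For person *j* in area (county) *i* of a given sex, the probability of the
outcome is modelled on the log-odds scale:

```
logit Pr(Y_ij = 1) = alpha + beta1·AGE_ij + beta2·RACE_ij + beta3·YEAR_ij
                     + Z_i·gamma + beta4·deltabar_i + delta_i
```

with `delta_i ~ N(0, sigma_delta^2)` an independent area random intercept.
Four nested families switch terms on and off:

| family     | county covariates `Z_i` | spatial covariate `deltabar_i` |
|------------|-------------------------|--------------------------------|
| naive      | no                      | no                             |
| geospatial | no                      | yes, from the naive fit        |
| covariate  | yes                     | no                             |
| full       | yes                     | yes, from the covariate fit    |

Each family additionally crosses an individual race term (in/out) and the
year coding (fixed categorical contrasts vs a per-area random slope),
yielding 16 specifications per sex. Sexes are modelled separately.

The spatial covariate `deltabar_i` is the mean of the estimated random
intercepts of the areas adjacent to *i* (shared boundary). It is computed
from a first-stage fit (naive or covariate family), held fixed, and the
model is refit with its coefficient `beta4`. Areas without neighbors
(islands) and neighbors absent from the first-stage fit contribute the
random-effect prior mean, 0. The two-stage procedure is run once, not
iterated, and the first stage is not refit jointly — the second stage
conditions on the first-stage estimates.

Model fitting is unweighted; poststratification weights enter only the
direct estimator below.

## Estimation

The marginal likelihood of the binomial logit mixed model is maximised
under the Laplace approximation. For fixed `(beta, log sigma)` the
conditional mode of the random effects factorises by area and is found by a
vectorised per-area Newton iteration (step-halving safeguard; convergence
when the penalised gradient falls below 1e-11 or steps reach the floating
point resolution of the objective). The outer problem is solved by L-BFGS-B
over `(log sigma, beta)` with an analytic gradient in the random-intercept
case, including the derivative of the Laplace log-determinant term and the
implicit dependence of the conditional mode on the parameters. `log sigma`
is bounded in `[log 1e-4, log 10]`; convergence uses gradient norm 1e-6 /
relative objective change 1e-12, at most 200 iterations.

When the year effect is random (a per-area linear trend on centred year,
with its own variance, independent of the intercept), the inner problem is
a per-area 2x2 Newton solve and the outer gradient is obtained by finite
differences. A fixed linear year-trend coefficient accompanies the random
slope so the family has a sensible mean model.

Numerical conventions:

* Area-level covariates and the spatial covariate are standardised
  internally (mean 0, SD 1) for optimizer conditioning; all estimates and
  covariances are transformed back and reported on the original scale, so
  adding a constant to a covariate moves only the intercept (by `-c·gamma`).
* The covariance of the fixed effects is the inverse of a central
  finite-difference Hessian of the Laplace objective at the optimum,
  computed from the analytic gradient (random-intercept case) or the
  objective values (random-year case). When `sigma` sits at its boundary the
  joint Hessian is singular; the covariance then conditions on `sigma` and
  inverts the `beta` block alone.
* `|standardised coefficient| > 12` raises a separation error naming the
  offending term. This fires on genuinely separated sparse cells (e.g. a
  demographic group with no events in a tiny resample) and such fits are
  recorded as flagged failures by the validation harness, never dropped
  silently.
* Year contrasts are coded against the earliest training year. Predicting a
  year outside the training set is an error under fixed-year coding.

An adaptive Gauss-Hermite quadrature implementation (51 nodes, centred and
scaled at each area's conditional mode) lives in the test suite as an
independent oracle for the Laplace log-likelihood; statsmodels' GLM is the
oracle for the `sigma -> 0` degenerate limit.

## Direct estimation and the gold standard

The direct estimator is design-based: within each survey-year x age-group
cell, the weighted outcome mean; cell estimates averaged over years with
equal year weights; age-specific rates combined with a standard age
distribution (packaged default: the US 2000 age distribution of the 30+
population), renormalised over the age groups actually present rather than
imputing zero prevalence to empty groups. The estimator is exactly
invariant to uniform weight rescaling within a year x age cell, and race is
deliberately not a standardisation axis.

The gold standard consists of the area x sex cells whose observation count
exceeds a threshold (default >900) in *both* of two pooled year windows
(defaults 1996-2004 and 2000-2008); the estimate itself is computed on the
second (later) window by default, with the estimation window exposed as a
parameter because the choice is not forced by the design.

## The validation experiment

Records are restricted to the gold-standard areas and resampled with
replacement to exactly L respondents per area-year (default levels L = 100,
50, 10; replicated 10 times per level). Each model specification is refit
on each resample, its predictions for the target year are aggregated to
area prevalence, and agreement with the gold standard is scored by Lin's
concordance correlation coefficient,

```
CCC = 2 cov(x,y) / (var(x) + var(y) + (mean x - mean y)^2)
```

with population (1/n) moments, and by RMSE. One additional row per
specification uses all available observations. A single-year direct
estimator is scored identically as a baseline. Non-convergent fits are
flagged rows, excluded from means but counted and reported.

Ranking: mean CCC per (specification, level), then the per-level means
averaged with equal weight across levels (so levels with more replicates do
not dominate), descending; ties broken by mean RMSE ascending. Per-replicate
rows are always retained so any other aggregation can be recovered.

## Aggregation and credibility regions

A fitted model is turned into an area prevalence by evaluating the inverse
logit of the linear predictor for every age x race cell (age only, if the
model excludes race) and averaging with weights = standard age distribution
x the area's race composition, renormalised to 1. Aggregation is therefore
a convex combination: monotone in every cell probability and strictly
inside (0,1).

Empirical 95% credibility regions re-draw the parameters (default 1,000
draws): fixed effects from `N(beta_hat, Cov)`, the area's random effect from
its conditional normal, independently — the Laplace fit does not provide the
cross-covariance, and the independence approximation errs on the side of
wider intervals. `sigma_delta` itself is held fixed across draws. Each draw
is aggregated as above and the bounds are the order statistics at ranks
`ceil(0.025·draws)` and `ceil(0.975·draws)`.

## The synthetic-data generator

The generator emulates the structure of a pooled multi-year national
telephone survey at county resolution:

* **Geography.** Areas on a near-square planar grid; contiguity = shared
  grid edge; an optional number of islands with no neighbors.
* **Sample sizes.** Per county-year counts are gamma-Poisson (negative
  binomial) with configurable mean (default 30-40) and dispersion (default
  0.3). The gamma size factor is drawn once per county, so large counties
  are large in every year — this reproduces both the observed regime in
  which the large majority of county-years have well under 100 respondents
  while a small tail is very large, and the persistence that makes a
  two-window gold-standard rule meaningful.
* **Risk surface.** County intercepts are drawn iid `N(0, sigma_delta^2)`,
  passed through one neighbor-mixing step
  `delta_i <- (1-m)·delta_i + m·mean(neighbor delta)` (islands unmixed) and
  rescaled to marginal SD `sigma_delta` (default 0.15, mixing 0.5). Age
  effects default to a steep chronic-disease gradient (-1.77 at 30-34 to
  +0.91 at 70-74 against reference 50-54), race effects to 0.41-0.69
  against the White non-Hispanic reference, and the year trend to
  +0.04/year.
* **Covariates.** Two covariates (shares of the Black and Hispanic
  populations) are read off the simulated demographic composition; the
  remainder (default: share with bachelor's degrees, poverty rate) are
  Gaussian with configurable location/scale and correlation `rho` with the
  standardised county intercept (default 0.5). The default was calibrated
  once so that area covariates carry roughly as much between-county
  information as moderate samples of the data themselves — the regime the
  validation framework is designed to discriminate in — and then frozen.
* **Composition and weights.** County age and race marginals are Dirichlet
  draws around national distributions; the joint composition is their
  product (no age x race dependence within county). Poststratification
  weights are gamma multipliers with configurable coefficient of variation
  (default 0.5), renormalised to mean exactly 1 per county-year cell.
* **Truth.** Each county's true prevalence is the exact aggregation of the
  inverse-logit cell probabilities at the final configured year with the
  same weights the estimation pipeline uses.

Not emulated: telephone-frame selection, nonresponse and raking (weights
are plain mean-1 multipliers), within-county age-race dependence, and any
upstream covariate measurement error. Passing tests therefore demonstrate
that the machinery recovers truth under the model's own assumptions plus
realistic sparsity — not that those assumptions hold in any particular real
survey.

## Problem sizes used by the test suite and acceptance script

Simulation studies use scales chosen so each check's sampling noise is well
below its decision margin: the degenerate-limit check uses 100 areas x
~4,000 records per area; Wald-coverage uses 100 replicates of 200 areas x 150
records; the spatial power/type-I arms use 400 areas (see limitations); the
validation experiment uses ~900 counties / ~57 gold areas x 5 replicates at
levels 100/50/10; interval coverage uses 100 replicates of 100 areas x ~600
records. The acceptance script runs the full pipeline at the 900-county
scale with 3 replicates per level.

## Known limitations

* **The Wald test on the spatial coefficient is anti-conservative, at any
  map size.** The neighbor-average covariate is a linear function `A·u` of
  the same realized area effects `u` that the second stage treats as iid
  residuals; conditioning on it as a fixed regressor makes the Wald
  statistic an improperly normalised quadratic form in `u` — the classic
  endogeneity of neighbor-average regressors in spatial autoregression.
  Measured null z-statistics for `beta4` have SD ~1.5 (rejection ~18% at
  the nominal 5% level) with 144-400 areas, and the inflation does not decay
  with the number of areas. Substituting the *true* neighbor-mean effects
  reproduces the same inflation, while an exchangeable area-level covariate
  in the identical fits is exactly calibrated (z SD ~1.00) — so this is a
  property of the two-stage design, not of the estimation code. Inference
  on `beta4` should be treated descriptively; the covariate's *predictive*
  value is what the downsampling validation framework assesses.
* **Variance components are Laplace ML, not REML.** With little information
  per cluster (roughly, fewer than ~50 effective Bernoulli observations per
  area) `sigma_delta` is noticeably biased low, random effects are
  over-shrunk, and credibility regions undercover. In the well-informed
  regime the intervals are calibrated (measured 95-100% empirical coverage
  at nominal 95%).
* Credibility draws ignore the fixed-effect / random-effect cross-covariance
  and the uncertainty in `sigma_delta`.
* Structured (e.g. CAR) random-effect covariance, survey-design-adjusted
  likelihoods, and design-based variances for the direct estimator are out
  of scope.
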