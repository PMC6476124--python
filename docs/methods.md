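# Methods

## Model

`graftrisk` fits a joint latent class mixed model (JLCM) for a
longitudinal kidney-function marker — serum creatinine (SCr, µmol/L) —
and a right-censored, optionally left-truncated time to graft failure.
The population is assumed to consist of `G` latent classes; conditional
on class, the marker process and the event time are independent.  Three
submodels are tied together in the individual likelihood:

1. **Membership** — multinomial logistic on baseline covariates
   (default: donor age ≥ 60 years), last class as reference:
   `pi_ig = softmax(xi_g' x_ci)`.
2. **Trajectory** — a monotone link `H(y; eta)` maps SCr to a latent
   Gaussian scale on which a linear mixed model holds:
   `H(Y_ij) = beta_0g + beta_1g t_ij + beta_2g t_ij^2 + b_0i + b_1i t_ij + e_ij`,
   with `b_i ~ N(0, B)` shared across classes and `e_ij ~ N(0, sigma^2)`.
3. **Survival** — class-specific two-parameter Weibull baseline with
   proportional covariate effects shared across classes:
   `Lambda_g(t|x) = (zeta_1g t)^{zeta_2g} exp(x_s' delta)`, where `x_s`
   collects pretransplant non-donor-specific antibodies (NDSA),
   dichotomized month-12 proteinuria (> 0.275 g/L), de novo
   donor-specific antibodies (dnDSA), acute rejection, and the
   dnDSA × rejection interaction.  Death with a functioning graft is
   treated as censoring; no competing-risk machinery.

The individual likelihood is
`L_i = sum_g pi_ig f_g(Y_i) f_g(T_i, E_i)` with log-sum-exp
stabilization; delayed entry divides each class's survival factor by
`S_g(T0|x)`.

### Identifiability convention

Latent-scale location and scale are not separately identified from the
link, the class intercepts, and the residual SD.  The convention here:
the residual SD is fixed at `sigma = 1` on the transformed scale, and
the link carries **no** free intercept (linear link: `H(y) = y/b`;
spline and beta-CDF links start at 0 at the lower support bound).  Class
intercepts are unconstrained.  Any monotone reparametrization of the
same fit gives identical hazard ratios, survival curves, posterior
probabilities, and predictions.

### Link functions

Four families: linear; rescaled beta-distribution CDF; quadratic
I-splines with equidistant nodes (default, 5 nodes); quadratic I-splines
with nodes at SCr quantiles.  I-splines are running integrals of
normalized M-splines (built on `scipy.interpolate.BSpline`); positivity
of the basis weights — enforced by squaring unconstrained optimizer
parameters — guarantees monotonicity by construction, so no candidate
iterate can produce a non-monotone transformation.  Observations outside
the training range are clamped to the support boundary, where the
Jacobian of every family remains positive.  Families are compared on the
discretized Akaike criterion (dAIC): each measurement's density
contribution is replaced by the model-implied probability of its
empirical-quantile bin (default 30 bins; outer bins open-ended; the
longitudinal part only, so one bin gives a discretized log-likelihood of
exactly zero), making fits under different transformations comparable.

## Estimation

Direct maximization (no EM) of the mixture log-likelihood over an
unconstrained vector: membership and hazard coefficients free; `B` via
its Cholesky factor; Weibull parameters and link weights as squares.
Optimizer: L-BFGS-B (memory 30) with central-difference numeric
gradients (relative step 1e-5), convergence at relative log-likelihood
change ≤ 1e-8 or projected gradient ≤ 1e-4, at most 600 iterations per
start.  The variance matrix is the inverse of the central-difference
observed information (relative step 1e-4); when it is not positive
definite the fit is returned with the variance flagged.

**Starting values.** JLCM likelihoods are multimodal.  The first start
clusters subjects by k-means (best of 8 restarts) on per-subject OLS
intercept/slope features of the transformed marker, then sets class
trajectories, exponential hazard rates, and membership intercepts from
the clusters.  Subsequent starts alternate between fresh k-means runs
with a random re-weighting of the slope feature (proposing level- vs
progression-based class structures) and random perturbations.  The
initial link scale is the *within-subject* residual SD around
per-subject linear trends — using the pooled residual SD (which also
contains between-class and between-subject variance) starts the
transformed scale several-fold too wide and was observed to funnel the
optimizer into class-merging local optima.  Default 10 starts;
simulation-scale runs in the test-suite use 1–2.

The number of classes is chosen by BIC (`-2 LL + p log N`, `N` =
subjects) over a candidate range.  Fitted classes are relabeled by the
latent mean at 18 months, ascending, so class 1 is always the
best-function class across seeds.

## Dynamic individual prediction

For a subject event-free at landmark `s` (default 1 year) with history
`Y(≤s)`, posterior membership is
`pi_g(s) ∝ pi_g(x_c) f_g(Y(≤s)) S_g(s|x_s)/S_g(T0|x_s)` and the
predicted failure probability over `(s, t]` is
`P(s,t) = sum_g pi_g(s) [1 − S_g(t|x_s)/S_g(s|x_s)]`.  The 95% band
draws `n_draws = 500` parameter vectors from `N(theta_hat, vcov)` in the
unconstrained space, recomputes the curve per draw, and reports
pointwise 2.5/50/97.5 percentiles; the median is the central curve.
Percentile (not Wald) bands were chosen because they respect the [0,1]
range and asymmetry near the bounds; the exact construction used in
comparable tools is rarely documented, so this is recorded as a package
decision.  After dnDSA or acute-rejection onset the curve is recomputed
with the updated hazard covariates and the landmark moved to the onset
time.  Covariates enter the hazard as time-fixed binaries; onset times
are used only to place the re-prediction landmark.

The decision rule reads the band over a 10-year horizon: *predicted
failure* when the upper limit exceeds 50% anywhere; *predicted survival*
when the median stays below 30% and the upper limit below 50%
throughout.  Those two conditions do not partition the outcome
space, so an explicit *indeterminate* category closes the gap; a binary
mode (failure iff the upper limit exceeds 50%) reproduces two-way
confusion arithmetic.  Whether to score at the horizon only or over the
whole curve is a genuinely open reading; the rule as implemented scans
the whole curve up to the horizon, and the horizon is a parameter.

## Synthetic cohorts

The generator emulates a retrospective transplant-cohort design: three classes with mean SCr
trajectories ~103 µmol/L slowly improving, ~150 stable, and ~150 rising
steeply within 18 months (random intercept SD 14, slope SD 8 µmol/L,
residual SD 12); membership tied to donor age ≥ 60 (prevalence 17.8%,
younger donors favouring class 1); class baseline 10-year failure risks
calibrated to 5% / 10% / ~100% with no class-3 graft surviving past 7
years (Weibull (0.0084, 1.2), (0.0153, 1.2), (0.28, 2.6)); hazard
ratios 3.27 (NDSA), 2.41 (proteinuria), 0.49 (dnDSA), 0.78 (rejection),
15.35 (interaction); covariate marginals 15.6% NDSA, 21.9% rejection
(94/135 within the first year), 9.7% dnDSA (onset uniform on 0.02–9.8
years), proteinuria lognormal(−2.14, 0.8) (mean 0.162 g/L, 14.4% above
the 0.275 cut); visits at months 1/3/6/12/18 with ~4-day jitter;
exponential death-censoring (9.1% by year 10); administrative censoring
at 10 years; inclusion requires ≥ 1 year of follow-up.

Hazard covariates are drawn independently of the latent class: the only
covariate–class link is donor age through the membership model, matching
the fitted model's assumptions.  (Per-class prevalence fields exist for
sensitivity experiments; making high-risk covariates class-concentrated
makes them informative about membership, which the donor-age-only
membership submodel cannot represent, and measurably attenuates the
fitted hazard coefficients.)  A consequence of keeping the reference
class risks, hazard ratios, and prevalences simultaneously is that the
implied 10-year observed failure fraction is ~17%, higher than the 11%
of the reference cohort profile — the real data reconcile these through joint
covariate structure and pre-10-year dropout that are not identifiable
from the available summary figures, and no attempt is made to guess
them.

The ≥ 1-year rule is applied by rejection (drop-and-redraw) by default;
a delayed-entry mode instead sets `entry_time` to 1 year so the
truncated likelihood conditions on the selection.  Recovery and
band-coverage simulations use the delayed-entry pairing, because fitting
a follow-up-selected sample *without* the truncation term is biased
(visible as an inflated late-time class-2 hazard).  Noise is added on
the latent scale and mapped through the link inverse, matching the
measurement model; optional rounding to integer µmol/L mimics laboratory
reporting (off by default).

A single-class curved-link preset (beta-CDF with shapes (0.5, 1.2) over
60–300 µmol/L) generates markedly skewed conditional SCr distributions
for link-selection experiments.

## What the simulations do and do not show

Passing recovery/selection/coverage checks on these cohorts shows the
estimation and prediction machinery is correct *under the model's own
assumptions* at realistic sizes (n ≈ 200–616, 3–5 visits/subject).  Real
cohorts add features the generator deliberately omits: joint covariate
dependence beyond class, informative visit schedules, measurement
rounding and outliers, non-Weibull baselines, era effects, and dropout —
so these results do not certify performance on real registry data.

One visible consequence: decision-rule sensitivity on a synthetic
validation split is low.  The split is stratified by dnDSA only and so
follows the population law, where most failures arise from the large
intermediate class whose members are — by construction — not
distinguishable from its survivors at the one-year landmark.  External
cohorts assembled around observed outcomes (e.g. one with 36 failures
among 60 patients) are failure-enriched in exactly the subjects the
model can flag, and the generator makes no attempt to reproduce that
enrichment.

## Problem sizes and numerical notes

Test-suite simulations use n = 250 (BIC selection over G ∈ {2,3,4}, 10
seeds), n = 150 (dAIC link selection, 10 seeds), n = 600 (recovery and
coverage; 5 independent training fits for the calibration check), as the
package's chosen desk-scale defaults.  Degenerate inputs: singular
longitudinal covariances are impossible by construction (Woodbury form
with eigenvalues ≥ 1); empty dAIC bins are merged; subjects without
pre-landmark measurements fall back to covariate-only membership with a
warning; an unavailable variance matrix degrades bands to the plug-in
curve, flagged.  Ties in quantile node placement raise a degenerate-
support error rather than silently collapsing knots.

## Known limitations

* Shared `B` across classes (class-specific scaling is a config switch
  but untested against data); no covariates other than class in the
  trajectory; no class-specific hazard coefficients.
* Numeric derivatives throughout: robust but slow; ~30 s per start on a
  616-subject cohort on one core.
* The beta-CDF link is numerically ill-conditioned where its density
  vanishes; inverses there are accurate on the transformed scale, not
  the creatinine scale.
* Left truncation conditions class-wise (`S_g(T0)` within each class
  term), the convention of standard JLCM software; it differs from
  conditioning the whole mixture on `T > T0` by a re-tilting of the
  membership intercepts, which are freely estimated.
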