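# Methods

`ahatraj` implements, end to end, the construction of a latent Active and
Healthy Ageing (AHA) metric from mixed-type longitudinal items, the
discovery of latent trajectory classes, and the association of
socio-economic covariates with those classes.  The real cohort this design
emulates is safeguarded, so every stage is exercised on synthetic panels
whose generative model is part of the package and is itself under test.

## Synthetic cohort (`ahatraj.synthetic`)

The generator encodes the study conditions as defaults:

- **Trajectory mixture.** Three latent classes with marginal shares
  (0.111, 0.793, 0.096) — a moderate-stable, a dominant high-stable, and a
  small decliner class.  Per class, growth factors (eta0, eta1) are normal
  with means (43.549, −3.269), (84.180, −6.577), (76.739, −50.017) on a
  0–100 trait scale and a shared 2×2 covariance
  [[53.718, −2.456], [−2.456, 40.840]].  The per-wave trait is the
  latent-basis curve theta_pt = eta0 + lambda_t·eta1 + eps_pt with
  lambda_1 = 0, lambda_T = 1 and a mildly concave interior
  (0, .18, .34, .48, .62, .75, .88, 1 over eight biennial waves), plus
  wave-level noise with SD 7 — chosen so that within-class spread and
  occasion noise are of the same order, as is typical for composite health
  indices.
- **Items.** 45 anchor items (available at all waves) and 6 wave-varying
  items available at baseline plus a random contiguous block of later
  waves.  Kinds cycle through binary and 3/4-category ordinals, plus four
  raw continuous performance tests and the six raw biomarkers (fibrinogen,
  HDL, triglycerides, LDL, CRP, HbA1c) with realistic population means and
  SDs.  Categorical responses follow a probit graded response model
  P(Y ≥ c) = Phi(a_k (theta* − b_kc)) on the standardised trait, making the
  generator structurally conjugate to the fitting model.  Optional
  wave-level deviations of item intercepts and discriminations
  (`item_wave_sd`, default 0) create the "multilevel" truth used to test the
  variance-structure variants.
- **Covariates and classes.** Education (3 levels), occupational class
  (3), wealth quintile, age, sex, ethnicity.  Class membership follows a
  multinomial logit of the dummy-coded covariates whose coefficients are
  the published education/wealth gradients (e.g. top-quintile wealth
  −2.500 vs the moderate class) with demographic effects backed out of the
  class-stratified descriptive table; class intercepts are calibrated by a
  fixed-point iteration so the marginal shares still match the configured
  proportions.  With zero covariate effects the model reduces exactly to
  the plain multinomial.
- **Missingness.** Monotone attrition with per-wave hazard 0.10 (optionally
  trait-dependent through a logit-linear coefficient, default 0) plus
  item-level Bernoulli holes at rate 0.05.  These rates reproduce the
  emulated panel's wave availability (roughly 100% at baseline declining
  to ~47% at the final wave).  The distal binary quality-of-life outcome is
  drawn per class with probabilities (0.151, 0.572, 0.097) and observed
  only for final-wave survivors.
- **Behaviours.** Smoking, alcohol and physical activity are ordinal
  probit draws on the current trait, so the mixed-model sensitivity
  analysis has realistic time-varying predictors.

What the generator does *not* emulate: item-specific marginal
distributions of the real battery, survey weights, refreshment sampling,
informative (non-MAR) dropout beyond the optional trait-linked hazard, and
measurement non-invariance across subgroups.  Passing tests therefore
demonstrate the correctness and calibration of the estimators under the
assumed model, not robustness to violations of it.

## Item preparation (`ahatraj.item_prep`)

Reverse-coded items are flipped so higher = better.  Biomarkers are
dichotomised at their published cut-offs (0 = higher risk), strict
comparisons except HbA1c (≥ 6.5%).  Continuous tests are SD-band
trichotomised (2 above mean+SD, 0 below mean−SD, else 1) with mean/SD from
the analysis sample at that wave.  Orientation-in-time scores 1 only when
all four questions are correct, missing if any answer is missing.
Eligibility gates: baseline missingness ≤ 25% (read inclusively —
"maximum" denotes an allowed value), and person-waves with at least
⌈battery/2⌉ observed items for the IRT stage (ceiling, since item counts
are integral).  The development/validation split is a simple random 70/30
with dev size round(0.7·n).  Outlier handling is a configurable per-item
valid-range table applied before recoding.

## Dimensionality (`ahatraj.dimensionality`)

Polychoric correlations are two-stage ML: thresholds from marginal probit
quantiles, correlation by maximising the bivariate cell likelihood with a
bivariate normal CDF built on Owen's T (exact to ~1e−13 against numerical
integration).  Estimation is pairwise-present; the matrix is
eigenvalue-repaired to PSD.  EFA is minres extraction (uniquenesses
optimised by L-BFGS) followed by Geomin oblique rotation (epsilon 0.01, the
common default for four or more factors) via the gradient-projection
algorithm with ten seeded random starts.  Item retention drops
cross-loaders (|loading| > 0.32 on two or more factors, absolute values
because sign is rotation-dependent) and items with max |loading| < 0.25.
The factor count is the smallest m whose EFA reaches CFI > 0.95 and
RMSEA < 0.06, reported with the scree eigenvalues.

The second-order CFA assigns each retained item to one first-order factor
and the first-order factors to one general factor, all latent variances
fixed at 1.  The discrepancy is normal-theory ML on the polychoric matrix:
the mean-and-variance-adjusted chi-square of specialised categorical
estimators is deliberately not replicated (bit-compatibility with that
software is a non-goal), and the fit-threshold logic operates on the
unadjusted statistic.  CFI/TLI use the independence baseline on the same
matrix; the RMSEA 90% CI inverts the noncentral chi-square.  Heywood cases
are flagged, not fatal.

## Multilevel IRT (`ahatraj.mlirt`)

The measurement model is the normal-ogive graded response model on
person-wave traits, with wave-level random deviations of item parameters
in four variance-structure variants: (a) none; (b) itemwise intercept
variance; (c) homogeneous intercept variance; (d) intercept and slope
variances with hierarchical item and slope parameters (a normal
hyperprior on the discriminations with sampled mean and variance).

Estimation is a data-augmented Gibbs sampler: truncated-normal latent
responses (Albert–Chib), conjugate normal updates for traits, wave
deviations and discriminations, truncated-normal cutpoint updates for
thresholds, and half-Cauchy(1) priors on variance components through the
inverse-gamma scale mixture.  The discrimination prior is N(1, 1)
truncated to positive — same support and similar mass as a lognormal, but
conjugate, which keeps every update closed-form.  Identification: traits
have a N(0,1) population prior, discriminations are positive,
baseline-wave deviations are fixed at zero, and at the top of each sweep a
likelihood-invariant transform recentres/rescales so the baseline-wave
trait sample has mean 0 and variance 1 (location moves into the
thresholds, scale into the discriminations).  This removes the two
slowest-mixing directions; split-R̂ on tracked summaries is reported and a
warning fires above 1.1.  Thresholds are additionally initialised at the
marginal probit quantiles, which makes short desk-scale chains usable.

Defaults are desk-scale (2000 iterations, 500 burn-in, thinning 2); the
full-scale 5000/100 schedule is one configuration flag away.  Outputs: EAP
scores and posterior SDs per eligible person-wave, EAP reliability
var(EAP)/(var(EAP)+mean posterior variance), DIC (Dbar + p_D with the
plug-in deviance at posterior means), and the wave-level ICC
sigma2_wave/(sigma2_wave + 1) per draw (probit residual variance is 1; for
variant b the itemwise variances are averaged), summarised as posterior
median with a central 95% credible interval.  Model selection prefers the
variant with lowest DIC; a reliability/DIC disagreement is logged.  The
0–100 AHA scale is a pooled min–max transform of the EAP scores (simplest
order-preserving map onto the reporting range); a normal-quantile
"t-score" map is provided as an alternative because the published
transformation is not fully specified.

## Trajectories (`ahatraj.trajectories`)

Growth mixtures are fitted by EM under FIML (persons grouped by
missingness pattern), with the constraint set: growth-factor covariance
and wave residual variances shared across classes; latent-basis loadings
shared across classes with fixed endpoints 0 and 1, so the intercept is
the baseline level and the slope the total change over follow-up.  The two
published equality statements about growth-factor variances are read as
this single constraint set.  Time is the wave index (mean two-year
spacing).  LCGA fixes the within-class growth covariance to zero (GLS
M-step for the class means).  Shapes: linear and quadratic (fixed
loadings) and latent basis (interior loadings updated in closed form each
M-step); the single-group shape is chosen by BIC.

Multistart: seeded K-means-style starts on (first level, last−first
change) with random perturbation, short EM triage, full EM on the best
`n_final`; desk-scale defaults 50/10 (configurable up to 1000/250).  The
per-start seeds are stored ranked by final log-likelihood so the best
solutions can be replicated exactly.  Convergence: relative log-likelihood
change < 1e−7 or 500 iterations; EM monotonicity is asserted in tests.
A covariance-coverage check (pairwise fraction jointly observed) aborts
below the 0.10 floor.

Class enumeration: AIC, BIC, SSABIC (penalty log((n+2)/24)), relative
entropy, and VLMR/adjusted-LMR tests.  Published implementations of the
Lo–Mendell–Rubin approximation disagree; here the statistic
2(LL_K − LL_{K−1}) is referred to a chi-square with 2d degrees of freedom
(d = extra non-mixing parameters, the Wolfe-style approximation of the
weighted-chi-square mixture), and the adjusted version multiplies the
statistic by the small-sample factor (n − 1 − d − K/2)/n, so its p-value is
never smaller.  Simulation shows the null distribution matches chi-square
with 2d df closely and the 5%-level rejection rate sits at ~0.05 under a
one-class truth; a parametric bootstrap (resimulate from the (K−1)-class
fit, refit both) is provided as the fallback arbiter.  `select_K` walks K
upward, accepting a step when both tests reject, all information criteria
decrease, no class is below 5% of the sample, and each class's average
modal posterior is at least 0.70; the last accepted K wins, with a
best-compromise-by-BIC fallback and a full decision log.

## Three-step covariate analysis (`ahatraj.class_covariates`)

Step 2 assigns modal classes and computes the classification-error matrix
Q[s,k] = P(W=s | C=k) by column-normalised posterior sums.  Step 3 is
Vermunt-style ML: the latent class is measured by W through Q (fixed), and
class membership follows a multinomial logit of the dummy-coded
covariates (references: no qualifications, routine/manual occupation,
first wealth quintile, male, White; age centred) with the distal outcome
as a class-specific Bernoulli inside the same likelihood.  Estimation is
EM with a Newton–Raphson weighted multinomial logit M-step; standard
errors come from the finite-difference observed information of the
marginal likelihood.  The likelihood uses Q exactly (zero cells are
harmless there); the 1e−4 floor protects only the reported fixed
measurement logits from −inf.  With Q = I the estimator reduces, to
machine precision, to the plain multinomial logit.  The growth-factor
regression on covariates is two-stage (posterior-mean growth factors,
OLS) rather than simultaneous full-information ML — the simultaneous
variant adds little at desk scale and the two-stage estimate serves the
same reporting role.  Odds ratios are exp(coef) with Wald 95% bounds
exp(coef ± 1.96·se), model-based SEs by default.

## Validation (`ahatraj.validation`)

The covariate-adjusted AUC uses placement values: each case's baseline
score is ranked (ties mid-ranked) against the empirical control
distribution of its own sex stratum, and the AUC is the mean placement;
the 95% CI is a percentile interval over 1000 person-level (cluster)
bootstrap resamples.  The mixed models are ML (not REML, so nested random
structures are LRT-comparable) with a random intercept per person and an
optional random slope on time-in-study (wave index × 2 years — the
conventional growth axis; age is an alternative carrier left
configurable).  For conditioning the outcome is standardised internally
and estimates mapped back; optimisers cascade (lbfgs → bfgs → cg →
powell) and a diagonal random-effects covariance is the structured
fallback.  The LRT is the plain chi-square (the 50:50 boundary mixture
would halve the p-value; plain chi-square is conservative and is what the
df = 1 comparison reports).

## Pipeline (`ahatraj.pipeline`, CLI `ahatraj`)

Stages run in a fixed order, each writing artefacts and a manifest (seed,
parameters, SHA-256 of outputs) into its own directory; stages
communicate only via the bundle and those files.  One global seed fans
out through fixed per-stage counters, so toggling a stage never shifts
another stage's stream; identical configurations reproduce identical
artefacts.  The CLI's demo defaults (600 persons, 24 items, variants a
and d, K = 2..4) are sized so a laptop run finishes in about a minute;
they are smaller than the generator's own cohort-scale defaults, which
the tests and the acceptance script use where the analysis requires them.

## Problem sizes used in tests and the acceptance script

IRT recovery uses 500 persons × 20 items × 4 waves; variance-structure
selection replicates use 250 × 10 × 4; mixture recovery uses 2000 persons
at the default three-class conditions; the enumeration-test calibration
uses 200 (tests) / 100 (script) replicates of n = 150, T = 4; the
three-step checks use 1200–5000 persons.  These sizes make every
stochastic check pass with wide margins while the full suite stays fast.

## Known limitations

- The Gibbs sampler's cutpoint updates mix slowly for very large samples;
  the quantile initialisation and identification transform compensate at
  desk scale, but production-scale runs should use the longer schedule and
  check the reported split-R̂.
- DIC uses the conditional (trait-level) deviance, as is conventional for
  IRT, so its absolute value is not comparable across eligibility sets.
- The LMR approximation is calibrated here for the implemented constraint
  set; for other covariance structures the bootstrap fallback is the safer
  arbiter.
- Step-3 standard errors ignore the sampling variability of Q itself
  (as does the standard three-step procedure).
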