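# Methods

`sdtrefer` analyses repeated urgent-referral decisions from clinical
vignette studies with equal-variance Gaussian signal detection theory
(SDT), and carries the derived per-responder indices through covariate
regressions, cross-task stability correlations, a mediation model and
Monte Carlo power analysis for indirect effects. A synthetic-data
generator with the same generative model makes every stage testable
without access to any real study data.

## The detection model

Each vignette is a case whose estimated cancer risk either exceeds the
3% national urgent-referral threshold (a positive case: the
guideline-appropriate decision is an urgent referral) or does not (a
negative case). For a responder with hit rate H (urgent referrals among
positive cases) and false-alarm rate FA (urgent referrals among negative
cases), the equal-variance Gaussian model gives

- discrimination d′ = z(H) − z(FA),
- criterion c = −[z(H) + z(FA)] / 2,

with z the standard-normal quantile. d′ measures how well the responder
separates cases that warrant urgent referral from cases that do not; c
locates their decision threshold, negative values marking a lenient
(refer-prone) style and positive values a conservative one.

Counts are corrected by adding 0.5 to every cell for every responder, so
rates become (k + 0.5)/(N + 1) and boundary responders (no hits or no
false alarms) stay computable. The correction is applied uniformly, not
only at the boundary, so all responders are on the same scale. Pooled
(sample-level) hit and false-alarm rates are reported uncorrected, as
plain ratios of the pooled counts.

Decisions are trichotomous (urgent / routine / none); the detection
model is binary, so routine referrals and no-referrals are collapsed
into "no urgent referral" before any rate is computed.

## Probit GLM formulation

The same model is estimable without any count correction as a trial-level
probit regression. With the case class coded signal = ±0.5,

P(urgent) = Φ(β₀ + β₁·signal + Σ γ_k x_k + Σ δ_k x_k·signal),

the intercept is −c and the signal slope is d′ at the covariate
reference; covariate main effects shift −c and covariate × signal
interactions shift d′. Responder nesting enters as independent Gaussian
random effects on the intercept (per-responder criterion) and the signal
slope (per-responder d′).

The marginal likelihood integrates the random effects on a Gauss–Hermite
grid (default 31 nodes per dimension; the non-adaptive grid at this size
matches adaptive-quadrature reference fits to ~0.01 on this class of
problem, which the test suite checks against `lme4::glmer`). Because
covariates are responder-level, all trials of a responder with the same
case class and outcome are exchangeable and are collapsed to weighted
binomial cells before quadrature, which reduces the likelihood cost by
the trial count per cell. Optimisation is L-BFGS-B on an internally
standardised design (coefficients and their covariance are mapped back
to natural scales, so reported effects are per percentage point of PPV,
per year of experience, etc.), with the analytic score; standard errors
come from the finite-difference observed information. Convergence is
reported honestly via the `converged` flag, and complete separation on a
binary covariate is raised as an explicit error naming the covariate.

Gender is coded female = 1 throughout, so a negative criterion-side
effect means women are more inclined to refer.

## Association analyses

Per-responder d′ and c are regressed by OLS on practice PPV (the share
of a practice's urgent referrals that convert to a cancer diagnosis, in
percentage points), practice sensitivity (the share of its cancer
patients who were urgently referred), gender and years of experience,
with analytic 95% CIs and two-sided p-values and no multiple-testing
adjustment. Experience enters continuously by default; a quartile
categorisation is available as an option. Cross-task stability is the
Pearson correlation of an index over the responders present in both
tasks. Group means are compared with a pooled-variance Student t-test
(df = n − 2), which is the convention the reported degrees of freedom in
this literature imply.

## Mediation

The gender → stress-from-uncertainty → criterion model is estimated by
three OLS regressions on complete cases (listwise deletion of missing
stress scores): mediator ~ predictor (a), outcome ~ predictor + mediator
(b and the direct effect), outcome ~ predictor (total). The indirect
effect is a·b; on a common complete-case sample the OLS decomposition
total = direct + indirect is an algebraic identity and is asserted to
1e−6. The indirect CI is a nonparametric percentile bootstrap (default
5000 resamples, seed 1234); the bootstrap is a vectorised closed-form
OLS identical to the statsmodels fits. A Sobel-type analytic interval is
deliberately not offered: the product of two coefficients is not normal
at these effect sizes, and the percentile bootstrap is the field
default. The proportion mediated is indirect/total exactly, returned
with an `inconsistent` flag when the two disagree in sign (the ratio
then loses its share-of-effect reading but is still reported).

## Monte Carlo power for indirect effects

Power to detect a·b at sample size n is estimated by simulation: each
replication draws n observations from a trivariate normal population for
(predictor, mediator, outcome), fits the two mediation regressions by
OLS, then draws many (a*, b*) pairs from the normal approximations to
the coefficient sampling distributions; the replication rejects when the
percentile interval of the products excludes zero. Power is the
rejection fraction, with Monte Carlo SE sqrt(p(1−p)/reps). Defaults
follow the published protocol for this procedure: 5000 replications,
20,000 draws per replication, a 95% interval and seed 1234. Raw data are
simulated per replication (rather than coefficients drawn directly from
a population covariance) because that is how the reference procedure for
this method is described.

When the population covariance is not printed, it is reconstructed from
reported summaries:

- binary predictor ↔ mediator: point-biserial r = t/√(t² + df) from the
  two-sample t statistic, with the predictor's SD √(p(1−p));
- mediator/predictor ↔ outcome: r = b·sd_x/sd_y from simple-regression
  slopes;
- the mediator's pooled SD solved from the t formula when only the mean
  difference and t are printed.

The reconstructed matrix is validated for positive semidefiniteness
(the violating leading minor is named on failure). Because the inputs
are reconstructed rather than observed, reproduction of published power
figures is approximate by construction; the declared tolerances are ±5
percentage points on power and ±15% on the required sample size, and the
search for the required n (smallest grid n with estimated power at or
above target, bisection with a common fixed seed across candidate n)
lands near the lower edge of that band on the default inputs.

## Synthetic data generator

`generate_study` emulates the structure of a 252-responder × 48-vignette
study. Defaults, all overridable through `SimConfig`:

- cohort: 52% female; experience lognormal(ln 13, 0.8144) years clipped
  to [1, 42] (median 13, IQR ≈ [8, 24], positively skewed); practice PPV
  uniform on [2, 16]%; practice sensitivity uniform on [30, 70]% (no
  distribution is published for sensitivity; this is a plausible
  detection-rate range and the analyses are insensitive to it);
- vignette risks log-uniform on (3, 18.04]% for positives and
  [0.18, 3)% for negatives, matching the published overall risk range;
- true indices: d′ ~ Normal(0.79, 0.32); c = −0.6516 + 0.05·PPV −
  0.17·female + Normal(0, 0.449). The intercept and noise SD are chosen
  so the marginal criterion has mean ≈ −0.29 and SD ≈ 0.50 given the
  covariate distributions;
- decisions: P(urgent) = Φ(±d′/2 − c), the unique symmetric placement
  under which population rates invert exactly to (d′, c) through the
  index formulas (asserted as a property test). Non-urgent decisions
  become routine referrals with conditional probability 1024/4820 ≈ 0.212,
  the published routine share among non-urgent decisions;
- stress-from-uncertainty: Normal(26.65 + 3.76·female, 8.45) truncated
  to [8, 48] (an 8-item scale; the item scoring, and hence the exact
  range, is an assumption that only affects the truncation tails), with
  3 scores missing among women;
- cross-task indices: second-task criterion correlated at r = 0.39 with
  a +0.79 mean shift (the companion task was more conservatively
  responded), second-task d′ independent (r = 0).

Everything is driven by one `numpy` Generator seed and is
bit-reproducible. The generator emulates the *statistical* structure
only: vignettes have no clinical content, responders have no order or
learning effects, and every responder answers the full grid. Passing
recovery tests therefore shows the estimators are consistent with this
generative model, not that any particular empirical dataset would yield
the same coefficients.

## Numerical choices and problem sizes

- Inverse-normal and normal CDF evaluations use `scipy.stats.norm`
  (`ndtri`/`ndtr`); tests compare against an independent root-finding
  oracle on the erf-based CDF at 1e−4 absolute.
- Index medians use the midpoint convention for even n; summary SDs use
  the n−1 denominator.
- Mixed-probit convergence: L-BFGS-B with ftol 1e−10 / gtol 1e−6, max
  200 iterations; the `converged` flag mirrors the optimiser.
- Degenerate inputs raise named errors rather than returning NaN:
  boundary rates (before correction), responders with only one case
  class, empty datasets, rank-deficient designs, zero pooled variance,
  zero total effect in the proportion mediated, constant mediator.
- Recovery and calibration tests run at reduced but statistically
  adequate sizes (e.g. 200 cohorts for coverage checks, 2000 responders ×
  200 trials for consistency checks, reduced replication counts for
  power monotonicity) — sizes chosen so binomial noise on the checked
  proportions is small relative to the asserted margins.

## Known limitations

- The mixed probit assumes independent random intercept and slope; a
  correlated-random-effects variant is not implemented.
- No unequal-variance SDT, nonparametric indices (A′, B″) or
  confidence-rating ROCs: decisions are binary after collapsing.
- Mediation offers a single mediator and no sensitivity analysis for
  unmeasured confounding of the mediator–outcome path.
- The power procedure treats a binary predictor as normal within each
  simulated replication, inheriting that approximation from the
  reference method it reimplements.
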