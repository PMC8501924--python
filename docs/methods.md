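# Methods

## Model

Four outcomes per subject are linked by a shared random-intercept vector
**b**ᵢ = (b₁ᵢ, b₂ᵢ, b₃ᵢ):

| sub-model | form |
| --- | --- |
| log ALT | v₁ᵢ(t) = **x**ᵢ(t)ᵀβ₁ + b₁ᵢ + ε₁ᵢ(t), ε₁ ~ N(0, σ₁²) |
| log bilirubin | v₂ᵢ(t) = **x**ᵢ(t)ᵀβ₂ + b₂ᵢ + ε₂ᵢ(t), ε₂ ~ N(0, σ₂²) |
| conmed count | C₂ᵢ \| b₃ᵢ ~ Poisson(Tᵢ exp(**x**ᵢᵀβ₃ + b₃ᵢ)) |
| AE count | C₁ᵢ \| **b**ᵢ ~ Poisson(Tᵢ exp(**x**ᵢᵀβ₄ + link)) |

Counts are cumulative over each subject's own follow-up Tᵢ (days), which
enters both count sub-models as a log-exposure offset, so count coefficients
are log incidence-rate ratios per day at risk.  AEs judged *definitely not
related* to the study drug are excluded before counting; unlikely, possibly
and probably related events are all retained.

Two association structures are supported.  The pure random-effects form
(`m7`) sets link = α₁b₁ᵢ + α₂b₂ᵢ + α₃b₃ᵢ.  The mixed current-value form
(`m9`, the default) sets link = α₁μ₁ᵢ(t\*) + α₂μ₂ᵢ(t\*) + α₃b₃ᵢ, where
μₖᵢ(t\*) = **x**ᵢ(t\*)ᵀβₖ + bₖᵢ is the expected current value of lab
outcome *k*.  Because the AE count is recorded once, at the end of
follow-up, the evaluation day t\* defaults to Tᵢ (configurable via
`ModelConfig.day_eval`).  The two structures coincide when α₁ = α₂ = 0.

Identifiability conventions: each random intercept enters its *own*
sub-model with loading fixed at 1, and the α coefficients appear only in
the AE sub-model.  A free loading on b₃ inside the conmed sub-model would
be jointly unidentifiable with σ_b3, so none is allowed.  The
random-effects covariance is diagonal — three SDs, no correlations.  The
shared-intercept construction still induces marginal correlation between
the outcomes, and the conmed intercept also absorbs count over-dispersion.

Covariates: treatment-arm indicators (reference AL), maternal age in years
(untransformed), and a second-trimester indicator (reference third
trimester).  The conventional Poisson comparator additionally carries a
primigravid indicator; the joint-model count sub-models do not — each
model's covariate set follows its own reporting convention.  The
longitudinal sub-models add a restricted cubic spline in visit day.

## Spline

Restricted (natural) cubic spline in the Harrell truncated-power form: K
knots give K−1 basis columns (the day itself plus K−2 restricted cubic
terms normalized by the squared boundary span), linear beyond the boundary
knots and C² everywhere.  Default knots {0, 7, 28, 63} days — the usual
percentile placement degenerates on a five-point visit grid, so fixed knots
spanning the schedule are used instead; they are configurable
(`ModelConfig.spline_knots`), and no reported quantity is sensitive to the
choice.  A 2-knot request is rejected rather than silently linearized.

## Likelihood and integration

The marginal likelihood multiplies, per subject, the Gaussian densities of
the log lab values, the two Poisson masses, and the random-effects density,
integrating **b**ᵢ out.  Integration is randomized quasi-Monte Carlo: a
3-dimensional Halton sequence (bases 2, 3, 5; the first 20 points dropped),
given a per-subject Cranley–Patterson shift keyed by (seed, canonical
subject rank), then mapped through the Gaussian quantile function and
scaled by the SDs.  Keying the shifts to the *sorted* subject order makes
the log-likelihood invariant to row permutations, and the same (seed,
draws) is bit-reproducible.  Default: 500 draws.  An SD of exactly 0 is a
point mass at 0 (the integral collapses to the conditional likelihood).
Antithetic mirroring is available but off by default.

Under the Student-t option for the random effects (a robustness analysis),
draws come from a variance-standardized t with fixed df (default 5, > 2
required), so the SDs retain their meaning.

A tensor-product Gauss–Hermite integrator over the three dimensions is the
small-problem reference: it converges to the closed-form marginal normal
likelihood in the counts-free sub-case (agreement to 1e-8 around 60+ nodes
per dimension) and the QMC value at 2000 draws agrees with the 15-node
reference to < 0.05 on a 5-subject dataset.  It is deliberately
non-adaptive — slow in high dimensions, which is exactly why the production
path is QMC — and supports Gaussian random effects only.

The per-(subject, draw) sweep is a fused numba kernel; the Gaussian lab
contribution is quadratic in the intercept, so its sufficient statistics
are folded into three per-subject coefficients and only the two count terms
need an exponential per draw.  A pure-numpy implementation of the same
quantity is kept as the fallback and as the path the Gauss–Hermite
reference uses, so the two integrators never share the fast kernel.

## Estimation

Simulated maximum likelihood: the QMC draws are generated once per fit and
held fixed across iterations, making the objective smooth and
deterministic (common random numbers).  Optimization is L-BFGS over an
unconstrained parameterization — all SDs log-transformed, β and α free —
with an analytic score.  The score of the simulated likelihood is the
self-normalized importance-weighted conditional score, and every term
reduces to 12 per-subject posterior moments of **b** computed in the same
kernel pass; the analytic gradient is verified against numerical
differentiation in the test suite.  A large history (`maxcor = 100`) copes
with the poor conditioning induced by the age column and the
intercept/current-value overlap.  Iteration cap 500; a fit hitting the cap
is returned flagged `converged=False` rather than raising, so recovery
experiments can tally failures.

Starting values come from independent per-outcome fits: random-intercept
linear mixed models per analyte (with a method-of-moments fallback),
offset-Poisson GLMs for the counts, α = 0, and σ_b3 = 0.1.

Standard errors: inverse of the negative Hessian of the marginal
log-likelihood at the MLE, obtained by central differences of the analytic
gradient with the same draws; symmetrized; a non-positive-definite
information matrix falls back to the pseudo-inverse with a warning and a
flag.  SDs are reported on the natural scale by the delta method and their
CIs on the log scale (exponentiated), keeping them positive.  Inference is
Wald throughout: 95% two-sided intervals, chi-square block tests.  AIC =
−2ℓ + 2k over the free parameters.

Parameters may be frozen via `ModelConfig.fixed`; freezing all α at 0 and
all σ_b at 0 collapses the AE sub-model to the conventional offset-Poisson
model, and the test suite verifies agreement to 1e-3.

## Synthetic-trial generator

`simulate_trial` draws from exactly the model above, so recovery
experiments score the estimator against a known truth.  Defaults emulate
the motivating trial: 870 subjects randomized 1:1:1, lab visits on days
{0, 7, 14, 28, 63}, 63-day follow-up, P(primigravid) = 0.511,
P(second trimester) = 0.839, maternal age 15 + Gamma(1.635, scale 3.997)
truncated above at 45 (calibrated by least squares to median 20 and IQR
18–24; a two-parameter gamma with a fixed lower bound cannot match all
three quantiles exactly).  The generative coefficients are the published
joint-model point estimates (`default_params`).  Two quantities those
estimates do not include are explicit assumptions: the longitudinal
residual SDs (0.25 for log ALT, 0.50 for log bilirubin) and the spline time
trend (flat ALT; a mild linear bilirubin decline of −0.004/day, matching
the described gradual decrease).  No reported quantity depends on either.

The published count-sub-model intercepts reproduce the trial's mean counts
*without* an exposure offset; since this package's count sub-models carry
offset log Tᵢ, `offset_adjusted` shifts both count intercepts by −log(63)
and the simulation defaults use the adjusted values.  The shift is logged.
With it, simulated trials land on the observed scale (≈1.7 AEs and ≈3.8
conmed reports per subject).

Listings are synthesized consistent with the drawn counts: AE records all
carry relatedness "possibly" (the relatedness filter is exercised by
dedicated fixtures, not the generator), conmed records default to the name
"paracetamol" so the medication-filter path is exercisable, and event days
are uniform over follow-up.  Independent substreams keyed off the master
seed drive covariates, random effects, residuals, counts and listing
detail, so changing the visit schedule does not perturb the count draws.

What the generator does *not* emulate: dropout or missed visits (everyone
completes 63 days; the motivating analysis treated missingness as
completely at random and only 7 subjects had missing points), informative
visit timing, residual correlation between the two lab outcomes beyond the
shared intercepts, medication-name diversity, or AE severity.  Passing
recovery tests therefore demonstrate correctness of the estimator under
the model's own assumptions, not robustness to their violation.

## Problem sizes used in the checks

Descriptive and arithmetic checks run on fixtures reproducing the published
table margins (three arms of 290).  Integration oracles use 5 subjects
(2000 QMC draws vs 15 Gauss–Hermite nodes per dimension; 80 nodes for the
closed-form comparison).  Limit-equivalence checks use n = 150 simulated
subjects.  Recovery runs 20 replicates at n = 300 with 500 draws —
comfortable for the α₃ bias (< 0.15) and 95%-coverage (within a 20-rep
binomial band of [0.75, 1.0]) checks.  The acceptance script fits the
full-size n = 870 trial.

## Known limitations

* Non-adaptive Gauss–Hermite reference only; for badly centred posteriors
  (many lab records, tiny residual SD) it needs many nodes.
* Diagonal random-effects covariance; an unstructured Σ is out of scope.
* The Poisson family is fixed; over-dispersion is handled only through the
  shared intercept (no negative binomial).
* Simulated-likelihood bias is O(1/draws); with the 500-draw default it is
  well below sampling noise at the trial sizes used here, but very small
  draw counts will bias variance parameters upward.
* Wald inference can be poor for variance components near zero; no
  profile-likelihood or LRT intervals are provided.
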