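# jointsafety

Joint modelling of multivariate longitudinal clinical-laboratory safety
outcomes, concomitant-medication counts and clinical adverse-event (AE)
counts in randomized drug trials.

In safety analyses these outcomes are usually summarized separately, even
though a patient who feels unwell tends to report more AEs *and* take more
concomitant medications (conmeds), and liver-function biomarkers such as
alanine aminotransferase (ALT) and total bilirubin move with the same
underlying state.  Ignoring those correlations wastes information and can
bias the estimated treatment effect on the AE incidence rate.  `jointsafety`
implements a four-sub-model joint likelihood for this setting — motivated by
a three-arm antimalarial-in-pregnancy trial (artemether–lumefantrine vs
amodiaquine–artesunate vs dihydroartemisinin–piperaquine, 870 women, 63-day
follow-up) — together with the conventional offset-Poisson comparator and a
synthetic-trial generator, so the whole method can be exercised and tested
without access to restricted trial data.

## The model

For subject *i* with shared random intercepts
**b**ᵢ = (b₁ᵢ, b₂ᵢ, b₃ᵢ) ~ MVN(0, diag(σ²_b)):

* log ALT: v₁ᵢ(t) = **x**ᵢ(t)ᵀ**β**₁ + b₁ᵢ + ε₁ᵢ(t), ε₁ ~ N(0, σ²₁)
* log bilirubin: v₂ᵢ(t) = **x**ᵢ(t)ᵀ**β**₂ + b₂ᵢ + ε₂ᵢ(t), ε₂ ~ N(0, σ²₂)
* conmed count: C₂ᵢ ~ Poisson(Tᵢ · exp(**x**ᵢᵀ**β**₃ + b₃ᵢ))
* AE count: C₁ᵢ ~ Poisson(Tᵢ · exp(**x**ᵢᵀ**β**₄ + link))

where Tᵢ is follow-up in days (an exposure offset), the time trend in
**x**ᵢ(t) is a restricted cubic spline (4 knots, 3 df), and the association
`link` is either

* **random effects** (m7): α₁b₁ᵢ + α₂b₂ᵢ + α₃b₃ᵢ, or
* **mixed current value** (m9): α₁μ₁ᵢ(t*) + α₂μ₂ᵢ(t*) + α₃b₃ᵢ,

with μₖ(t*) the expected current value of lab outcome *k* at the evaluation
day (end of follow-up by default).  exp(αₖ) is an incidence-rate ratio (IRR)
per unit of the linking quantity.  The marginal likelihood integrates
**b**ᵢ out by randomized quasi-Monte-Carlo (Halton draws, per-subject
scrambling), maximized by quasi-Newton with an analytic score; a
tensor-product Gauss–Hermite integrator serves as the small-problem
reference.  Model comparison is by AIC; inference is Wald.

## Worked example

```python
from jointsafety import (IntegrationSettings, fit_joint, fit_poisson_m1,
                         irr_transform)
from jointsafety.simulate import SimulationParams, simulate_trial

sp = SimulationParams(n_subjects=300, seed=11)   # published-parameter truth
trial, truth = simulate_trial(sp)
pois = fit_poisson_m1(trial, include_gravidity=False)
fit = fit_joint(trial, None, IntegrationSettings(draws=500, seed=11))
a3 = fit.estimates["alpha_conmed"]; lo, hi = fit.ci("alpha_conmed")
print(f"alpha_conmed = {a3:.4f} (95% CI {lo:.4f}, {hi:.4f}); "
      f"IRR = {irr_transform(a3):.4f}")
print(f"AE ASAQ log IRR: joint {fit.estimates['ae:asaq']:.4f} "
      f"vs Poisson {pois.estimates['asaq']:.4f}")
print(f"loglik = {fit.loglik:.2f}, AIC = {fit.aic:.2f}")
```

prints

```
alpha_conmed = 1.5841 (95% CI 1.3012, 1.8670); IRR = 4.8749
AE ASAQ log IRR: joint 0.0357 vs Poisson -0.0326
loglik = -2858.97, AIC = 5785.94
```

The conmed association used to generate these data was α₃ = 1.7487 (IRR
5.75): a unit increase in a subject's conmed random intercept multiplies
their AE rate about five-fold, and the fitted 95% interval covers the truth.
The joint and Poisson treatment coefficients differ because the joint model
adjusts for the shared heterogeneity the Poisson model ignores.

The same workflow is available from the shell:

```sh
jointsafety simulate --n 300 --seed 11 --out sim/
jointsafety summarize --data sim/ --out tables/
jointsafety fit --data sim/ --structure m9 --draws 500 --seed 11 --out fit/
jointsafety compare --data sim/ --out cmp/
jointsafety recover --reps 20 --n 300 --out rec/
```

Every output directory contains `run.json` (command, configuration, seed,
version) so a run can be reproduced exactly.

## Layout

| module | contents |
| --- | --- |
| `jointsafety.trial_data` | data model, CSV readers, AE-relatedness filter, count aggregation, descriptive tables |
| `jointsafety.design` | restricted cubic spline basis, design rows for all four sub-models |
| `jointsafety.model` | conditional/marginal log-likelihood, QMC integration, Gauss–Hermite reference |
| `jointsafety.estimation` | joint MLE, offset-Poisson comparator, SEs, Wald tests, IRRs, AIC, model comparison |
| `jointsafety.simulate` | synthetic-trial generator, parameter-recovery experiments |
| `jointsafety.cli` | `jointsafety` command-line entry points |

See `docs/methods.md` for modelling assumptions, numerical choices and
limitations.
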