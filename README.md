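# pencure

Penalized semi-parametric **mixture cure models** for **cause-specific
competing risks**, with SCAD/LASSO variable selection.

`pencure` is for survival analyses in which (a) a fraction of the
cohort is effectively cured — the Kaplan–Meier curve for the event of
interest plateaus well above zero — and (b) a competing event (e.g.
death before relapse) can preclude the event of interest.  The
motivating use case is identifying prognostic factors for relapse and
death in pediatric leukemia registries, where cohorts are small, many
clinical/laboratory covariates are candidates, and stepwise selection
is unstable.

## The model

For covariates `x`, a latent `Y` marks susceptibility to the event of
interest.  The population survival is the mixture

    S_pop(t | x) = (1 − π(x)) + π(x) · S_u(t | x)

- **Incidence**: `π(x) = expit(θ₀ + x'θ)` — logistic probability of
  being uncured; `1 − π(x)` is the cure probability and `exp(θⱼ)` an
  odds ratio (OR).
- **Latency**: `S_u(t | x) = S₀(t)^{exp(x'β)}` — Cox proportional
  hazards for susceptibles with a nonparametric Breslow baseline;
  `exp(βⱼ)` a hazard ratio (HR).

Fitting is by EM (posterior uncured weights → weighted logistic and
weighted Cox M-steps), with a zero-tail constraint for identifiability.
Competing events are handled cause-specifically (other causes recoded
as censoring).  Either or both components can be penalized with LASSO
or SCAD (shape a = 3.7), tuned over a λ grid by AIC or BIC; confidence
intervals come from a percentile bootstrap.  Kaplan–Meier curves,
Aalen–Johansen cumulative incidence functions, and the Maller–Zhou
sufficient-follow-up check round out the toolkit.  See
`docs/methods.md` for the full account.

Because registry patient data are typically not shareable, the package
ships a synthetic-cohort generator with known ground truth
(`pencure.synthetic`), including a frozen scenario calibrated to a
childhood-leukemia cohort profile (n = 187, 12 covariates, ≈62%
censored / ≈13% relapse / ≈25% competing death).

## Worked example

Simulate a leukemia-like cohort, describe it, and fit the models:

```sh
pencure simulate --scenario leukemia --n 187 --seed 3 --out cohort.csv
pencure describe --data cohort.csv --cause 1 --out desc
pencure fit --data cohort.csv --cause 1 --criterion bic --n-lambda 12 --out report
```

The `describe` step prints

```
KM plateau 0.7660; Maller-Zhou q_n=0.1818 p=5.05e-17: evidence of
sufficient follow-up; evidence of a nonzero cured fraction
```

— the relapse KM curve plateaus at 0.766 (an estimated 76.6% never
relapse), and the Maller–Zhou check (q_n = 0.18, α_n ≈ 5e-17) says
follow-up extends far enough past the last relapse to read that plateau
as a cured fraction, so a cure model is justified.

`fit` writes coefficient tables, tuning paths, and a model-comparison
table (`report/model_comparison.csv`):

```
method,bic,aic,df,loglik
SCAD,410.02,400.33,3,-197.16
LASSO,410.35,407.12,1,-202.56
Full model,506.52,412.82,29,-177.41
```

The BIC-selected SCAD model keeps 3 of 29 coefficients and beats the
full model by ~96 BIC points.  Its selected coefficients
(`report/scad_coefficients.csv`, nonzero rows):

```
component          name    estimate  ratio
incidence   (Intercept)       -0.99   0.37
incidence plt_150k_400k      -34.92   0.00
  latency plt_150k_400k     -144.51   0.00
```

Platelet count 150–400k is selected in both components.  Its runaway
magnitude (reported at the coefficient cap, with a separation warning
in the run log) reflects an empty cell: none of the 21 such subjects in
this draw relapsed, so the finite-sample estimate diverges — the same
sparse-cell inflation that small real cohorts produce.  OR/HR columns
are `exp(coefficient)` rounded half-up to 2 decimals; e.g. a latency
coefficient of −2.5 is HR 0.08, meaning the complementary group has
`1/exp(−2.5) ≈ 12.2` times the relapse hazard.

The same pipeline is available as a library:

```python
from pencure import (leukemia_scenario, generate_cohort,
                     run_cause_specific_analysis, RunConfig)
cohort, latent = generate_cohort(leukemia_scenario(n=187, seed=3))
report = run_cause_specific_analysis(cohort, target_cause=1,
                                     config=RunConfig(criterion="bic"))
print(report.comparison)
```

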