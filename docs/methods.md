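# Methods

## Model

`pencure` fits a semi-parametric **mixture cure model** to
competing-risks cohorts, one cause at a time.  For a subject with
covariate vector `x`, a latent indicator `Y` marks susceptibility to the
event of interest (`Y = 1`, uncured) versus long-term immunity
(`Y = 0`, cured).  The population survival for that event is

    S_pop(t | x) = (1 - pi(x)) + pi(x) * S_u(t | x),

with two regression components:

- **Incidence** — a logistic model for susceptibility,
  `pi(x) = expit(theta_0 + x' theta)`.  `1 - pi(x)` is the subject's
  cure probability; `exp(theta_j)` is an odds ratio for being
  susceptible.
- **Latency** — a Cox proportional-hazards model for the event time of
  susceptibles, `S_u(t | x) = S_0(t)^{exp(x' beta)}`, with a
  nonparametric baseline estimated by Breslow's method; `exp(beta_j)`
  is a hazard ratio among the uncured.

Under competing risks the model is applied **cause-specifically**: to
analyse cause `j`, all other event types are recoded as censorings.
This estimates the cause-specific hazard of `j` and requires the usual
(untestable) assumption that competing risks are conditionally
independent given covariates.  The two cause-specific analyses (e.g.
relapse-specific and death-specific) partition the events and share the
censored subjects.

### Estimation: EM with Breslow baseline

The cure status of a censored subject is unobserved, so estimation is
by EM on posterior "uncured" weights:

- **E-step** — subjects with the event get weight 1; a subject censored
  at `t` gets `w = pi S_u(t) / (1 - pi + pi S_u(t))`.
- **M-step (incidence)** — weighted logistic regression of `w` on `x`,
  solved by Newton iterations with step-halving.
- **M-step (latency)** — weighted Cox partial likelihood in which
  censored subjects enter risk sets with multiplier `w_i` (events carry
  weight 1), followed by the weighted Breslow baseline
  `dH_0(t_k) = d_k / sum_{risk set} w_i exp(x_i' beta)`.  Ties are
  handled by Breslow's approximation, consistent with the baseline
  estimator; events precede censorings at tied times.

Because each M-step only ever accepts objective-improving updates, the
observed-data log-likelihood is nondecreasing across EM iterations (the
suite checks this to 1e-8 on random cohorts).

**Zero-tail constraint.**  `S_u(t | x)` is set to 0 beyond the largest
event time.  Without it the cured fraction is not identifiable from a
finite follow-up; with it, a subject censored after the last event is
treated as definitively cured.  The flip side, demonstrated while
designing the synthetic scenarios, is that the estimator is biased when
follow-up is *not* sufficient — if a substantial share of susceptibles
is still event-free at the administrative horizon, their mass is
misattributed to the cured component and spurious incidence effects
appear.  The Maller–Zhou check exists precisely to screen for this.

### Penalized variable selection

Both components can be penalized (intercept always exempt).  The
penalized objective is `loglik - n * sum_j p_lambda(|b_j|)` with either

- **LASSO**: `p_lambda(b) = lambda |b|`, or
- **SCAD**: derivative `lambda` for `b < lambda`,
  `(a lambda - b)_+ / (a - 1)` for `b >= lambda`; shape `a = 3.7`
  (the conventional default), which leaves large coefficients nearly
  unbiased while zeroing small ones.

Penalized M-steps use the **local quadratic approximation** (LQA): the
penalty is majorized by a quadratic around the current coefficients,
`D_j = p'(|b_j|) / (|b_j| + 1e-8)` enters the Newton system as a ridge,
and coefficients below 1e-6 in magnitude are hard-thresholded to exact
zero.  Two numerical consequences shape the implementation:

- LQA pins a coefficient that is exactly zero, so fits are anchored at
  the naive (unpenalized-style) initial estimates rather than at zero,
  and the tuning path runs from the smallest lambda upward with warm
  starts — the direction in which coefficients only need to shrink.
- A singular penalized Hessian gets a 1e-8 ridge, logged.

**Tuning.**  A single shared lambda is used for both components (the
simplest scheme consistent with a single tuning parameter; per-component
tuning was considered and rejected as a default because the 2-d grid
multiplies cost without changing the qualitative selections on the
synthetic scenarios).  The default grid has 30 log-spaced values from
`lambda_max` down to `0.001 * lambda_max`, where `lambda_max` is twice
the largest per-coordinate null-model score over both components (on
standardized covariates, divided by n) — the factor 2 covers the growth
of E-step weights over the initial event indicator so the top of the
grid genuinely reaches the intercept-only model.  Models are scored by

    AIC = -2 loglik + 2 df,      BIC = -2 loglik + ln(n) df,

with `df` the count of nonzero coefficients across both components,
intercept included (exact for LASSO under orthogonality, the standard
approximation for SCAD; baseline-hazard jumps are not counted).  Ties
are broken toward the larger lambda, i.e. the sparser model.

**Standardization.**  Covariates are internally standardized (mean 0,
sd 1) before fitting so the penalty acts on comparable scales;
coefficients, the incidence intercept, and the Breslow increments are
transformed back afterwards.  The log-likelihood is invariant to this
reparametrization, so AIC/BIC comparisons are unaffected.

### Other numerical choices

- Logistic quantities via `expit`/`logaddexp`; linear predictors clipped
  at ±700 before exponentiation.
- Coefficients are confined to a ±50 box on the working scale.  A
  coefficient beyond 15 flags separation: the likelihood is flat along
  that direction, and the estimate is reported at the bound (only when
  that does not reduce the objective) with a warning.  This mirrors the
  inflated estimates sparse cells produce in real cohorts.
- Collinear or constant covariate columns are pruned before fitting
  (Gram–Schmidt against the columns already kept, tolerance 1e-8),
  re-embedded as exact zeros in the output, and warned about.
- EM stops when the largest parameter change is below 1e-6 (default) or
  after 500 iterations; non-convergence is flagged on the result, not
  raised.  Inner Newton solvers within the EM are capped at 25
  iterations per M-step — a generalized EM: any improving update
  preserves the ascent — and run to gradient norm 1e-8 when called
  directly.
- Initialization: incidence from a logistic fit of the event indicator,
  latency from a naive Cox fit treating all censored subjects as
  censored.

### Bootstrap confidence intervals

Nonparametric bootstrap resampling subjects with replacement, refitting
the full model on each replicate, and taking **percentile** intervals
(the method is deliberately the simplest member of the bootstrap family;
basic and BCa variants were considered out of scope).  Non-converged
replicates are dropped and counted, with an error if more than half
drop.  All resampling is driven by a single seeded generator, so
interval tables are bit-identical under a fixed seed.

### Nonparametric descriptives

- Kaplan–Meier product-limit curves per cause (other causes censored);
  the terminal value at the largest observed time estimates the cured
  fraction under sufficient follow-up.
- Aalen–Johansen cumulative incidence functions; by construction
  `sum_j CIF_j(t) + S_allcause(t) = 1` pointwise, which the suite
  checks at 1e-10.
- **Maller–Zhou sufficient-follow-up check**: with `t*_n` the largest
  event time and `t_n` the largest observed time, `N_n` counts events in
  `(2 t*_n - t_n, t*_n]`, `q_n = N_n / n`, and `alpha_n = (1 - q_n)^n`
  approximates the probability that follow-up is insufficient.  This is
  the interval-count variant and is known to be conservative; the
  verdict strings ("evidence of sufficient follow-up" at
  `alpha_n < 0.05`; "evidence of a nonzero cured fraction" when the KM
  plateau is positive with the last observation censored) are this
  package's own wording.

## Synthetic cohorts

The generator (`pencure.synthetic`) draws data with exactly the
structure the model assumes: covariates from declared binary /
multi-level / continuous specs, cure status
`Y ~ Bernoulli(pi(x; theta*))`, Weibull-baseline proportional-hazards
times for the event of interest (susceptibles only) and for the
competing event (everyone — cure attaches to the event of interest
only), and independent exponential censoring truncated at an
administrative horizon.  Weibull baselines give closed-form inverse-CDF
sampling under PH.  Latent cure indicators are stored beside the
observed table and never shown to the fitters.

Two named scenarios are frozen:

- **`leukemia_scenario`** — n = 187 with twelve clinical/laboratory
  variables (continuous age; binary sex, leukemia type, hemoglobin,
  CNS involvement, mediastinal tumor, splenomegaly, lymphadenopathy,
  hepatomegaly, arthritis signs; three-level WBC and platelet factors
  expanded to two indicators each) at childhood-leukemia-registry
  prevalences.  Incidence intercept −1.60, moderate effect sizes
  (|coef| ≤ 1.2), relapse baseline Weibull(shape 0.9, scale 18 months),
  competing-death baseline Weibull(1, 450), censoring rate 0.0095/month
  with a 285-month horizon.  The intercept, death scale, and censoring
  rate were calibrated by pilot simulation so the expected cause mix is
  ≈62% censored / ≈13% relapse / ≈25% death and the relapse KM curve
  plateaus above 0.5.  The short latency scale is deliberate: it makes
  follow-up genuinely sufficient (susceptibles essentially always
  relapse before the horizon), the regime in which the cure fraction is
  identified.
- **`sparse_scenario`** — n = 1000, six balanced binary covariates,
  incidence support {x1} (coefficient 2.0), latency support {x3, x4}
  (±1.5), no competing cause, generous follow-up: the large-effect
  regime in which a consistent selector should recover the exact
  supports.

What the generator does **not** emulate: covariate-dependent or
informative censoring, dependence between relapse and death beyond
shared covariates, time-varying covariates, measurement error, or the
messiness of registry data (missingness patterns, recording artifacts).
Passing recovery and selection tests therefore demonstrates correctness
of the estimator under its own assumptions, not robustness to their
violation.

## Problem sizes in the test suite

The suite uses n = 2000 with 20 replicates for coefficient recovery,
n = 1000 with 20 replicates for support recovery, and B = 200 bootstrap
replications over 20 outer cohorts for coverage — sizes chosen so each
study gives stable rates while the whole suite stays comfortably
re-runnable on a laptop.  Coverage is pooled over coefficients and
replicates; recovery bias is the per-component mean of
|mean-over-replicates error|.

## Known limitations

- The LQA path cannot revive a coefficient once pinned at zero; the
  upward-lambda warm-start ordering makes this harmless in practice but
  a coordinate-descent implementation would not share the limitation.
- `df` for SCAD is the nonzero count, an approximation.
- The Maller–Zhou p-value is conservative; borderline follow-up should
  be judged from the KM plateau as well.
- No Fine–Gray sub-distribution modelling, Gray's test, interval
  censoring, left truncation, or time-varying covariates.
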