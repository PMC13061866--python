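# Methods

## Model

A cohort's relative survival — observed all-cause survival divided by
the expected survival of an age/sex/calendar-matched general population
— is modelled as a mixture of a cured subpopulation with no excess
mortality and an uncured subpopulation with parametric net survival:

    RS(t) = π + (1 − π) · S_u(t | θ),       π ∈ (0, 1).

Assumptions: (i) the life table correctly describes the background
mortality of every subject (no unmeasured demographic confounding of
expected survival); (ii) excess and background hazards are additive, so
an uncured subject's death time is the minimum of independent background
and excess latent times; (iii) censoring is independent of the latent
cure status given covariates; (iv) `S_u → 0` within follow-up — the cure
fraction is only identified when the uncured have essentially exhausted
their excess risk before the administrative horizon (the fitter warns
when follow-up looks short relative to the fitted `S_u`).

### Likelihood

With `h_pop,i` and `H_pop,i` the subject's background hazard and
cumulative hazard along their attained-age/calendar path, and
`h_E(t) = (1 − π_i) f_u(t) / RS_i(t)` the excess hazard, subject `i`
contributes

    d_i · log(h_pop,i(t_i) + h_E(t_i)) − H_pop,i(t_i) + log RS_i(t_i).

The parameter-free population terms are retained so the reported
log-likelihood and AIC refer to the observed data; they cancel in
family comparisons. For a death the expression is evaluated in the
algebraically equivalent, numerically safer form
`log(h_pop · RS + (1 − π) f_u)`. Covariates enter the cure fraction
only (logistic link); the excess-survival parameters θ are shared. This
matches subgroup reporting in which each stratum is refitted
separately, so θ may differ between strata but not within a covariate
model.

### Families

Six excess-survival families, with natural parameterizations:

| family | S_u(t) | free parameters |
|---|---|---|
| exponential | exp(−t/σ) | σ |
| weibull | exp(−(t/σ)^k) | k, σ |
| lognormal | 1 − Φ((ln t − μ)/s) | μ, s |
| weibull_exponential | p·Weib + (1−p)·Exp | p, k, σ, λ |
| weibull_weibull | p·Weib₁ + (1−p)·Weib₂ | p, k₁, σ₁, k₂, σ₂ |
| generalized_modified_weibull | 1 − [1 − exp(−b·t^γ·e^{λt})]^α | α, b, γ, λ |

The generalized modified Weibull uses the standard four-parameter form;
λ ≥ 0. Mixture survival and density are evaluated through log-sum-exp;
degenerate weights (p = 0 or 1) are exact, which is what the nested-
family equivalence tests exercise. The two-Weibull mixture is reported
with σ₁ ≤ σ₂ (components relabelled after fitting) to resolve label
switching.

## Estimation and inference

Maximum likelihood on an unconstrained scale (log for positive
parameters, logit for probabilities), L-BFGS-B with central-difference
gradients, multi-start: a deterministic ladder of cure-fraction starts
(5/10/20/40%) around a moment-based θ initializer, plus seeded random
perturbations (default 10 starts). Convergence requires the
*per-observation* gradient max-norm below 1e-5 — an absolute criterion
on the total gradient would conflate cohort size with optimizer quality
— together with the optimizer's own function-tolerance stop (1e-9).
Identical options and seed give bit-identical fits.

The covariance matrix is the inverse numerical Hessian (symmetrized;
pseudo-inverse with a diagnostic message when singular). CIs for π and
β are Wald intervals on the link scale, back-transformed. A fit is
flagged "no definitive cure fraction" when the back-transformed CI
spans essentially all of (0,1), the estimate sits at a boundary, or the
Hessian is not positive definite — deliberately reported as
non-identifiability rather than as π ≈ 0.

AIC = 2k − 2·loglik; selection takes the converged fit with minimal
AIC, ties broken toward fewer parameters, then the canonical family
order above.

## Expected survival and SMRs

Hazards are piecewise constant on one-year age × calendar-year cells;
probability-dialect tables convert via `h = −log(1 − q)`. Ages above
the table clamp to the oldest row, calendar years to the nearest
available year. Cohort expected survival follows the Ederer II
convention: at each grid step the mean conditional one-step expected
survival of the subjects still at risk multiplies the running product,
so expected survival accrues only over observed person-time. Ederer II
was chosen as the modern default for cure work; Ederer I/Hakulinen are
out of scope.

Interval SMRs divide observed deaths in `[start, end)` by expected
deaths, the exact integral of each subject's background hazard over the
person-time they contribute to the interval. CIs are exact
(Garwood/chi-square) Poisson intervals for the observed count scaled by
1/E — well defined at zero counts (one-sided upper bound) and
conservative by construction, which the coverage tests account for.

## Cure points

Two criteria are first-class:

* **SMR normalization** (primary): the start of the earliest interval
  from which *every* later defined interval's 95% CI contains 1.0. The
  sustained condition prevents a transient dip in excess mortality from
  declaring cure prematurely when a later excess peak follows.
* **Conditional probability** (secondary): the smallest `t` with
  `π / RS(t) ≥ 0.80` (threshold configurable), solved by bracketing and
  Brent's method to 1e-6 y. Its uncertainty band (and that of the
  time-dependent cure probability curve) comes from multivariate-normal
  parameter draws on the unconstrained scale — cheap and consistent
  with Wald inference, but inheriting its asymptotics.

The analytic SMR-criterion cure point for a *generated* cohort is a
documented approximation: for a reference subject (mean age, majority
sex) the per-year expected background deaths `E_k` among expected
survivors and excess deaths `X_k = n(1−π)(S_u(k) − S_u(k+1))` are
compared, an interval counting as detectably elevated while
`X_k > 1.96·√(E_k + X_k)`. It captures how the operational cure point
shrinks with cohort size but ignores censoring and covariate spread, so
it is used for qualitative truth (ordering, rough location), not tight
recovery bounds; the conditional-criterion truth, by contrast, is exact
and drives the quantitative cure-point recovery test.

## Discrimination

Cumulative/dynamic time-dependent AUC with Uno-style IPCW: cases die by
the horizon, controls survive past it, and both are weighted by the
inverse Kaplan–Meier estimate of the censoring survival (left limits at
event times). With no censoring this reduces exactly to pairwise
concordance. The default marker is the model-predicted probability of
death by the horizon, `1 − [π_i + (1−π_i)S_u(h)] · S_pop,i(h)`, from
the covariate cure model — a no-covariate model gives every subject the
same disease component, leaving only demographic variation, and AUCs
near 0.5–0.6 on homogeneous synthetic cohorts are therefore expected,
not a defect. Bootstrap CIs resample subjects (default 500 draws,
seeded) and reuse the full-sample censoring weights, a standard
shortcut that slightly understates weight-estimation variability.

## Synthetic cohorts

The generator emulates a single-institution oesophageal-cancer-like
cohort: diagnosis age truncated-normal (mean 67, sd 8, range 40–90),
69.4% male, accrual uniform over 2014–2023 with administrative
censoring at the start of 2024, optional exponential dropout, cure
status Bernoulli with a common π (default 10.4%) or a logistic model on
generated covariates, and Weibull(1.3, 1.2 y) excess times by default —
an aggressive tumour with most excess deaths within three years.
Background deaths are drawn by inverse-transform sampling along each
subject's life-table hazard path. The packaged life table is
Gompertz–Makeham, `h(age) = 5e-4 + 3e-5·e^{0.09·age}`, year-homogeneous
(calendar clamping makes one year sufficient) and identical across
sexes by default.

Recovery experiments use a single accrual year and a 15-year horizon
(20 for the slower registry-style excess) so that the cure fraction is
cleanly identified; 20 cohorts per scenario at n = 2000–5000 (3000 per
group in two-group designs) keep each experiment within a few minutes
on one CPU while holding the Monte Carlo error of a mean cure fraction
near 0.1–0.2 percentage points.

What the generator does **not** emulate: disease recurrence or
progression as separate processes, cause-of-death coding, registry
matching procedures, covariate correlation structures, or life-table
misspecification. Passing recovery tests therefore demonstrates
internal consistency of estimator and generative model under correct
specification — not robustness to the ways real cohorts violate it.

## Known limitations

* Wald/parametric-bootstrap uncertainty everywhere; no profile
  likelihood or nonparametric bootstrap for π.
* Cure covariates are cure-fraction-only; covariate effects on θ
  (accelerated excess mortality) are not modelled.
* The SMR-criterion cure point is a step function of the interval grid;
  yearly intervals give yearly resolution.
* Fits with very few events, or follow-up much shorter than the excess
  support, are honestly non-identified and reported as such rather than
  extrapolated.
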