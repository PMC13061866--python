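# relcure

Relative-survival mixture cure modelling for cancer cohorts.

Clinicians and registry analysts ask two questions about a cancer
population that 5-year overall survival cannot answer: *what fraction of
patients will never die of their disease* (the **cure fraction**), and
*when does the mortality of survivors return to that of the general
population* (the **cure point**)? `relcure` answers both from
individual-level follow-up data and a general-population life table,
without needing cause-of-death information.

## The model

Relative survival divides observed all-cause survival by the expected
survival of a demographically matched population,
`RS(t) = S_obs(t) / S_exp(t)`, and is modelled as a two-component
mixture

```
RS(t) = π + (1 − π) · S_u(t | θ)
```

where `π` is the cure fraction (the cured die at population rates only)
and `S_u` is the net survival of the uncured, drawn from one of six
parametric families (exponential, Weibull, log-normal,
Weibull–exponential and Weibull–Weibull mixtures, generalized modified
Weibull), selected by AIC. Subject `i`'s all-cause hazard is
`h_pop,i(t) + h_E(t)` with excess hazard
`h_E(t) = (1 − π_i) f_u(t) / RS_i(t)`, giving a full observed-data
likelihood; covariates act on the cure fraction through a logistic link,
`π_i = expit(β₀ + βᵀx_i)`.

Alongside the model the package provides

- Kaplan–Meier observed survival and Ederer II expected survival;
- interval **standardized mortality ratios** (observed/expected deaths
  over person-time) with exact Poisson CIs, and the cure point as the
  time from which all later interval SMRs stay compatible with 1.0;
- the time-dependent probability of being cured given survival,
  `π / RS(t)`, with a parametric-bootstrap band, and the alternative
  cure point at which 80% of survivors are cured;
- IPCW time-dependent ROC/AUC for model discrimination;
- a synthetic-cohort generator with known cure structure (cured deaths
  drawn from the life table, uncured deaths from the minimum of
  background and excess latent times) for end-to-end validation.

## Worked example

```python
import numpy as np
from relcure import (SimulationConfig, CureModelSpec, FitOptions,
                     fixture_life_table, simulate_cohort, fit_cure_model,
                     interval_smr, cure_point_conditional, cure_point_smr)

lt = fixture_life_table()           # packaged Gompertz-Makeham life table
config = SimulationConfig(n=3000, seed=42, pi=0.104, family="weibull",
                          theta=(1.3, 1.2), year_start=2005.0,
                          year_end=2005.0, admin_censor_year=2020.0)
cohort, truth = simulate_cohort(config, lt)
fit = fit_cure_model(cohort, lt, CureModelSpec("weibull"), FitOptions(seed=42))
smr = interval_smr(cohort, lt, np.arange(0.0, 16.0))
```

prints (via the fuller snippet in `analysis/`):

```
cure fraction: 9.5% (95% CI 8.5-10.7%), true 10.4%
first-year SMR: 42.3 (95% CI 40.2-44.5)
cure point (SMR normalization): 7.0 y
cure point (80% of survivors cured): 3.20 y
```

A cohort of 3000 with a true 10.4% cure fraction and aggressive Weibull
excess mortality yields a fitted cure fraction whose CI covers the
truth; early mortality is ~42× the population rate, the interval SMRs
stay statistically indistinguishable from 1.0 from year 7 on, and 80%
of survivors are model-cured from year 3.2 — illustrating why the two
cure-point criteria are reported side by side.

The numbered scripts under `analysis/` walk the full workflow on
synthetic study cohorts: simulation, six-family fitting with AIC
selection, SMR trajectories and cure points, subgroup and covariate
models, and time-dependent AUC, writing tables under `results/`. The
`relcure` command exposes the same pipeline
(`relcure report --config run.yaml`).

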