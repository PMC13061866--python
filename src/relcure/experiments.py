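"""Reusable simulation-recovery experiments.

Each experiment generates synthetic cohorts whose true cure structure
is known, runs the corresponding estimator, and reports recovered
versus true quantities averaged over seeds.  The analysis scripts, the
test suite and the reproduction script all drive these functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import Cohort
from .cure_models import CureModelSpec, FitOptions, fit_cure_model
from .cure_inference import cure_point_conditional
from .life_tables import LifeTable
from .synthetic_data import (SimulationConfig, analytic_cure_point,
                             concat_cohorts, fixture_life_table,
                             simulate_cohort)

__all__ = ["RecoveryResult", "cure_fraction_recovery",
           "two_group_recovery", "cure_point_recovery"]


@dataclass(frozen=True)
class RecoveryResult:
    true_values: dict[str, float]
    estimates: dict[str, list[float]]

    def mean(self, key: str) -> float:
        return float(np.mean(self.estimates[key]))

    def bias(self, key: str) -> float:
        return self.mean(key) - self.true_values[key]


def _options(seed: int, n_starts: int = 6) -> FitOptions:
    return FitOptions(n_starts=n_starts, seed=seed, raise_on_failure=False)


def cure_fraction_recovery(pi: float, seeds, n: int = 5000,
                           theta=(1.3, 1.2), family: str = "weibull",
                           followup: float = 15.0,
                           lt: LifeTable | None = None) -> RecoveryResult:
    """Fit the no-covariate cure model to cohorts with known cure fraction.

    Cohorts accrue in a single year with administrative censoring after
    ``followup`` years, so the uncured excess distribution is fully
    identified.  Returns per-seed cure-fraction estimates.
    """
    lt = lt or fixture_life_table()
    estimates = []
    for seed in seeds:
        config = SimulationConfig(n=n, seed=int(seed), pi=pi, family=family,
                                  theta=tuple(theta), year_start=2005.0,
                                  year_end=2005.0,
                                  admin_censor_year=2005.0 + followup)
        cohort, _ = simulate_cohort(config, lt)
        fit = fit_cure_model(cohort, lt, CureModelSpec(family),
                             _options(int(seed)))
        estimates.append(fit.pi_hat)
    return RecoveryResult(true_values={"pi": pi},
                          estimates={"pi": estimates})


def _group_config(pi, n, seed, theta, family, followup, **overrides):
    kw = dict(n=n, seed=seed, pi=pi, family=family, theta=tuple(theta),
              year_start=2005.0, year_end=2005.0,
              admin_censor_year=2005.0 + followup)
    kw.update(overrides)
    return SimulationConfig(**kw)


def two_group_recovery(pi_by_group: dict[str, float], grouping: str, seeds,
                       n_per_group: int = 3000, theta=(1.3, 1.2),
                       family: str = "weibull", followup: float = 15.0,
                       lt: LifeTable | None = None) -> RecoveryResult:
    """Recover per-group cure fractions through the logistic-link model.

    ``grouping`` is ``"sex"`` (groups "female"/"male", simulated by
    forcing each subcohort's sex) or ``"age"`` (groups "under65"/
    "over65", simulated by truncating the diagnosis-age draw below or
    above 65).  One model is fitted to the pooled cohort with the group
    indicator as a cure covariate, and the group fractions are
    back-transformed from the linear predictor.
    """
    lt = lt or fixture_life_table()
    estimates: dict[str, list[float]] = {g: [] for g in pi_by_group}
    for seed in seeds:
        seed = int(seed)
        parts = []
        for j, (group, pi) in enumerate(sorted(pi_by_group.items())):
            if grouping == "sex":
                over = {"p_male": 1.0 if group == "male" else 0.0}
            elif grouping == "age":
                over = {"age_range": (40.0, 64.999) if group == "under65"
                        else (65.0, 90.0)}
            else:
                raise ValueError(f"unknown grouping {grouping!r}")
            config = _group_config(pi, n_per_group, seed * 10 + j, theta,
                                   family, followup, **over)
            cohort, _ = simulate_cohort(config, lt)
            parts.append(cohort)
        pooled = concat_cohorts(*parts)
        if grouping == "sex":
            covariate = "sex"
        else:
            covariate = "age65"
            pooled = Cohort(pooled.df.assign(
                age65=(pooled.df["age"] >= 65.0).astype(float)))
        fit = fit_cure_model(pooled, lt, CureModelSpec(family, (covariate,)),
                             _options(seed))
        from scipy.special import expit
        b0, b1 = fit.beta
        if grouping == "sex":
            recovered = {"female": float(expit(b0)),
                         "male": float(expit(b0 + b1))}
        else:
            recovered = {"under65": float(expit(b0)),
                         "over65": float(expit(b0 + b1))}
        for g in pi_by_group:
            estimates[g].append(recovered[g])
    return RecoveryResult(true_values=dict(pi_by_group), estimates=estimates)


def cure_point_recovery(pi: float, seeds, n: int = 5000, theta=(1.3, 1.2),
                        family: str = "weibull", threshold: float = 0.80,
                        followup: float = 15.0,
                        lt: LifeTable | None = None) -> RecoveryResult:
    """Compare fitted conditional-criterion cure points with the
    analytic cure point implied by the generating parameters."""
    lt = lt or fixture_life_table()
    base = SimulationConfig(n=n, seed=0, pi=pi, family=family,
                            theta=tuple(theta), year_start=2005.0,
                            year_end=2005.0,
                            admin_censor_year=2005.0 + followup)
    truth = analytic_cure_point(base, lt, "conditional_probability", threshold)
    estimates = []
    for seed in seeds:
        config = SimulationConfig(n=n, seed=int(seed), pi=pi, family=family,
                                  theta=tuple(theta), year_start=2005.0,
                                  year_end=2005.0,
                                  admin_censor_year=2005.0 + followup)
        cohort, _ = simulate_cohort(config, lt)
        fit = fit_cure_model(cohort, lt, CureModelSpec(family),
                             _options(int(seed)))
        cp = cure_point_conditional(fit, threshold=threshold)
        estimates.append(cp.cure_point)
    return RecoveryResult(true_values={"cure_point": truth},
                          estimates={"cure_point": estimates})
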