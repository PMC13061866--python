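"""Cure points, time-dependent cure probability, and population curves.

Two operational definitions of the cure point are supported side by
side:

* ``smr_normalization`` (primary): the start of the earliest follow-up
  interval from which the interval SMR's 95% CI — and those of all
  later defined intervals — include 1.0, i.e. cohort mortality is no
  longer distinguishable from the general population and stays that
  way.
* ``conditional_probability`` (secondary): the earliest time at which
  the model-based probability of being cured given survival,
  P(cured | alive at t) = pi / RS(t), reaches a threshold (default
  80% of survivors cured).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .cure_models import CureModelFit
from .survival_estimators import SMRSeries

__all__ = ["CurePointResult", "conditional_cure_probability",
           "cure_point_conditional", "cure_point_smr", "population_curves"]


@dataclass(frozen=True)
class CurePointResult:
    criterion: str                 # smr_normalization | conditional_probability
    cure_point: float | None       # years; None when undefined
    threshold: float | None = None  # for the conditional criterion

    @property
    def defined(self) -> bool:
        return self.cure_point is not None


def conditional_cure_probability(fit: CureModelFit, t, band: bool = False,
                                 n_draws: int = 1000, seed: int = 0):
    """P(cured | alive at t) = pi / RS_model(t) for a no-covariate fit.

    Nondecreasing in t, equal to pi at t=0, tending to 1.  With
    ``band=True`` also returns a pointwise 95% band from multivariate
    normal parameter draws on the unconstrained scale (parametric
    bootstrap consistent with Wald inference).
    """
    t = np.asarray(t, dtype=float)
    point = fit.pi_hat / fit.rs(t)
    if not band:
        return point
    rng = np.random.default_rng(seed)
    fam = fit.spec.get_family()
    n_beta = fit.beta.size
    draws = rng.multivariate_normal(fit.params, fit.vcov, size=n_draws,
                                    method="svd")
    curves = np.empty((n_draws, t.size))
    from scipy.special import expit
    for i, x in enumerate(draws):
        pi_d = expit(x[0])
        theta_d = fam.to_natural(x[n_beta:])
        rs_d = pi_d + (1 - pi_d) * fam.sf(t, theta_d)
        curves[i] = pi_d / rs_d
    low, high = np.percentile(curves, [2.5, 97.5], axis=0)
    return point, low, high


def cure_point_conditional(fit: CureModelFit, threshold: float = 0.80,
                           horizon: float = 100.0) -> CurePointResult:
    """Smallest t with pi / RS_model(t) >= threshold.

    Found by bracketing and bisection to 1e-6 years.  A threshold at or
    below pi is already met at t=0; a threshold not reached within
    ``horizon`` years leaves the cure point undefined.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    pi = fit.pi_hat
    if threshold <= pi:
        warnings.warn("threshold is at or below the cure fraction; "
                      "the criterion is met at t = 0")
        return CurePointResult("conditional_probability", 0.0, threshold)

    def shortfall(t):
        return pi / fit.rs(t) - threshold

    if shortfall(horizon) < 0:
        warnings.warn(f"conditional cure probability stays below "
                      f"{threshold} within {horizon} years")
        return CurePointResult("conditional_probability", None, threshold)
    root = optimize.brentq(shortfall, 0.0, horizon, xtol=1e-6)
    return CurePointResult("conditional_probability", float(root), threshold)


def cure_point_smr(smr: SMRSeries) -> CurePointResult:
    """Start of the earliest interval from which all later defined
    intervals' SMR CIs include 1.0; undefined if the last defined
    interval still excludes 1."""
    if len(smr) == 0:
        raise ValueError("empty SMR series")
    starts = np.asarray(smr.start, dtype=float)
    defined = np.asarray(smr.defined, dtype=bool)
    includes_one = (np.asarray(smr.ci_low) <= 1.0) & (np.asarray(smr.ci_high) >= 1.0)
    ok = includes_one | ~defined  # undefined intervals cannot contradict cure
    # earliest index from which every later interval is compatible with SMR=1
    suffix_ok = np.logical_and.accumulate(ok[::-1])[::-1]
    if not suffix_ok.any() or not defined.any():
        return CurePointResult("smr_normalization", None)
    first = int(np.argmax(suffix_ok))
    return CurePointResult("smr_normalization", float(starts[first]))


def population_curves(fit: CureModelFit, grid) -> pd.DataFrame:
    """Relative-survival curves of the total, uncured and cured groups.

    On the relative-survival scale the cured group's curve is
    identically 1; total = pi + (1 - pi) * uncured pointwise.
    """
    grid = np.asarray(grid, dtype=float)
    uncured = fit.uncured_survival(grid)
    return pd.DataFrame({
        "time": grid,
        "total_rs": fit.pi_hat + (1 - fit.pi_hat) * uncured,
        "uncured_rs": uncured,
        "cured_rs": np.ones_like(grid),
    })
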