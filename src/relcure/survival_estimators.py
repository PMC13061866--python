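"""Nonparametric observed survival, relative survival, and interval SMRs.

Observed overall survival is the Kaplan-Meier product-limit estimate
(via lifelines).  Relative survival divides it by the cohort's Ederer II
expected survival.  Standardized mortality ratios compare observed
deaths in follow-up intervals with the deaths expected from population
hazards over the person-time actually contributed, with exact
(Garwood/chi-square) Poisson confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .cohort import Cohort
from .life_tables import LifeTable, PopulationPath, expected_survival_cohort

__all__ = ["StepCurve", "SMRSeries", "km_survival", "relative_survival_curve",
           "interval_smr", "monthly_grid"]


@dataclass(frozen=True)
class StepCurve:
    """Right-continuous step function with value 1 at time 0."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t, v = np.asarray(self.times, float), np.asarray(self.values, float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D and equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def at(self, t):
        """Evaluate the step function at time(s) t (value 1 before the
        first jump)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], 1.0)
        return float(out) if out.ndim == 0 else out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "value": self.values})


def monthly_grid(t_max: float) -> np.ndarray:
    """Default evaluation grid: monthly steps from 1/12 up to t_max."""
    n = int(np.floor(t_max * 12))
    return np.arange(1, n + 1) / 12.0


def km_survival(cohort: Cohort) -> StepCurve:
    """Kaplan-Meier estimate of observed all-cause survival."""
    kmf = KaplanMeierFitter()
    kmf.fit(cohort.df["time"], event_observed=cohort.df["event"])
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    values = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = times > 0
    return StepCurve(times[keep], values[keep])


def relative_survival_curve(cohort: Cohort, lt: LifeTable, grid=None) -> StepCurve:
    """Relative survival RS(t) = S_observed(t) / S_expected(t) on a grid.

    The default grid is monthly to the largest follow-up time.  RS may
    exceed 1 when the cohort outlives its demographic expectation.
    """
    if grid is None:
        grid = monthly_grid(float(cohort.df["time"].max()))
    grid = np.asarray(grid, dtype=float)
    observed = km_survival(cohort).at(grid)
    expected = expected_survival_cohort(lt, cohort, grid)
    if np.any(expected <= 0):
        raise ValueError("expected survival is 0 on the grid; cannot form RS")
    return StepCurve(grid, observed / expected)


@dataclass(frozen=True)
class SMRSeries:
    """Per-interval observed/expected deaths with exact 95% CIs.

    ``defined`` is False for intervals with no expected person-time
    (and no observed deaths), where the SMR is undefined.
    """

    start: np.ndarray
    end: np.ndarray
    observed: np.ndarray
    expected: np.ndarray
    smr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    defined: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.defined is None:
            object.__setattr__(self, "defined",
                               np.ones_like(np.asarray(self.start), dtype=bool))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "start": self.start, "end": self.end,
            "observed_deaths": self.observed, "expected_deaths": self.expected,
            "smr": self.smr, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "defined": self.defined,
        })

    def __len__(self) -> int:
        return len(np.asarray(self.start))


def poisson_ci_exact(k: int, alpha: float = 0.05) -> tuple[float, float]:
    """Garwood exact CI for a Poisson count (chi-square form)."""
    low = 0.0 if k == 0 else 0.5 * stats.chi2.ppf(alpha / 2, 2 * k)
    high = 0.5 * stats.chi2.ppf(1 - alpha / 2, 2 * k + 2)
    return low, high


def expected_deaths(cohort: Cohort, lt: LifeTable, breaks) -> np.ndarray:
    """Expected deaths per interval from population hazards.

    Each subject contributes the integral of their background hazard
    over the person-time they spend in each interval ``[start, end)``
    (deaths and censorings stop contribution at exit).
    """
    breaks = np.asarray(breaks, dtype=float)
    df = cohort.df
    horizon = max(120.0, float(breaks[-1]) + 1.0)
    out = np.zeros(breaks.size - 1)
    for age, sex, year, time in zip(df["age"], df["sex"], df["year"], df["time"]):
        path = PopulationPath(lt, age, sex, year, horizon=horizon)
        upper = np.minimum(breaks[1:], time)
        lower = np.minimum(breaks[:-1], time)
        live = upper > lower
        if live.any():
            out[live] += path.cum_hazard(upper[live]) - path.cum_hazard(lower[live])
    return out


def interval_smr(cohort: Cohort, lt: LifeTable, breaks=None,
                 alpha: float = 0.05) -> SMRSeries:
    """Observed/expected death ratio per follow-up interval.

    ``breaks`` are strictly increasing interval endpoints starting at 0
    (default: yearly intervals covering the follow-up).  The CI is the
    exact Poisson interval for the observed count divided by the
    expected count; with zero observed deaths the SMR is 0 with a
    one-sided upper bound.
    """
    df = cohort.df
    if breaks is None:
        breaks = np.arange(0.0, np.ceil(df["time"].max()) + 1.0)
    breaks = np.asarray(breaks, dtype=float)
    if breaks[0] != 0 or np.any(np.diff(breaks) <= 0):
        raise ValueError("breaks must be strictly increasing and start at 0")

    death_times = df.loc[df["event"] == 1, "time"].to_numpy()
    observed, _ = np.histogram(death_times, bins=breaks)
    expected = expected_deaths(cohort, lt, breaks)

    n = breaks.size - 1
    smr = np.full(n, np.nan)
    lo = np.full(n, np.nan)
    hi = np.full(n, np.nan)
    defined = np.ones(n, dtype=bool)
    for j in range(n):
        if expected[j] <= 0:
            if observed[j] > 0:
                raise ValueError(
                    f"interval [{breaks[j]}, {breaks[j+1]}) has observed deaths "
                    "but zero expected deaths")
            defined[j] = False
            continue
        smr[j] = observed[j] / expected[j]
        l, h = poisson_ci_exact(int(observed[j]), alpha)
        lo[j], hi[j] = l / expected[j], h / expected[j]
    return SMRSeries(start=breaks[:-1], end=breaks[1:],
                     observed=observed.astype(int), expected=expected,
                     smr=smr, ci_low=lo, ci_high=hi, defined=defined)
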