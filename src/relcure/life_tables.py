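"""Population life tables and expected (background) survival.

A life table gives the general-population mortality of a demographic
reference group by single year of attained age, sex, and calendar year.
It is the denominator of every relative-survival quantity in this
package: expected survival, expected deaths for SMRs, and the background
hazard entering the mixture cure likelihood.

Conventions
-----------
* Hazards are per year and piecewise constant on one-year age x calendar
  cells (half-open intervals ``[a, a+1)`` and ``[y, y+1)`` in attained
  age and calendar time).
* Tables read in the ``probability`` dialect store annual death
  probabilities ``q`` which are converted to hazards via
  ``h = -log(1 - q)`` (the piecewise-exponential convention).
* Lookups clamp: ages above ``age_max`` (or below ``age_min``) use the
  nearest available row, calendar years outside the table's range use
  the nearest available year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "PopulationPath",
    "read_life_table",
    "population_hazard",
    "expected_survival_individual",
    "expected_survival_cohort",
]

_SEXES = ("male", "female")


@dataclass(frozen=True)
class LifeTable:
    """Annual background hazards on a complete (age, sex, year) grid.

    ``hazard[sex]`` is a 2-D array of shape ``(n_ages, n_years)`` holding
    the hazard per year for the cell ``[age, age+1) x [year, year+1)``.
    """

    age_min: int
    age_max: int
    year_min: int
    year_max: int
    hazard: dict[str, np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        n_ages = self.age_max - self.age_min + 1
        n_years = self.year_max - self.year_min + 1
        for sex, arr in self.hazard.items():
            if sex not in _SEXES:
                raise ValueError(f"unknown sex {sex!r}; expected one of {_SEXES}")
            if arr.shape != (n_ages, n_years):
                raise ValueError(
                    f"hazard grid for {sex!r} has shape {arr.shape}, "
                    f"expected {(n_ages, n_years)}"
                )
            if np.any(arr < 0) or not np.all(np.isfinite(arr)):
                raise ValueError(f"hazards for {sex!r} must be finite and >= 0")

    @property
    def sexes(self) -> tuple[str, ...]:
        return tuple(self.hazard)

    def _sex_grid(self, sex: str) -> np.ndarray:
        try:
            return self.hazard[sex]
        except KeyError:
            raise KeyError(
                f"sex {sex!r} not present in life table (has {self.sexes})"
            ) from None

    def hazard_at(self, age, sex: str, year):
        """Piecewise-constant hazard at real-valued attained age / year.

        Vectorised over ``age`` and ``year``; out-of-range ages and years
        clamp to the nearest row/column.
        """
        grid = self._sex_grid(sex)
        a = np.clip(np.floor(np.asarray(age)).astype(int) - self.age_min,
                    0, self.age_max - self.age_min)
        y = np.clip(np.floor(np.asarray(year)).astype(int) - self.year_min,
                    0, self.year_max - self.year_min)
        return grid[a, y]


def read_life_table(path, dialect: str) -> LifeTable:
    """Read a life-table CSV with columns ``age,sex,year,value``.

    ``dialect`` is ``"probability"`` (value is the annual death
    probability q, converted to a hazard via ``-log(1-q)``) or
    ``"rate"`` (value is already a hazard per year).
    """
    if dialect not in ("probability", "rate"):
        raise ValueError(f"dialect must be 'probability' or 'rate', got {dialect!r}")
    df = pd.read_csv(path)
    required = {"age", "sex", "year", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"life table {path} missing columns {sorted(missing)}")
    bad_sex = set(df["sex"]) - set(_SEXES)
    if bad_sex:
        raise ValueError(f"unknown sex values {sorted(bad_sex)} in {path}")

    if dialect == "probability":
        if (df["value"] >= 1).any() or (df["value"] < 0).any():
            bad = df[(df["value"] >= 1) | (df["value"] < 0)].iloc[0]
            raise ValueError(
                f"annual death probability must lie in [0,1): got {bad['value']} "
                f"at (age={bad['age']}, sex={bad['sex']}, year={bad['year']})"
            )
        df = df.assign(value=-np.log1p(-df["value"]))
    elif (df["value"] < 0).any():
        bad = df[df["value"] < 0].iloc[0]
        raise ValueError(
            f"hazard rate must be >= 0: got {bad['value']} "
            f"at (age={bad['age']}, sex={bad['sex']}, year={bad['year']})"
        )

    age_min, age_max = int(df["age"].min()), int(df["age"].max())
    year_min, year_max = int(df["year"].min()), int(df["year"].max())
    ages = np.arange(age_min, age_max + 1)
    years = np.arange(year_min, year_max + 1)
    hazard = {}
    for sex, sub in df.groupby("sex"):
        grid = sub.pivot_table(index="age", columns="year", values="value",
                               aggfunc="first")
        grid = grid.reindex(index=ages, columns=years)
        if grid.isna().any().any():
            a = grid.index[grid.isna().any(axis=1)][0]
            y = grid.columns[grid.isna().any(axis=0)][0]
            raise ValueError(
                f"life table {path} has a missing cell inside its declared "
                f"ranges, e.g. (age={a}, sex={sex}, year={y})"
            )
        hazard[sex] = grid.to_numpy(dtype=float)
    return LifeTable(age_min=age_min, age_max=age_max,
                     year_min=year_min, year_max=year_max, hazard=hazard)


def population_hazard(lt: LifeTable, age, sex: str, year):
    """Background hazard per year at real-valued attained age and year."""
    return lt.hazard_at(age, sex, year)


class PopulationPath:
    """A subject's background-hazard trajectory from diagnosis onward.

    Precomputes the piecewise-constant hazard along the joint attained
    age / calendar-year path starting at ``(age0, year0)``, so that
    cumulative hazards, expected survival and inverse-CDF sampling are
    cheap repeated operations.  Beyond ``horizon`` the final hazard is
    extended as a constant (the table clamps anyway).
    """

    def __init__(self, lt: LifeTable, age0: float, sex: str, year0: float,
                 horizon: float = 120.0):
        if age0 < 0:
            raise ValueError("age at diagnosis must be >= 0")
        self.age0, self.sex, self.year0 = float(age0), sex, float(year0)
        # hazard changes whenever attained age or calendar year crosses
        # an integer; take the union of both breakpoint ladders
        cuts_age = np.arange(math.floor(age0) + 1 - age0, horizon, 1.0)
        cuts_year = np.arange(math.floor(year0) + 1 - year0, horizon, 1.0)
        starts = np.unique(np.concatenate([[0.0], cuts_age, cuts_year]))
        starts = starts[starts < horizon]
        self.starts = starts
        mid = starts + 1e-9  # evaluate just inside each piece
        self.piece_hazard = np.asarray(
            lt.hazard_at(age0 + mid, sex, year0 + mid), dtype=float)
        widths = np.diff(np.append(starts, horizon))
        # cumulative hazard at each piece start
        self.cum_at_start = np.concatenate(
            [[0.0], np.cumsum(self.piece_hazard * widths)[:-1]])
        self.horizon = float(horizon)

    def cum_hazard(self, t):
        """Cumulative background hazard H_pop(t); vectorised, t >= 0."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("t must be >= 0")
        idx = np.searchsorted(self.starts, t, side="right") - 1
        return self.cum_at_start[idx] + self.piece_hazard[idx] * (t - self.starts[idx])

    def hazard(self, t):
        """Background hazard at time t since diagnosis."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.starts, t, side="right") - 1
        return self.piece_hazard[idx]

    def inverse_cum_hazard(self, e: float) -> float:
        """Smallest t with H_pop(t) = e; +inf when never reached."""
        cum_end = self.cum_at_start[-1] + self.piece_hazard[-1] * (
            self.horizon - self.starts[-1])
        if e > cum_end:
            if self.piece_hazard[-1] <= 0:
                return math.inf
            return self.horizon + (e - cum_end) / self.piece_hazard[-1]
        idx = int(np.searchsorted(self.cum_at_start, e, side="right")) - 1
        h = self.piece_hazard[idx]
        if h <= 0:  # flat piece: event occurs at first later accrual
            later = np.nonzero(self.cum_at_start > e - 1e-300)[0]
            if later.size == 0:
                return math.inf
            return float(self.starts[later[0]])
        return float(self.starts[idx] + (e - self.cum_at_start[idx]) / h)


def expected_survival_individual(lt: LifeTable, age0: float, sex: str,
                                 year0: float, t) -> np.ndarray | float:
    """Expected survival S_pop(t) of one subject from diagnosis.

    ``exp(-integral of the background hazard along the attained-age /
    calendar path)``; equals the product of one-year cell survival
    probabilities over integer horizons.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    horizon = max(120.0, float(np.max(t_arr)) + 1.0)
    path = PopulationPath(lt, age0, sex, year0, horizon=horizon)
    out = np.exp(-path.cum_hazard(t_arr))
    return float(out) if np.isscalar(t) or out.ndim == 0 else out


def expected_survival_cohort(lt: LifeTable, cohort, grid) -> np.ndarray:
    """Ederer II expected survival of a cohort on a time grid.

    At each grid step the conditional expected survival factors of the
    subjects still at risk (followed beyond the step start) are
    averaged; the curve is the running product.  Subjects stop
    contributing once censored or dead, which is the Ederer II
    convention.  Returns the curve evaluated at ``grid`` (values in
    (0, 1], nonincreasing; the value at t=0 is 1).
    """
    from .cohort import Cohort  # local import to avoid a cycle

    if isinstance(cohort, Cohort):
        df = cohort.df
    else:
        df = cohort
    if len(df) == 0:
        raise ValueError("cohort is empty")
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0) or grid[0] < 0:
        raise ValueError("grid must be strictly increasing and nonnegative")
    horizon = max(120.0, float(grid[-1]) + 1.0)
    paths = [PopulationPath(lt, a, s, y, horizon=horizon)
             for a, s, y in zip(df["age"], df["sex"], df["year"])]
    times = df["time"].to_numpy(dtype=float)
    pts = np.concatenate([[0.0], grid])
    cum = np.stack([p.cum_hazard(pts) for p in paths])  # (n, len(grid)+1)
    cond = np.exp(-np.diff(cum, axis=1))                # per-interval factors
    surv = np.empty(grid.size)
    running = 1.0
    last = None
    for j in range(grid.size):
        at_risk = times > pts[j]
        if at_risk.any():
            running *= float(np.mean(cond[at_risk, j]))
            last = running
        # nobody at risk: Ederer II accrues nothing, curve stays flat
        surv[j] = running if last is not None else running
    return surv
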