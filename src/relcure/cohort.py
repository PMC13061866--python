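"""Individual-level cohort records.

A cohort is a table of follow-up records: one row per subject with age,
sex and calendar year at diagnosis, follow-up time in years, an
all-cause death indicator, and any number of extra covariate columns
(treatment group, BMI, comorbidity, ...).  Internally it is a pandas
DataFrame with validated core columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CORE_COLUMNS = ("id", "age", "sex", "year", "time", "event")


@dataclass(frozen=True)
class Cohort:
    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in CORE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"cohort is missing columns {missing}")
        if len(df) == 0:
            raise ValueError("cohort has no subjects")
        if (df["time"] <= 0).any():
            bad = df.loc[df["time"] <= 0, "id"].iloc[0]
            raise ValueError(f"follow-up time must be > 0 (subject {bad!r})")
        if not df["event"].isin([0, 1]).all():
            raise ValueError("event must be 0 (censored) or 1 (death)")
        if not df["sex"].isin(["male", "female"]).all():
            raise ValueError("sex must be 'male' or 'female'")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.df.columns if c not in CORE_COLUMNS]

    @property
    def n_events(self) -> int:
        return int(self.df["event"].sum())

    def subset(self, mask) -> "Cohort":
        return Cohort(self.df.loc[mask].reset_index(drop=True))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def read_cohort(path) -> Cohort:
    """Read a cohort CSV (columns ``id,age,sex,year,time,event[,...]``)."""
    df = pd.read_csv(path, float_precision="round_trip")
    return Cohort(df)


def make_cohort(age, sex, year, time, event, ids=None, covariates=None) -> Cohort:
    """Assemble a cohort from arrays (convenience for simulation/tests)."""
    n = len(np.asarray(time))
    data = {
        "id": np.arange(n) if ids is None else ids,
        "age": np.broadcast_to(np.asarray(age, dtype=float), (n,)),
        "sex": np.broadcast_to(np.asarray(sex), (n,)),
        "year": np.broadcast_to(np.asarray(year, dtype=float), (n,)),
        "time": np.asarray(time, dtype=float),
        "event": np.asarray(event, dtype=int),
    }
    df = pd.DataFrame(data)
    if covariates:
        for name, values in covariates.items():
            df[name] = values
    return Cohort(df)
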