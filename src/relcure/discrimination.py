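"""Time-dependent ROC/AUC with inverse-probability-of-censoring weights.

Discrimination of a risk marker at a fixed horizon h uses the
cumulative/dynamic definition: cases die by h, controls survive past h.
Right censoring is handled by weighting subjects by the inverse of the
Kaplan-Meier estimate of the censoring survival function G (Uno-style
IPCW), so that with no censoring the estimate reduces exactly to the
proportion of concordant case-control pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .cohort import Cohort

__all__ = ["AUCSeries", "censoring_weights", "time_dependent_auc"]


@dataclass(frozen=True)
class AUCSeries:
    horizons: np.ndarray
    auc: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"horizon": self.horizons, "auc": self.auc,
                             "ci_low": self.ci_low, "ci_high": self.ci_high})


def _censoring_km(times, events):
    """KM of the censoring distribution (censorings are the 'events')."""
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=1 - np.asarray(events))
    sf = kmf.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)

def _sf_left(times_grid, values, t):
    """Left limit G(t-) of a right-continuous step function."""
    idx = np.searchsorted(times_grid, np.asarray(t, dtype=float), side="left") - 1
    return np.where(idx >= 0, values[np.clip(idx, 0, None)], 1.0)


def censoring_weights(cohort: Cohort, horizon: float) -> np.ndarray:
    """IPCW weights at a horizon.

    Cases (death at t_i <= horizon) get 1/G(t_i-), subjects still in
    follow-up past the horizon get 1/G(horizon); subjects censored
    before the horizon without an event get weight 0.
    """
    df = cohort.df
    times = df["time"].to_numpy(dtype=float)
    events = df["event"].to_numpy(dtype=int)
    if horizon > times.max():
        raise ValueError("horizon lies beyond the observed follow-up")
    gt, gv = _censoring_km(times, events)
    w = np.zeros(len(df))
    case = (events == 1) & (times <= horizon)
    control = times > horizon
    g_case = _sf_left(gt, gv, times[case])
    g_ctrl = _sf_left(gt, gv, np.full(control.sum(), horizon))
    if np.any(g_case <= 0) or np.any(g_ctrl <= 0):
        raise ValueError("censoring survival estimate reaches 0 before the "
                         "horizon; IPCW weights undefined")
    w[case] = 1.0 / g_case
    w[control] = 1.0 / g_ctrl
    return w


def _weighted_auc(marker, case, control, w):
    mc, wc = marker[case], w[case]
    mk, wk = marker[control], w[control]
    # pairwise concordance with ties counted half
    greater = (mc[:, None] > mk[None, :]).astype(float)
    ties = (mc[:, None] == mk[None, :])
    conc = greater + 0.5 * ties
    weight = wc[:, None] * wk[None, :]
    return float(np.sum(conc * weight) / np.sum(weight))


def time_dependent_auc(marker, cohort: Cohort, horizons,
                       n_boot: int = 500, seed: int = 0,
                       alpha: float = 0.05) -> AUCSeries:
    """Cumulative/dynamic IPCW AUC of a risk marker at fixed horizons.

    Higher marker values must mean higher predicted risk of death by
    the horizon.  CIs are percentile bootstrap over subjects (seeded);
    set ``n_boot=0`` to skip them.  Horizons with no cases or no
    controls yield NaN with a warning.
    """
    marker = np.asarray(marker, dtype=float)
    df = cohort.df
    times = df["time"].to_numpy(dtype=float)
    events = df["event"].to_numpy(dtype=int)
    if marker.shape != times.shape or not np.all(np.isfinite(marker)):
        raise ValueError("marker must be finite, one value per subject")
    horizons = np.asarray(horizons, dtype=float)
    if np.any(np.diff(horizons) <= 0):
        raise ValueError("horizons must be strictly increasing")

    rng = np.random.default_rng(seed)
    n = len(df)
    boot_idx = [rng.integers(0, n, size=n) for _ in range(n_boot)]

    auc = np.full(horizons.size, np.nan)
    lo = np.full(horizons.size, np.nan)
    hi = np.full(horizons.size, np.nan)
    for j, h in enumerate(horizons):
        w = censoring_weights(cohort, h)
        case = (events == 1) & (times <= h)
        control = times > h
        if not case.any() or not control.any():
            warnings.warn(f"no cases or no controls at horizon {h}; "
                          "AUC undefined")
            continue
        auc[j] = _weighted_auc(marker, case, control, w)
        if n_boot:
            stats = []
            for idx in boot_idx:
                c, k = case[idx], control[idx]
                if c.any() and k.any():
                    stats.append(_weighted_auc(marker[idx], c, k, w[idx]))
            if stats:
                lo[j], hi[j] = np.percentile(stats, [100 * alpha / 2,
                                                     100 * (1 - alpha / 2)])
    return AUCSeries(horizons=horizons, auc=auc, ci_low=lo, ci_high=hi)
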