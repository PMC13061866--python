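"""Config-driven orchestration of the full cure-modelling workflow.

A run loads (or simulates) a cohort against a life table, estimates
relative survival and interval SMRs, fits the requested mixture cure
model families, selects one by AIC, derives cure points under both
criteria, refits per subgroup, fits the covariate cure regression, and
evaluates time-dependent discrimination — writing a JSON report plus
CSV artifacts, fully deterministic given the configured seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cohort import Cohort, read_cohort
from .cure_inference import (conditional_cure_probability,
                             cure_point_conditional, cure_point_smr,
                             population_curves)
from .cure_models import (ConvergenceError, CureModelSpec, FitOptions,
                          PopulationTerms, fit_cure_model,
                          predict_cure_probability, select_by_aic)
from .discrimination import time_dependent_auc
from .families import FAMILIES
from .life_tables import (LifeTable, PopulationPath, read_life_table)
from .survival_estimators import interval_smr, km_survival, monthly_grid, \
    relative_survival_curve
from .synthetic_data import SimulationConfig, fixture_life_table, simulate_cohort

log = logging.getLogger("relcure")

DEFAULT_FAMILIES = tuple(FAMILIES)


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path} is not a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    payload = {k: v for k, v in cfg.items() if k != "output_dir"}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True,
                   default=str).encode()).hexdigest()[:12]


def _load_life_table(cfg: dict) -> LifeTable:
    spec = cfg.get("life_table", "fixture")
    if spec == "fixture" or spec is None:
        return fixture_life_table()
    if not isinstance(spec, dict) or "path" not in spec:
        raise ConfigError("life_table must be 'fixture' or {path, dialect}")
    return read_life_table(spec["path"], dialect=spec.get("dialect", "rate"))


def _load_cohort(cfg: dict, lt: LifeTable, outdir: Path):
    if "cohort" in cfg and cfg["cohort"]:
        return read_cohort(cfg["cohort"]), None
    if "simulate" not in cfg:
        raise ConfigError("config needs either a cohort path or a "
                          "simulate block")
    sim = dict(cfg["simulate"])
    sim.setdefault("seed", cfg.get("seed", 0))
    if "theta" in sim:
        sim["theta"] = tuple(sim["theta"])
    config = SimulationConfig(**sim)
    cohort, truth = simulate_cohort(config, lt)
    cohort.to_csv(outdir / "cohort.csv")
    truth.to_json(outdir / "truth.json")
    return cohort, truth


def model_risk_marker(fit, cohort: Cohort, lt: LifeTable, horizon: float,
                      pop_sf=None) -> np.ndarray:
    """Predicted probability of death by a horizon, per subject.

    1 - [pi_i + (1 - pi_i) S_u(h)] * S_pop,i(h): disease survival from
    the (possibly covariate-dependent) cure model times the subject's
    expected background survival.
    """
    pi = predict_cure_probability(fit, cohort) if fit.covariates \
        else np.full(len(cohort), fit.pi_hat)
    su = float(fit.uncured_survival(horizon))
    if pop_sf is None:
        pop_sf = subject_expected_survival(cohort, lt, horizon)
    return 1.0 - (pi + (1 - pi) * su) * pop_sf


def subject_expected_survival(cohort: Cohort, lt: LifeTable,
                              t: float) -> np.ndarray:
    df = cohort.df
    out = np.empty(len(df))
    for j, (age, sex, year) in enumerate(zip(df["age"], df["sex"], df["year"])):
        path = PopulationPath(lt, age, sex, year, horizon=max(120.0, t + 1))
        out[j] = np.exp(-float(path.cum_hazard(t)))
    return out


def _fit_summary_or_error(cohort, lt, spec, options, pop):
    try:
        fit = fit_cure_model(cohort, lt, spec, options, pop=pop)
        return fit, None
    except ConvergenceError as exc:
        return exc.best_fit, str(exc)
    except ValueError as exc:
        return None, str(exc)


def _no_definitive_cure(fit) -> bool:
    """Boundary / flat-likelihood diagnostics: the cure fraction is not
    identified (its CI spans essentially all of (0,1), the Hessian is
    not PD, or the estimate sits at the boundary)."""
    if fit is None or not fit.converged:
        return True
    lo, hi = fit.pi_ci
    if hi - lo > 0.90 or fit.pi_hat < 1e-4 or fit.pi_hat > 1 - 1e-4:
        return True
    return any("positive definite" in m or "singular" in m
               for m in fit.messages)


def run_analysis(config: dict | str | Path) -> dict:
    """Execute the full workflow described by a run configuration.

    ``config`` is a mapping or a path to a YAML file; returns the run
    report (also written to ``<output_dir>/report.json``).
    """
    cfg = load_config(config) if not isinstance(config, dict) else config
    seed = int(cfg.get("seed", 0))
    outdir = Path(cfg.get("output_dir", "relcure_run"))
    (outdir / "fits").mkdir(parents=True, exist_ok=True)
    (outdir / "curves").mkdir(parents=True, exist_ok=True)

    stage = "life_table"
    try:
        lt = _load_life_table(cfg)
        stage = "cohort"
        cohort, truth = _load_cohort(cfg, lt, outdir)
        for name in cfg.get("subgroups", []) or []:
            if name not in cohort.df.columns:
                raise ConfigError(f"subgroup column {name!r} not in cohort")
        for name in cfg.get("covariate_model", []) or []:
            if name not in cohort.df.columns:
                raise ConfigError(f"covariate {name!r} not in cohort")

        stage = "survival_estimation"
        t_max = float(cohort.df["time"].max())
        grid = monthly_grid(t_max)
        rs_curve = relative_survival_curve(cohort, lt, grid)
        rs_curve.to_frame().to_csv(outdir / "curves" / "relative_survival.csv",
                                   index=False)
        km = km_survival(cohort)
        km.to_frame().to_csv(outdir / "curves" / "observed_km.csv", index=False)

        stage = "smr"
        max_years = cfg.get("smr", {}).get("max_years")
        breaks = np.arange(0.0, (max_years or np.ceil(t_max)) + 1.0)
        smr = interval_smr(cohort, lt, breaks)
        smr.to_frame().to_csv(outdir / "smr.csv", index=False)

        stage = "model_fitting"
        families = cfg.get("families") or list(DEFAULT_FAMILIES)
        fit_cfg = cfg.get("fit", {}) or {}
        options = FitOptions(n_starts=int(fit_cfg.get("n_starts", 10)),
                             seed=seed, raise_on_failure=False)
        pop = PopulationTerms.from_cohort(cohort, lt)
        fits, fit_errors = {}, {}
        for family in families:
            fit, err = _fit_summary_or_error(
                cohort, lt, CureModelSpec(family=family), options, pop)
            if fit is not None:
                fits[family] = fit
                with open(outdir / "fits" / f"{family}.json", "w") as fh:
                    json.dump(fit.summary(), fh, indent=2, sort_keys=True)
            if err:
                fit_errors[family] = err
                log.warning("family %s: %s", family, err)
        selected = select_by_aic(fits.values())

        stage = "cure_points"
        threshold = cfg.get("cure_point", {}).get("threshold", 0.80)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cp_cond = cure_point_conditional(selected, threshold=threshold)
        cp_smr = cure_point_smr(smr)
        curves = population_curves(selected, grid)
        curves.to_csv(outdir / "curves" / "population_curves.csv", index=False)
        ccp, lo, hi = conditional_cure_probability(
            selected, grid, band=True, seed=seed)
        np.savetxt(outdir / "curves" / "conditional_cure_probability.csv",
                   np.column_stack([grid, ccp, lo, hi]), delimiter=",",
                   header="time,p_cured_given_alive,ci_low,ci_high", comments="")

        stage = "subgroups"
        subgroup_results = {}
        for name in cfg.get("subgroups", []) or []:
            levels = sorted(cohort.df[name].unique(), key=str)
            per_level = {}
            for level in levels:
                sub = cohort.subset(cohort.df[name] == level)
                fit, err = _fit_summary_or_error(
                    sub, lt, CureModelSpec(family=selected.family), options,
                    PopulationTerms.from_cohort(sub, lt))
                entry: dict = {"n": len(sub), "events": sub.n_events}
                if fit is None:
                    entry["status"] = "fit failed"
                    entry["error"] = err
                elif _no_definitive_cure(fit):
                    entry["status"] = "no definitive cure fraction"
                    entry["cure_fraction"] = fit.pi_hat
                else:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        cp = cure_point_conditional(fit, threshold=threshold)
                    sub_smr = interval_smr(sub, lt, breaks)
                    entry.update({
                        "status": "ok",
                        "cure_fraction": fit.pi_hat,
                        "cure_fraction_ci": list(fit.pi_ci),
                        "cure_point_conditional": cp.cure_point,
                        "cure_point_smr": cure_point_smr(sub_smr).cure_point,
                        "aic": fit.aic,
                    })
                per_level[str(level)] = entry
            subgroup_results[name] = per_level

        stage = "covariate_model"
        covariate_result = None
        cov_names = cfg.get("covariate_model", []) or []
        cov_fit = None
        if cov_names:
            cov_fit, err = _fit_summary_or_error(
                cohort, lt, CureModelSpec(family=selected.family,
                                          covariates=tuple(cov_names)),
                options, pop)
            if cov_fit is not None:
                covariate_result = cov_fit.summary()
                with open(outdir / "fits" / "covariate_model.json", "w") as fh:
                    json.dump(covariate_result, fh, indent=2, sort_keys=True)
            else:
                covariate_result = {"status": "fit failed", "error": err}

        stage = "discrimination"
        auc_result = None
        auc_cfg = cfg.get("auc")
        if auc_cfg is not None:
            horizons = [h for h in auc_cfg.get(
                "horizons", list(range(1, 9))) if h < t_max]
            marker_fit = cov_fit if (cov_fit is not None
                                     and cov_fit.converged) else selected
            rows = []
            for h in horizons:
                marker = model_risk_marker(marker_fit, cohort, lt, h)
                series = time_dependent_auc(
                    marker, cohort, [h],
                    n_boot=int(auc_cfg.get("n_boot", 500)), seed=seed)
                rows.append((h, series.auc[0], series.ci_low[0],
                             series.ci_high[0]))
            auc_result = [{"horizon": h, "auc": a, "ci_low": l, "ci_high": u}
                          for h, a, l, u in rows]
            with open(outdir / "auc.csv", "w") as fh:
                fh.write("horizon,auc,ci_low,ci_high\n")
                for h, a, l, u in rows:
                    fh.write(f"{h},{a},{l},{u}\n")
    except ConfigError:
        raise
    except Exception as exc:
        raise RuntimeError(f"analysis failed at stage {stage!r}: {exc}") from exc

    report = {
        "provenance": {
            "version": __version__,
            "config_hash": config_hash(cfg),
            "seed": seed,
        },
        "n": len(cohort),
        "events": cohort.n_events,
        "families_fitted": {name: fit.summary() for name, fit in fits.items()},
        "fit_errors": fit_errors,
        "selected_family": selected.family,
        "cure_fraction": selected.pi_hat,
        "cure_fraction_ci": list(selected.pi_ci),
        "aic": selected.aic,
        "cure_point_conditional": cp_cond.cure_point,
        "cure_point_conditional_threshold": threshold,
        "cure_point_smr": cp_smr.cure_point,
        "smr": smr.to_frame().to_dict(orient="records"),
        "subgroups": subgroup_results,
        "covariate_model": covariate_result,
        "auc": auc_result,
    }
    if truth is not None:
        report["simulation_truth"] = {
            "pi": truth.pi, "mean_pi": truth.mean_pi,
            "family": truth.family, "theta": list(truth.theta),
        }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return report
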