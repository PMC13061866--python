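"""Mixture cure models in the relative-survival framework.

The cohort is modelled as a mixture of a cured subpopulation, subject
only to background (population) mortality, and an uncured subpopulation
with additional disease-related excess hazard:

    RS(t) = pi + (1 - pi) * S_u(t | theta)

where ``pi`` is the cure fraction and ``S_u`` the net survival of the
uncured group, drawn from one of six parametric families.  The observed
all-cause hazard of subject i is ``h_pop,i(t) + h_E(t)`` with excess
hazard ``h_E(t) = (1 - pi_i) f_u(t) / RS_i(t)``, giving the individual
log-likelihood contribution

    d_i * log(h_pop,i(t_i) + h_E(t_i)) - H_pop,i(t_i) + log RS_i(t_i)

The (parameter-free) population terms are kept so that the reported
log-likelihood and AIC refer to the observed data.  Covariates enter
the cure fraction through a logistic link, ``pi_i = expit(b0 + b'x_i)``;
the family parameters theta are shared across subjects.

Fitting is maximum likelihood by multi-start quasi-Newton (L-BFGS-B
with central-difference gradients) on an unconstrained scale; standard
errors come from the inverse numerical Hessian, and confidence
intervals are Wald intervals on the link scale, back-transformed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit
from statsmodels.tools.numdiff import approx_hess1

from .cohort import Cohort
from .families import FAMILIES, ParametricFamily, get_family
from .life_tables import LifeTable, PopulationPath

__all__ = [
    "CureModelSpec", "FitOptions", "CureModelFit", "PopulationTerms",
    "uncured_survival", "mixture_rs", "log_likelihood", "fit_cure_model",
    "select_by_aic", "predict_cure_probability", "design_matrix",
    "pack_params", "ConvergenceError",
]

Z95 = 1.959963984540054


class ConvergenceError(RuntimeError):
    """Raised when no optimizer start converges; carries the best fit found."""

    def __init__(self, message, best_fit=None):
        super().__init__(message)
        self.best_fit = best_fit


@dataclass(frozen=True)
class CureModelSpec:
    """Which excess-survival family to use and which covariates act on pi."""

    family: str
    covariates: tuple[str, ...] = ()

    def get_family(self) -> ParametricFamily:
        return get_family(self.family)


@dataclass(frozen=True)
class FitOptions:
    n_starts: int = 10
    seed: int = 0
    gtol: float = 1e-5       # gradient max-norm, per observation
    ftol: float = 1e-9
    maxiter: int = 1000
    raise_on_failure: bool = True


@dataclass(frozen=True)
class PopulationTerms:
    """Per-subject background-hazard quantities at exit time.

    These are parameter-free, so they are computed once per cohort and
    reused across likelihood evaluations and model families.
    """

    hazard_at_exit: np.ndarray     # h_pop,i(t_i)
    cum_hazard_at_exit: np.ndarray  # H_pop,i(t_i)

    @classmethod
    def from_cohort(cls, cohort: Cohort, lt: LifeTable) -> "PopulationTerms":
        df = cohort.df
        horizon = max(120.0, float(df["time"].max()) + 1.0)
        h = np.empty(len(df))
        H = np.empty(len(df))
        for j, (age, sex, year, time) in enumerate(
                zip(df["age"], df["sex"], df["year"], df["time"])):
            path = PopulationPath(lt, age, sex, year, horizon=horizon)
            h[j] = path.hazard(time)
            H[j] = path.cum_hazard(time)
        return cls(hazard_at_exit=h, cum_hazard_at_exit=H)


def uncured_survival(family, theta, t):
    """S_u(t | theta) for a named family (validates the natural domain)."""
    fam = get_family(family) if isinstance(family, str) else family
    theta = np.asarray(theta, dtype=float)
    fam.check_domain(theta)
    return fam.sf(t, theta)


def mixture_rs(pi, family, theta, t):
    """Model relative survival RS(t) = pi + (1 - pi) S_u(t)."""
    if not 0 <= pi <= 1:
        raise ValueError("cure fraction pi must lie in [0, 1]")
    return pi + (1.0 - pi) * uncured_survival(family, theta, t)


def design_matrix(cohort, covariates, encoding: dict | None = None):
    """Intercept + covariate columns as floats.

    Two-level string columns (e.g. sex) are dummy-coded with the
    lexicographically first level as reference; the learned coding is
    returned so predictions reuse it.  Returns ``(X, encoding)``.
    """
    df = cohort.df if isinstance(cohort, Cohort) else pd.DataFrame(cohort)
    encoding = dict(encoding) if encoding else {}
    cols = [np.ones(len(df))]
    for name in covariates:
        if name not in df.columns:
            raise KeyError(f"covariate {name!r} not present in cohort")
        col = df[name]
        if name in encoding:
            cols.append((col == encoding[name]).to_numpy(dtype=float))
        elif col.dtype == object or str(col.dtype) == "category":
            levels = sorted(col.unique())
            if len(levels) > 2:
                raise ValueError(
                    f"covariate {name!r} is non-numeric with {len(levels)} "
                    "levels; encode it numerically first")
            encoding[name] = levels[-1]
            cols.append((col == levels[-1]).to_numpy(dtype=float))
        else:
            cols.append(col.to_numpy(dtype=float))
    X = np.column_stack(cols)
    if not np.all(np.isfinite(X)):
        raise ValueError("covariate matrix contains non-finite values")
    return X, encoding


def pack_params(spec: CureModelSpec, pi=None, beta=None, theta=None) -> np.ndarray:
    """Assemble the unconstrained parameter vector [beta..., u_theta...].

    Give either ``pi`` (no-covariate model: stored as logit pi) or the
    full ``beta`` vector (intercept first); ``theta`` is on the natural
    scale.
    """
    fam = spec.get_family()
    if beta is None:
        if pi is None:
            raise ValueError("provide pi or beta")
        if spec.covariates:
            raise ValueError("covariate model requires the full beta vector")
        beta = np.array([logit(pi)])
    beta = np.asarray(beta, dtype=float)
    if beta.size != len(spec.covariates) + 1:
        raise ValueError(
            f"beta has {beta.size} entries, expected {len(spec.covariates) + 1}")
    fam.check_domain(np.asarray(theta, dtype=float))
    return np.concatenate([beta, fam.to_unconstrained(np.asarray(theta, float))])


def _loglik_vector(params, spec, fam, X, times, events, pop) -> np.ndarray:
    """Per-subject log-likelihood contributions (may contain -inf/nan)."""
    n_beta = X.shape[1]
    beta = params[:n_beta]
    theta = fam.to_natural(params[n_beta:])
    pi = expit(X @ beta)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        log_sf = fam.log_sf(times, theta)
        rs = pi + (1.0 - pi) * np.exp(log_sf)
        contrib = np.where(events == 1, 0.0, np.log(rs))
        if events.any():
            e = events == 1
            dens = (1.0 - pi[e]) * np.exp(fam.log_pdf(times[e], theta))
            # log(h_pop * RS + (1-pi) f_u) == log(h_pop + h_E) + log RS
            contrib_e = np.log(pop.hazard_at_exit[e] * rs[e] + dens)
            contrib = contrib.copy()
            contrib[e] = contrib_e
    return contrib - pop.cum_hazard_at_exit


def log_likelihood(cohort: Cohort, lt: LifeTable, spec: CureModelSpec,
                   params, pop: PopulationTerms | None = None) -> float:
    """Observed-data log-likelihood at an unconstrained parameter vector.

    ``params`` is ``[beta..., u_theta...]`` — the logit-scale cure
    coefficients (a single logit-pi when the spec has no covariates)
    followed by the family parameters on their unconstrained scale.
    Use :func:`pack_params` to build it from natural-scale values.
    """
    fam = spec.get_family()
    params = np.asarray(params, dtype=float)
    if pop is None:
        pop = PopulationTerms.from_cohort(cohort, lt)
    X, _ = design_matrix(cohort, spec.covariates)
    times = cohort.df["time"].to_numpy(dtype=float)
    events = cohort.df["event"].to_numpy(dtype=int)
    vec = _loglik_vector(params, spec, fam, X, times, events, pop)
    if not np.all(np.isfinite(vec)):
        bad = cohort.df["id"].iloc[int(np.argmax(~np.isfinite(vec)))]
        raise ValueError(
            f"non-finite log-likelihood contribution for subject {bad!r}")
    return float(np.sum(vec))


def _central_grad(f, x, h=1e-6):
    g = np.empty_like(x)
    for i in range(x.size):
        step = h * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += step
        xm[i] -= step
        g[i] = (f(xp) - f(xm)) / (2 * step)
    return g


@dataclass(frozen=True)
class CureModelFit:
    """A fitted relative-survival mixture cure model."""

    spec: CureModelSpec
    params: np.ndarray            # unconstrained [beta..., u_theta...]
    beta: np.ndarray              # logit-scale cure coefficients
    theta: np.ndarray             # family parameters, natural scale
    pi_hat: float                 # cure fraction at the baseline profile
    pi_ci: tuple[float, float]
    loglik: float
    aic: float
    vcov: np.ndarray              # on the unconstrained scale
    converged: bool
    grad_norm: float
    n: int
    events: int
    n_starts_used: int = 0
    seed: int = 0
    messages: tuple[str, ...] = ()
    encoding: dict = field(default_factory=dict)  # string-covariate coding

    @property
    def family(self) -> str:
        return self.spec.family

    @property
    def n_free_params(self) -> int:
        return self.params.size

    @property
    def covariates(self) -> tuple[str, ...]:
        return self.spec.covariates

    def uncured_survival(self, t):
        return self.spec.get_family().sf(t, self.theta)

    def rs(self, t, pi=None):
        """Model relative survival at the baseline (or given) cure fraction."""
        p = self.pi_hat if pi is None else pi
        return p + (1.0 - p) * self.uncured_survival(t)

    def beta_table(self) -> pd.DataFrame:
        names = ["intercept", *self.spec.covariates]
        se = np.sqrt(np.clip(np.diag(self.vcov)[:self.beta.size], 0, None))
        return pd.DataFrame({
            "name": names, "coef": self.beta, "se": se,
            "ci_low": self.beta - Z95 * se, "ci_high": self.beta + Z95 * se,
        })

    def theta_dict(self) -> dict[str, float]:
        return dict(zip(self.spec.get_family().param_names,
                        map(float, self.theta)))

    def summary(self) -> dict:
        return {
            "family": self.family,
            "covariates": list(self.covariates),
            "cure_fraction": self.pi_hat,
            "cure_fraction_ci": list(self.pi_ci),
            "beta": self.beta_table().to_dict(orient="records"),
            "theta": self.theta_dict(),
            "loglik": self.loglik,
            "aic": self.aic,
            "n": self.n,
            "events": self.events,
            "converged": self.converged,
            "grad_norm": self.grad_norm,
            "messages": list(self.messages),
        }


def _start_points(fam, spec, times, events, options) -> list[np.ndarray]:
    rng = np.random.default_rng(options.seed)
    event_times = times[events == 1]
    theta0 = fam.to_unconstrained(fam.init(event_times))
    pi_grid = [0.05, 0.1, 0.2, 0.4]
    starts = []
    for i in range(options.n_starts):
        pi0 = pi_grid[i % len(pi_grid)]
        beta0 = np.zeros(len(spec.covariates) + 1)
        beta0[0] = logit(pi0)
        th = theta0.copy()
        if i >= len(pi_grid):  # perturb later starts for basin coverage
            th = th + rng.normal(scale=0.5, size=th.size)
            beta0[0] += rng.normal(scale=0.5)
        starts.append(np.concatenate([beta0, th]))
    return starts


def fit_cure_model(cohort: Cohort, lt: LifeTable, spec: CureModelSpec,
                   options: FitOptions = FitOptions(),
                   pop: PopulationTerms | None = None) -> CureModelFit:
    """Maximum-likelihood fit of a relative-survival mixture cure model.

    Runs ``options.n_starts`` deterministic L-BFGS-B starts (seeded by
    ``options.seed``) and keeps the best; convergence requires the
    per-observation gradient max-norm to fall below ``options.gtol``.
    Raises :class:`ConvergenceError` (carrying the best fit) if no start
    converges and ``options.raise_on_failure`` is set.
    """
    fam = spec.get_family()
    if cohort.n_events < 1:
        raise ValueError("cure model needs at least one observed death")
    if pop is None:
        pop = PopulationTerms.from_cohort(cohort, lt)
    X, encoding = design_matrix(cohort, spec.covariates)
    times = cohort.df["time"].to_numpy(dtype=float)
    events = cohort.df["event"].to_numpy(dtype=int)
    n = len(cohort)

    def neg_ll(x):
        vec = _loglik_vector(x, spec, fam, X, times, events, pop)
        total = np.sum(vec)
        return np.inf if not np.isfinite(total) else -float(total)

    def neg_grad(x):
        return _central_grad(neg_ll, x)

    best = None
    for x0 in _start_points(fam, spec, times, events, options):
        if not np.isfinite(neg_ll(x0)):
            continue
        try:
            res = optimize.minimize(
                neg_ll, x0, jac=neg_grad, method="L-BFGS-B",
                options={"maxiter": options.maxiter, "ftol": options.ftol,
                         "gtol": options.gtol * n * 0.1})
        except (FloatingPointError, np.linalg.LinAlgError):  # pragma: no cover
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise ConvergenceError(
            f"no finite starting point for family {spec.family!r}")

    x = best.x
    gnorm = float(np.max(np.abs(neg_grad(x)))) / n
    converged = gnorm < options.gtol or bool(best.success)
    messages = []
    if gnorm >= options.gtol:
        messages.append(f"per-observation gradient max-norm {gnorm:.2e} "
                        f"above tolerance {options.gtol:.0e}")

    x, relabel_msg = _canonicalize(spec, fam, x)
    if relabel_msg:
        messages.append(relabel_msg)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hess = approx_hess1(x, neg_ll)
    hess = 0.5 * (hess + hess.T)
    try:
        vcov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(hess)
        messages.append("Hessian singular; covariance from pseudo-inverse")
    if np.any(np.diag(vcov) < 0):
        messages.append("Hessian not positive definite at the optimum "
                        "(possible boundary or flat likelihood)")

    n_beta = X.shape[1]
    beta = x[:n_beta]
    theta = fam.to_natural(x[n_beta:])
    se0 = float(np.sqrt(max(vcov[0, 0], 0.0)))
    pi_hat = float(expit(beta[0]))
    pi_ci = (float(expit(beta[0] - Z95 * se0)), float(expit(beta[0] + Z95 * se0)))
    loglik = -float(best.fun)
    fit = CureModelFit(
        spec=spec, params=x, beta=beta, theta=theta, pi_hat=pi_hat,
        pi_ci=pi_ci, loglik=loglik, aic=2 * x.size - 2 * loglik,
        vcov=vcov, converged=converged, grad_norm=gnorm, n=n,
        events=int(events.sum()), n_starts_used=options.n_starts,
        seed=options.seed, messages=tuple(messages), encoding=encoding)
    if not converged and options.raise_on_failure:
        raise ConvergenceError(
            f"family {spec.family!r} did not converge "
            f"(gradient max-norm {gnorm:.3g})", best_fit=fit)
    return fit


def _canonicalize(spec, fam, x):
    """Resolve mixture label switching: report sigma1 <= sigma2."""
    if spec.family != "weibull_weibull":
        return x, None
    n_beta = x.size - fam.n_params
    theta = fam.to_natural(x[n_beta:])
    p, k1, s1, k2, s2 = theta
    if s1 <= s2:
        return x, None
    theta = np.array([1.0 - p, k2, s2, k1, s1])
    return np.concatenate([x[:n_beta], fam.to_unconstrained(theta)]), \
        "mixture components relabelled so that sigma1 <= sigma2"


def select_by_aic(fits) -> CureModelFit:
    """Pick the converged fit with minimal AIC.

    Ties break toward fewer parameters, then the canonical family
    order.  A single converged candidate is returned with a warning.
    """
    fits = list(fits)
    converged = [f for f in fits if f.converged]
    if not converged:
        raise ValueError("no converged fits to select from")
    if len(converged) == 1 and len(fits) > 1:
        warnings.warn("only one candidate converged; AIC selection is moot")
    order = {name: i for i, name in enumerate(FAMILIES)}
    return min(converged,
               key=lambda f: (f.aic, f.n_free_params, order.get(f.family, 99)))


def predict_cure_probability(fit: CureModelFit, covariates=None) -> np.ndarray:
    """Per-subject cure probability expit(b0 + b'x) under a fitted model."""
    if not fit.covariates:
        n = 1 if covariates is None else len(covariates)
        return np.full(n, fit.pi_hat)
    if covariates is None:
        raise ValueError("fit has covariates; supply a covariate table")
    X, _ = design_matrix(covariates, fit.covariates, encoding=fit.encoding)
    return expit(X @ fit.beta)
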