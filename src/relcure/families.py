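"""Parametric survival families for the uncured component.

Six families for the uncured group's net (relative) survival S_u(t):

* ``exponential``                S_u = exp(-t/sigma)
* ``weibull``                    S_u = exp(-(t/sigma)^k)
* ``lognormal``                  S_u = 1 - Phi((ln t - mu)/s)
* ``weibull_exponential``        p*Weibull + (1-p)*Exponential mixture
* ``weibull_weibull``            two-component Weibull mixture
* ``generalized_modified_weibull``
                                 S_u = 1 - [1 - exp(-b t^gamma e^{lambda t})]^alpha

Each family exposes log S_u and log f_u on the natural parameter scale
plus a smooth bijection to an unconstrained scale (log for positive
parameters, logit for mixture weights) used by the optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats
from scipy.special import expit, logit, logsumexp

__all__ = ["ParametricFamily", "FAMILIES", "get_family"]


def _log1mexp(x):
    """log(1 - exp(x)) for x < 0, numerically stable both near 0 and -inf."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        return np.where(x > -np.log(2.0),
                        np.log(-np.expm1(np.minimum(x, -1e-300))),
                        np.log1p(-np.exp(x)))


@dataclass(frozen=True)
class ParametricFamily:
    name: str
    param_names: tuple[str, ...]
    log_sf: Callable  # (t, theta) -> log S_u(t)
    log_pdf: Callable  # (t, theta) -> log f_u(t)
    to_natural: Callable  # unconstrained u -> natural theta
    to_unconstrained: Callable  # natural theta -> u
    check_domain: Callable  # natural theta -> None or raises
    init: Callable  # event times -> natural theta guess

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def sf(self, t, theta):
        return np.exp(self.log_sf(np.asarray(t, float), np.asarray(theta, float)))

    def pdf(self, t, theta):
        return np.exp(self.log_pdf(np.asarray(t, float), np.asarray(theta, float)))


def _pos(theta, names, idx):
    for i in idx:
        if not theta[i] > 0:
            raise ValueError(f"parameter {names[i]!r} must be > 0, got {theta[i]}")


# -- exponential: theta = (sigma,) ------------------------------------------

def _exp_log_sf(t, th):
    return -t / th[0]


def _exp_log_pdf(t, th):
    return -np.log(th[0]) - t / th[0]


# -- weibull: theta = (k, sigma) --------------------------------------------

def _wei_log_sf(t, th):
    k, s = th
    with np.errstate(divide="ignore"):
        return -np.exp(k * (np.log(t) - np.log(s)))


def _wei_log_pdf(t, th):
    k, s = th
    logt = np.log(t)
    return np.log(k) - np.log(s) + (k - 1) * (logt - np.log(s)) \
        - np.exp(k * (logt - np.log(s)))


# -- lognormal: theta = (mu, s) ---------------------------------------------

def _lnorm_log_sf(t, th):
    mu, s = th
    with np.errstate(divide="ignore"):
        return stats.norm.logsf((np.log(t) - mu) / s)


def _lnorm_log_pdf(t, th):
    mu, s = th
    z = (np.log(t) - mu) / s
    return stats.norm.logpdf(z) - np.log(s) - np.log(t)


# -- two-component mixtures --------------------------------------------------

def _mix_log(p, la, lb):
    """log(p*exp(la) + (1-p)*exp(lb)) stably; handles scalar or array t."""
    la, lb = np.asarray(la, float), np.asarray(lb, float)
    shape = np.broadcast(la, lb).shape
    stacked = np.stack([np.atleast_1d(la), np.atleast_1d(lb)])
    w = np.array([p, 1.0 - p])
    with np.errstate(divide="ignore"):
        logw = np.log(w)
    out = logsumexp(stacked + logw[:, None], axis=0)
    return out.reshape(shape) if shape else out[0]


def _we_log_sf(t, th):
    p, k, s, lam = th
    return _mix_log(p, _wei_log_sf(t, (k, s)), -t / lam)


def _we_log_pdf(t, th):
    p, k, s, lam = th
    return _mix_log(p, _wei_log_pdf(t, (k, s)), -np.log(lam) - t / lam)


def _ww_log_sf(t, th):
    p, k1, s1, k2, s2 = th
    return _mix_log(p, _wei_log_sf(t, (k1, s1)), _wei_log_sf(t, (k2, s2)))


def _ww_log_pdf(t, th):
    p, k1, s1, k2, s2 = th
    return _mix_log(p, _wei_log_pdf(t, (k1, s1)), _wei_log_pdf(t, (k2, s2)))


# -- generalized modified Weibull: theta = (alpha, b, gamma, lam) ------------
# S_u(t) = 1 - G(t)^alpha with G(t) = 1 - exp(-b t^gamma e^{lam t})

def _gmw_parts(t, th):
    alpha, b, gamma, lam = th
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore"):
        logt = np.log(t)
    z = b * np.exp(gamma * logt + lam * t)
    log_g_cdf = _log1mexp(-z)  # log G(t)
    return z, logt, log_g_cdf


def _gmw_log_sf(t, th):
    alpha = th[0]
    _, _, log_g = _gmw_parts(t, th)
    return _log1mexp(np.minimum(alpha * log_g, -1e-300))


def _gmw_log_pdf(t, th):
    alpha, b, gamma, lam = th
    z, logt, log_g = _gmw_parts(t, th)
    log_g_pdf = np.log(b) + lam * t + (gamma - 1) * logt \
        + np.log(gamma + lam * t) - z
    return np.log(alpha) + (alpha - 1) * log_g + log_g_pdf


def _median(times):
    times = np.asarray(times, float)
    return float(np.median(times)) if times.size else 1.0


FAMILIES: dict[str, ParametricFamily] = {}


def _register(fam: ParametricFamily) -> None:
    FAMILIES[fam.name] = fam


_register(ParametricFamily(
    name="exponential",
    param_names=("sigma",),
    log_sf=_exp_log_sf, log_pdf=_exp_log_pdf,
    to_natural=lambda u: np.exp(u),
    to_unconstrained=lambda th: np.log(th),
    check_domain=lambda th: _pos(th, ("sigma",), [0]),
    init=lambda times: np.array([max(_median(times), 1e-3)]),
))

_register(ParametricFamily(
    name="weibull",
    param_names=("shape", "sigma"),
    log_sf=_wei_log_sf, log_pdf=_wei_log_pdf,
    to_natural=lambda u: np.exp(u),
    to_unconstrained=lambda th: np.log(th),
    check_domain=lambda th: _pos(th, ("shape", "sigma"), [0, 1]),
    init=lambda times: np.array([1.0, max(_median(times), 1e-3)]),
))

_register(ParametricFamily(
    name="lognormal",
    param_names=("mu", "s"),
    log_sf=_lnorm_log_sf, log_pdf=_lnorm_log_pdf,
    to_natural=lambda u: np.array([u[0], np.exp(u[1])]),
    to_unconstrained=lambda th: np.array([th[0], np.log(th[1])]),
    check_domain=lambda th: _pos(th, ("mu", "s"), [1]),
    init=lambda times: np.array([np.log(max(_median(times), 1e-3)), 1.0]),
))

_register(ParametricFamily(
    name="weibull_exponential",
    param_names=("p", "shape", "sigma", "lam"),
    log_sf=_we_log_sf, log_pdf=_we_log_pdf,
    to_natural=lambda u: np.array([expit(u[0]), *np.exp(u[1:])]),
    to_unconstrained=lambda th: np.array([logit(th[0]), *np.log(th[1:])]),
    check_domain=lambda th: (
        _pos(th, ("p", "shape", "sigma", "lam"), [1, 2, 3]),
        None if 0 <= th[0] <= 1 else (_ for _ in ()).throw(
            ValueError("mixture weight p must lie in [0, 1]")))[-1],
    init=lambda times: np.array(
        [0.5, 1.0, max(_median(times), 1e-3), max(_median(times), 1e-3)]),
))

_register(ParametricFamily(
    name="weibull_weibull",
    param_names=("p", "shape1", "sigma1", "shape2", "sigma2"),
    log_sf=_ww_log_sf, log_pdf=_ww_log_pdf,
    to_natural=lambda u: np.array([expit(u[0]), *np.exp(u[1:])]),
    to_unconstrained=lambda th: np.array([logit(th[0]), *np.log(th[1:])]),
    check_domain=lambda th: (
        _pos(th, ("p", "shape1", "sigma1", "shape2", "sigma2"), [1, 2, 3, 4]),
        None if 0 <= th[0] <= 1 else (_ for _ in ()).throw(
            ValueError("mixture weight p must lie in [0, 1]")))[-1],
    init=lambda times: np.array(
        [0.5, 1.0, max(0.5 * _median(times), 1e-3),
         1.0, max(2.0 * _median(times), 1e-3)]),
))

_register(ParametricFamily(
    name="generalized_modified_weibull",
    param_names=("alpha", "b", "gamma", "lam"),
    log_sf=_gmw_log_sf, log_pdf=_gmw_log_pdf,
    to_natural=lambda u: np.exp(u),
    to_unconstrained=lambda th: np.log(th),
    check_domain=lambda th: (
        _pos(th, ("alpha", "b", "gamma", "lam"), [0, 1, 2]),
        None if th[3] >= 0 else (_ for _ in ()).throw(
            ValueError("parameter 'lam' must be >= 0")))[-1],
    init=lambda times: np.array(
        [1.0, 1.0 / max(_median(times), 1e-3), 1.0, 1e-3]),
))


def get_family(name: str) -> ParametricFamily:
    try:
        return FAMILIES[name]
    except KeyError:
        raise ValueError(
            f"unknown family {name!r}; available: {list(FAMILIES)}") from None
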