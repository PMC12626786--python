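"""Parametric survival fitting, model selection, and extrapolation.

Eight families are supported, covering the standard choices for
extrapolating oncology trial endpoints beyond follow-up: exponential,
gamma, generalized gamma, Gompertz, Weibull (accelerated-failure-time
and proportional-hazards parameterizations), log-logistic and
log-normal.  Fitting is maximum likelihood under right censoring,

    ll = sum_i [ d_i * log f(t_i) + (1 - d_i) * log S(t_i) ],

maximized by multi-start quasi-Newton optimization on log-transformed
scale parameters (shape parameters that may be negative — the Gompertz
shape and the generalized-gamma Q — stay on the natural scale).

Parameterizations (time in months throughout):

===================  ==========================  =============================
family               params                      survival function
===================  ==========================  =============================
exponential          rate                        exp(-rate*t)
gamma                shape, rate                 1 - P(shape, rate*t)
generalized-gamma    mu, sigma, Q                Prentice location/scale/shape
gompertz             shape, rate                 exp(-rate/shape*(e^{shape*t}-1))
weibull              shape, scale  (AFT)         exp(-(t/scale)^shape)
weibull-ph           shape, rate   (PH)          exp(-rate*t^shape)
log-logistic         shape, scale                1/(1+(t/scale)^shape)
log-normal           mu, sigma                   1 - Phi((log t - mu)/sigma)
===================  ==========================  =============================

P is the regularized lower incomplete gamma function and Phi the standard
normal CDF.  The generalized gamma follows the location/scale/shape
convention of the flexible-survival literature: for Q != 0, with
w = (log t - mu)/sigma and u = Q^-2 * exp(Q*w),

    S(t) = 1 - P(Q^-2, u)   if Q > 0,
    S(t) = P(Q^-2, u)       if Q < 0,

and Q -> 0 recovers the log-normal.  A negative Gompertz shape yields a
survival plateau S(inf) = exp(rate/shape) > 0, which is why this family
is implemented directly rather than through a library distribution
restricted to positive shapes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "FAMILIES",
    "SurvivalFit",
    "fit",
    "fit_all",
    "select_best",
    "survival_at",
    "cumulative_hazard_at",
    "fits_to_table",
    "fit_to_json",
]

_TINY = 1e-300


# ---------------------------------------------------------------------------
# family definitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Family:
    name: str
    param_names: tuple[str, ...]
    # True where the parameter is constrained positive (optimized on log scale)
    positive: tuple[bool, ...]
    logpdf: Callable[[np.ndarray, np.ndarray], np.ndarray]
    logsf: Callable[[np.ndarray, np.ndarray], np.ndarray]
    starts: Callable[[np.ndarray, np.ndarray], list[np.ndarray]]

    @property
    def k(self) -> int:
        return len(self.param_names)


def _exp_logpdf(t, p):
    return np.log(p[0]) - p[0] * t


def _exp_logsf(t, p):
    return -p[0] * t


def _gamma_logpdf(t, p):
    return stats.gamma.logpdf(t, a=p[0], scale=1.0 / p[1])


def _gamma_logsf(t, p):
    return stats.gamma.logsf(t, a=p[0], scale=1.0 / p[1])


def _gengamma_logpdf(t, p):
    mu, sigma, q = p
    logt = np.log(t)
    if abs(q) < 1e-5:
        return stats.norm.logpdf(logt, loc=mu, scale=sigma) - logt
    w = (logt - mu) / sigma
    qi2 = q ** -2.0
    return (
        np.log(abs(q))
        - np.log(sigma)
        - logt
        + qi2 * np.log(qi2)
        - special.gammaln(qi2)
        + qi2 * (q * w - np.exp(np.clip(q * w, -700.0, 700.0)))
    )


def _gengamma_logsf(t, p):
    mu, sigma, q = p
    logt = np.log(t)
    if abs(q) < 1e-5:
        return stats.norm.logsf(logt, loc=mu, scale=sigma)
    w = (logt - mu) / sigma
    qi2 = q ** -2.0
    u = qi2 * np.exp(np.clip(q * w, -700.0, 700.0))
    if q > 0:
        sf = special.gammaincc(qi2, u)
    else:
        sf = special.gammainc(qi2, u)
    return np.log(np.maximum(sf, _TINY))


def _gompertz_cumhaz(t, shape, rate):
    if abs(shape) < 1e-9:
        return rate * t
    return rate / shape * np.expm1(np.clip(shape * t, -700.0, 700.0))


def _gompertz_logpdf(t, p):
    shape, rate = p
    return np.log(rate) + shape * t - _gompertz_cumhaz(t, shape, rate)


def _gompertz_logsf(t, p):
    return -_gompertz_cumhaz(t, p[0], p[1])


def _weibull_logpdf(t, p):
    shape, scale = p
    z = t / scale
    return np.log(shape / scale) + (shape - 1.0) * np.log(z) - z ** shape


def _weibull_logsf(t, p):
    return -((t / p[1]) ** p[0])


def _weibullph_logpdf(t, p):
    shape, rate = p
    return np.log(rate * shape) + (shape - 1.0) * np.log(t) - rate * t ** shape


def _weibullph_logsf(t, p):
    return -p[1] * t ** p[0]


def _loglogistic_logpdf(t, p):
    return stats.fisk.logpdf(t, c=p[0], scale=p[1])


def _loglogistic_logsf(t, p):
    return stats.fisk.logsf(t, c=p[0], scale=p[1])


def _lognormal_logpdf(t, p):
    return stats.lognorm.logpdf(t, s=p[1], scale=math.exp(p[0]))


def _lognormal_logsf(t, p):
    return stats.lognorm.logsf(t, s=p[1], scale=math.exp(p[0]))


def _event_times(times, events):
    et = times[events.astype(bool)]
    return et if et.size else times


def _starts_exponential(times, events):
    rate = max(events.sum(), 1.0) / times.sum()
    return [np.array([rate])]


def _starts_gamma(times, events):
    et = _event_times(times, events)
    m, v = et.mean(), max(et.var(), 1e-6)
    shape = max(m * m / v, 0.05)
    return [np.array([shape, shape / m]), np.array([1.0, 1.0 / m])]


def _starts_gengamma(times, events):
    lt = np.log(_event_times(times, events))
    mu, sigma = lt.mean(), max(lt.std(), 0.1)
    return [np.array([mu, sigma, q]) for q in (-0.5, 0.5, 1.0, 1.5)]


def _starts_gompertz(times, events):
    rate = max(events.sum(), 1.0) / times.sum()
    return [np.array([s, rate]) for s in (-0.05, 0.01, 0.05)]


def _starts_weibull(times, events):
    et = _event_times(times, events)
    scale = et.mean()
    return [np.array([s, scale]) for s in (0.7, 1.0, 1.5)]


def _starts_weibullph(times, events):
    et = _event_times(times, events)
    scale = et.mean()
    return [np.array([s, scale ** -s]) for s in (0.7, 1.0, 1.5)]


def _starts_loglogistic(times, events):
    et = _event_times(times, events)
    return [np.array([s, np.median(et)]) for s in (0.8, 1.5, 3.0)]


def _starts_lognormal(times, events):
    lt = np.log(_event_times(times, events))
    return [np.array([lt.mean(), max(lt.std(), 0.1)])]


FAMILIES: dict[str, _Family] = {
    f.name: f
    for f in [
        _Family("exponential", ("rate",), (True,),
                _exp_logpdf, _exp_logsf, _starts_exponential),
        _Family("gamma", ("shape", "rate"), (True, True),
                _gamma_logpdf, _gamma_logsf, _starts_gamma),
        _Family("generalized-gamma", ("mu", "sigma", "Q"), (False, True, False),
                _gengamma_logpdf, _gengamma_logsf, _starts_gengamma),
        _Family("gompertz", ("shape", "rate"), (False, True),
                _gompertz_logpdf, _gompertz_logsf, _starts_gompertz),
        _Family("weibull", ("shape", "scale"), (True, True),
                _weibull_logpdf, _weibull_logsf, _starts_weibull),
        _Family("weibull-ph", ("shape", "rate"), (True, True),
                _weibullph_logpdf, _weibullph_logsf, _starts_weibullph),
        _Family("log-logistic", ("shape", "scale"), (True, True),
                _loglogistic_logpdf, _loglogistic_logsf, _starts_loglogistic),
        _Family("log-normal", ("mu", "sigma"), (False, True),
                _lognormal_logpdf, _lognormal_logsf, _starts_lognormal),
    ]
}

_ALIASES = {
    "exp": "exponential",
    "gengamma": "generalized-gamma",
    "weibull-aft": "weibull",
    "weibullph": "weibull-ph",
    "weibull-PH": "weibull-ph",
    "llogis": "log-logistic",
    "lnorm": "log-normal",
}


def _resolve_family(name: str) -> _Family:
    key = _ALIASES.get(name, _ALIASES.get(name.lower(), name.lower()))
    if key not in FAMILIES:
        raise ValueError(
            f"unknown survival family {name!r}; known families: "
            + ", ".join(sorted(FAMILIES))
        )
    return FAMILIES[key]


# ---------------------------------------------------------------------------
# fit result
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurvivalFit:
    """A fitted parametric survival model.

    AIC and BIC follow the usual definitions ``-2*ll + 2k`` and
    ``-2*ll + k*log(n)`` with ``k`` the number of free parameters and
    ``n`` the number of subjects (events plus censored).
    """

    family: str
    params: dict[str, float]
    loglik: float
    aic: float
    bic: float
    n: int

    def param_vector(self) -> np.ndarray:
        fam = _resolve_family(self.family)
        return np.array([self.params[name] for name in fam.param_names])

    def survival(self, t) -> np.ndarray | float:
        return survival_at(self, t)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _pack(fam: _Family, theta: np.ndarray) -> np.ndarray:
    out = theta.astype(float).copy()
    for i, pos in enumerate(fam.positive):
        if pos:
            out[i] = math.log(max(theta[i], 1e-12))
    return out


def _unpack(fam: _Family, z: np.ndarray) -> np.ndarray:
    out = z.astype(float).copy()
    for i, pos in enumerate(fam.positive):
        if pos:
            out[i] = math.exp(min(z[i], 50.0))
    return out


def _negloglik(z, fam: _Family, times, events):
    p = _unpack(fam, np.asarray(z))
    with np.errstate(all="ignore"):
        lp = fam.logpdf(times, p)
        ls = fam.logsf(times, p)
        ll = np.where(events == 1, lp, ls)
    if not np.all(np.isfinite(ll)):
        return 1e12
    return -float(ll.sum())


def fit(ipd, family: str) -> SurvivalFit:
    """Maximum-likelihood fit of one parametric family to right-censored data.

    Parameters
    ----------
    ipd
        A DataFrame with columns ``time`` (or ``time_months``) and
        ``event`` (1 = event, 0 = censored), or any iterable of
        ``(time, event)`` records exposing those attributes.
    family
        Family name (see :data:`FAMILIES`; common aliases such as
        ``"weibull-AFT"`` or ``"gengamma"`` are accepted).

    Raises
    ------
    ValueError
        For an unknown family or data with fewer than two events.
    RuntimeError
        If every optimizer start fails to converge; the message carries
        the optimizer diagnostics.
    """
    fam = _resolve_family(family)
    times, events = _as_arrays(ipd)
    if (events == 1).sum() < 2:
        raise ValueError("at least two events are required to fit a survival model")
    if np.any(times <= 0):
        # digitized grids can place the first event at t=0; nudge off the origin
        times = np.maximum(times, 1e-6)

    if fam.name == "exponential":
        # exact MLE under right censoring: events / total follow-up
        rate = float(events.sum() / times.sum())
        ll = float(events.sum() * math.log(rate) - rate * times.sum())
        n = len(times)
        return SurvivalFit("exponential", {"rate": rate}, ll,
                           -2.0 * ll + 2.0, -2.0 * ll + math.log(n), n)

    best = None
    diagnostics = []
    for theta0 in fam.starts(times, events):
        z0 = _pack(fam, theta0)
        res = optimize.minimize(
            _negloglik, z0, args=(fam, times, events), method="L-BFGS-B",
        )
        diagnostics.append(f"start={np.round(theta0, 4).tolist()} -> "
                           f"success={res.success} nll={res.fun:.4f} ({res.message})")
        if res.fun < 1e11 and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(
            "maximum-likelihood fit failed to converge for family "
            f"{fam.name!r}:\n" + "\n".join(diagnostics)
        )
    # polish with Nelder-Mead, which is robust near ill-conditioned optima
    res = optimize.minimize(_negloglik, best.x, args=(fam, times, events),
                            method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
    if res.fun < best.fun:
        best = res

    p = _unpack(fam, best.x)
    ll = -float(best.fun)
    k = fam.k
    n = len(times)
    return SurvivalFit(
        family=fam.name,
        params=dict(zip(fam.param_names, map(float, p))),
        loglik=ll,
        aic=-2.0 * ll + 2.0 * k,
        bic=-2.0 * ll + k * math.log(n),
        n=n,
    )


def _as_arrays(ipd) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(ipd, pd.DataFrame):
        tcol = "time" if "time" in ipd.columns else "time_months"
        times = ipd[tcol].to_numpy(float)
        events = ipd["event"].to_numpy(int)
    else:
        recs = list(ipd)
        times = np.array([r.time for r in recs], float)
        events = np.array([r.event for r in recs], int)
    if len(times) == 0:
        raise ValueError("empty survival data")
    return times, events


def fit_all(ipd, families: Iterable[str] | None = None) -> list[SurvivalFit]:
    """Fit every family (default: all eight) and return the fits."""
    names = list(families) if families is not None else list(FAMILIES)
    return [fit(ipd, name) for name in names]


def select_best(fits: Sequence[SurvivalFit]) -> SurvivalFit:
    """Pick the fit with the lowest AIC.

    Ties on AIC are broken by the lower BIC, then by fewer parameters.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("select_best requires at least one fit")
    return min(fits, key=lambda f: (f.aic, f.bic, len(f.params)))


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def survival_at(fit: SurvivalFit, t) -> np.ndarray | float:
    """S(t) for a fitted model; S(0) = 1, non-increasing, clipped to [0, 1]."""
    fam = _resolve_family(fit.family)
    tv = np.asarray(t, float)
    if np.any(tv < 0):
        raise ValueError("survival_at requires t >= 0")
    scalar = tv.ndim == 0
    tv = np.atleast_1d(tv)
    p = fit.param_vector()
    s = np.ones_like(tv)
    pos = tv > 0
    with np.errstate(all="ignore"):
        s[pos] = np.exp(fam.logsf(tv[pos], p))
    s = np.clip(s, 0.0, 1.0)
    return float(s[0]) if scalar else s


def cumulative_hazard_at(fit: SurvivalFit, t) -> np.ndarray | float:
    """H(t) = -log S(t)."""
    s = survival_at(fit, t)
    return -np.log(np.maximum(s, _TINY))


def hazard_at(fit: SurvivalFit, t) -> np.ndarray | float:
    """Instantaneous hazard f(t)/S(t)."""
    fam = _resolve_family(fit.family)
    tv = np.atleast_1d(np.asarray(t, float))
    p = fit.param_vector()
    with np.errstate(all="ignore"):
        h = np.exp(fam.logpdf(tv, p) - fam.logsf(tv, p))
    return float(h[0]) if np.asarray(t).ndim == 0 else h


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def fits_to_table(fits: Sequence[SurvivalFit]) -> pd.DataFrame:
    """Goodness-of-fit comparison table (one row per family, AIC-sorted)."""
    rows = [
        {
            "family": f.family,
            "n_params": len(f.params),
            "loglik": f.loglik,
            "aic": f.aic,
            "bic": f.bic,
            **{f"param_{k}": v for k, v in f.params.items()},
        }
        for f in fits
    ]
    return pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)


def fit_to_json(fit: SurvivalFit) -> str:
    return json.dumps(
        {
            "family": fit.family,
            "params": fit.params,
            "loglik": fit.loglik,
            "aic": fit.aic,
            "bic": fit.bic,
            "n": fit.n,
        },
        indent=2,
    )
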