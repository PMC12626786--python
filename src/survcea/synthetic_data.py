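"""Synthetic trial data: ground-truth survival, digitized curves, parameters.

Emulates the inputs of a two-arm consolidation-therapy trial in
limited-stage small-cell lung cancer: per-arm overall-survival (OS) and
progression-free-survival (PFS) event times with right censoring, the
coarse digitized KM coordinates a graph digitizer would extract from the
published figures, and the full cost/utility parameter table of the
economic model.

The bundled two-arm preset gives the intervention arm a proportional
hazard of 0.73 relative to control — a plausible immunotherapy effect
size used purely as a fixture value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from lifelines import KaplanMeierFitter

from .km_reconstruction import KMCurve
from .uncertainty import ParamSpec

__all__ = [
    "TrueSurvivalSpec", "DigitizationSpec", "generate_ipd", "digitize",
    "default_params", "default_ae_incidence", "trial_preset",
    "params_to_yaml", "params_from_yaml",
]


# ---------------------------------------------------------------------------
# ground-truth survival specs
# ---------------------------------------------------------------------------

_SAMPLERS = {}


def _sampler(name):
    def deco(fn):
        _SAMPLERS[name] = fn
        return fn
    return deco


@_sampler("exponential")
def _rvs_exponential(rng, n, p):
    return rng.exponential(1.0 / p["rate"], n)


@_sampler("gamma")
def _rvs_gamma(rng, n, p):
    return rng.gamma(p["shape"], 1.0 / p["rate"], n)


@_sampler("weibull")
def _rvs_weibull(rng, n, p):
    return p["scale"] * rng.weibull(p["shape"], n)


@_sampler("weibull-ph")
def _rvs_weibull_ph(rng, n, p):
    # S(t) = exp(-rate * t^shape): t = (E/rate)^(1/shape), E ~ Exp(1)
    e = rng.exponential(1.0, n)
    return (e / p["rate"]) ** (1.0 / p["shape"])


@_sampler("log-normal")
def _rvs_lognormal(rng, n, p):
    return rng.lognormal(p["mu"], p["sigma"], n)


@_sampler("log-logistic")
def _rvs_loglogistic(rng, n, p):
    u = rng.uniform(0.0, 1.0, n)
    return p["scale"] * (u / (1.0 - u)) ** (1.0 / p["shape"])


@_sampler("gompertz")
def _rvs_gompertz(rng, n, p):
    # H(t) = rate/shape * (exp(shape t) - 1); invert H(t) = E ~ Exp(1).
    # Negative shape gives a cure plateau: subjects with E beyond the
    # total hazard never fail (time = inf, later administratively censored).
    a, b = p["shape"], p["rate"]
    e = rng.exponential(1.0, n)
    if abs(a) < 1e-12:
        return e / b
    arg = 1.0 + a * e / b
    t = np.full(n, np.inf)
    ok = arg > 0
    t[ok] = np.log(arg[ok]) / a
    return t


@_sampler("generalized-gamma")
def _rvs_gengamma(rng, n, p):
    mu, sigma, q = p["mu"], p["sigma"], p["Q"]
    if abs(q) < 1e-5:
        return np.exp(mu + sigma * rng.standard_normal(n))
    g = rng.gamma(q ** -2.0, 1.0, n)
    return np.exp(mu + sigma * np.log(q * q * g) / q)


@dataclass(frozen=True)
class TrueSurvivalSpec:
    """Ground-truth time-to-event distribution for one arm/endpoint."""

    family: str
    params: dict[str, float]
    label: str = ""

    def __post_init__(self):
        if self.family not in _SAMPLERS:
            raise ValueError(
                f"unknown survival family {self.family!r}; known families: "
                + ", ".join(sorted(_SAMPLERS)))
        for key, val in self.params.items():
            if key in ("rate", "scale", "sigma", "shape") and self.family != "gompertz":
                if val <= 0:
                    raise ValueError(f"{self.family} parameter {key} must be > 0")
        if self.family == "gompertz" and self.params["rate"] <= 0:
            raise ValueError("gompertz rate must be > 0")

    def with_hazard_ratio(self, hr: float) -> "TrueSurvivalSpec":
        """Apply a proportional-hazards multiplier (S -> S**hr).

        Exact for the families whose cumulative hazard is linear in the
        rate parameter (exponential, weibull-ph, gompertz).
        """
        p = dict(self.params)
        if self.family in ("exponential", "weibull-ph", "gompertz"):
            p["rate"] *= hr
        elif self.family == "weibull":
            p["scale"] *= hr ** (-1.0 / p["shape"])
        else:
            raise ValueError(
                f"proportional-hazards scaling not defined for {self.family}")
        return replace(self, params=p)


def generate_ipd(spec: TrueSurvivalSpec, n: int, censor_rate: float,
                 admin_censor: float, seed: int) -> pd.DataFrame:
    """Draw right-censored event times from a ground-truth distribution.

    Censoring is the minimum of an independent exponential time with the
    given monthly rate and an administrative cutoff (months).  Returns a
    DataFrame with columns ``time`` and ``event``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= censor_rate < 1.0):
        raise ValueError("censor_rate must lie in [0, 1)")
    if admin_censor <= 0:
        raise ValueError("admin_censor must be positive")
    rng = np.random.default_rng(seed)
    t_event = _SAMPLERS[spec.family](rng, n, spec.params)
    if censor_rate > 0:
        t_cens = rng.exponential(1.0 / censor_rate, n)
    else:
        t_cens = np.full(n, np.inf)
    t_cens = np.minimum(t_cens, admin_censor)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame({"time": time, "event": event})


# ---------------------------------------------------------------------------
# digitization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DigitizationSpec:
    """How a graph digitizer degrades a KM curve.

    grid_step: months between extracted points; prob_round: decimals kept
    on the probability axis; jitter_sd: additive Gaussian noise on the
    probabilities; risk_interval: months between at-risk readings.
    """

    grid_step: float = 1.0
    prob_round: int = 3
    jitter_sd: float = 0.0
    risk_interval: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if self.prob_round < 2:
            raise ValueError("prob_round must be at least 2")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")


def digitize(ipd: pd.DataFrame, dspec: DigitizationSpec, label: str = "") -> KMCurve:
    """Kaplan-Meier estimate on a coarse grid with digitization artefacts.

    The KM estimate is evaluated every ``grid_step`` months, rounded,
    jittered, clamped to [0, 1] and re-monotonized; at-risk counts are
    read every ``risk_interval`` months.
    """
    if len(ipd) == 0:
        raise ValueError("cannot digitize an empty data set")
    if int(ipd["event"].sum()) == 0:
        raise ValueError("cannot digitize a data set with no events")
    kmf = KaplanMeierFitter()
    kmf.fit(ipd["time"], ipd["event"])
    t_max = float(ipd["time"].max())
    grid = np.arange(0.0, t_max + dspec.grid_step / 2, dspec.grid_step)
    surv = kmf.survival_function_at_times(grid).to_numpy(float)
    surv = np.round(surv, dspec.prob_round)
    if dspec.jitter_sd > 0:
        rng = np.random.default_rng(dspec.seed)
        surv = surv + rng.normal(0.0, dspec.jitter_sd, surv.shape)
    surv = np.clip(surv, 0.0, 1.0)
    surv = np.minimum.accumulate(surv)

    risk_times = np.arange(0.0, t_max + dspec.risk_interval / 2,
                           dspec.risk_interval)
    times = ipd["time"].to_numpy(float)
    at_risk = np.array([(times >= rt).sum() for rt in risk_times])
    return KMCurve(grid, surv, risk_times, at_risk, label=label)


# ---------------------------------------------------------------------------
# model parameter table
# ---------------------------------------------------------------------------

_COSTS = {
    "durvalumab": (7631.74, 6105.39, 9158.09),
    "topotecan": (72.17, 57.74, 86.61),
    "carboplatin": (87.94, 70.35, 105.53),
    "etoposide": (266.67, 213.33, 320.00),
    "best_supportive_care": (327.46, 261.97, 392.95),
    "laboratory_test": (134.36, 107.49, 161.23),
    "imaging_examination": (140.65, 112.52, 168.78),
    "palliative_care": (2549.63, 2039.71, 3059.56),
}

_AE_COSTS = {
    "rash": (400.00, 320.00, 480.00),
    "pulmonary_embolism": (992.26, 793.81, 1190.72),
    "anemia": (497.41, 397.93, 596.89),
    "fatigue": (188.20, 150.56, 225.84),
    "diarrhea": (5.18, 4.14, 6.22),
    "hypertension": (14.73, 11.78, 17.67),
}

_UTILITIES = {
    "utility_pfs": (0.673, 0.528, 0.808),
    "utility_pd": (0.473, 0.378, 0.568),
}

_AE_DISUTILITIES = {
    "rash": (0.03, 0.02, 0.04),
    "pulmonary_embolism": (0.20, 0.16, 0.24),
    "anemia": (0.04, 0.03, 0.05),
    "fatigue": (0.01, 0.008, 0.012),
    "diarrhea": (0.39, 0.27, 0.76),
    "hypertension": (0.04, 0.03, 0.05),
}

AE_NAMES = tuple(_AE_COSTS)


def default_params() -> dict[str, ParamSpec]:
    """The full base-case parameter table (costs in USD per cycle,
    utilities per year, 5% annual discount varied over 0-8%).

    Costs draw Gamma distributions in probabilistic analysis, utilities
    and disutilities Beta, and the discount rate a Beta rescaled to its
    [0, 0.08] range.
    """
    out: dict[str, ParamSpec] = {}
    for name, (b, lo, hi) in _COSTS.items():
        out[name] = ParamSpec(name, b, lo, hi, "gamma")
    for name, (b, lo, hi) in _AE_COSTS.items():
        key = f"ae_cost_{name}"
        out[key] = ParamSpec(key, b, lo, hi, "gamma")
    for name, (b, lo, hi) in _UTILITIES.items():
        out[name] = ParamSpec(name, b, lo, hi, "beta")
    for name, (b, lo, hi) in _AE_DISUTILITIES.items():
        key = f"disutility_{name}"
        out[key] = ParamSpec(key, b, lo, hi, "beta")
    out["discount_rate"] = ParamSpec("discount_rate", 0.05, 0.0, 0.08,
                                     "scaled-beta")
    return out


def default_ae_incidence(prob: float = 0.05) -> dict[str, dict[str, float]]:
    """Per-arm grade-3+ adverse-event probabilities.

    The economic model only counts events with incidence above 5%; the
    fixture sets every listed event to that inclusion floor in both arms
    (incidences are study inputs, not published constants).
    """
    return {
        "control": {name: prob for name in AE_NAMES},
        "intervention": {name: prob for name in AE_NAMES},
    }


def params_to_yaml(params: dict[str, ParamSpec]) -> str:
    return yaml.safe_dump(
        {
            name: {"base": s.base, "low": s.low, "high": s.high,
                   "dist": s.dist}
            for name, s in params.items()
        },
        sort_keys=True,
    )


def params_from_yaml(text: str) -> dict[str, ParamSpec]:
    raw = yaml.safe_load(text)
    return {
        name: ParamSpec(name, d["base"], d["low"], d["high"], d["dist"])
        for name, d in raw.items()
    }


# ---------------------------------------------------------------------------
# two-arm trial preset
# ---------------------------------------------------------------------------

def _weibull_ph_rate(shape: float, median: float) -> float:
    # S(median) = 0.5 with S(t) = exp(-rate * t^shape)
    return math.log(2.0) / median ** shape


@dataclass(frozen=True)
class TrialPreset:
    """Shapes and sizes of the synthetic two-arm trial."""

    os_control: TrueSurvivalSpec
    pfs_control: TrueSurvivalSpec
    os_intervention: TrueSurvivalSpec
    pfs_intervention: TrueSurvivalSpec
    n_per_arm: int = 265
    censor_rate: float = 0.005
    admin_censor: float = 38.0

    def specs(self) -> dict[tuple[str, str], TrueSurvivalSpec]:
        return {
            ("control", "os"): self.os_control,
            ("control", "pfs"): self.pfs_control,
            ("intervention", "os"): self.os_intervention,
            ("intervention", "pfs"): self.pfs_intervention,
        }

    def simulate(self, seed: int) -> dict[tuple[str, str], pd.DataFrame]:
        """One IPD table per (arm, endpoint), seeded per endpoint."""
        out = {}
        for i, (key, spec) in enumerate(self.specs().items()):
            out[key] = generate_ipd(spec, self.n_per_arm, self.censor_rate,
                                    self.admin_censor, seed=seed * 4 + i)
        return out


def trial_preset(hazard_ratio: float = 0.73, n_per_arm: int = 265,
                 censor_rate: float = 0.005,
                 admin_censor: float = 38.0) -> TrialPreset:
    """Two-arm consolidation-trial fixture.

    Control OS is Weibull (shape 1.2, median 33 months) and control PFS
    Weibull (shape 0.85, median 9 months) — limited-stage SCLC scale.
    The intervention arm applies a proportional-hazards multiplier
    (default 0.73) to both endpoints.  Follow-up is administratively
    censored at 38 months with light random dropout.
    """
    os_c = TrueSurvivalSpec("weibull-ph",
                            {"shape": 1.2, "rate": _weibull_ph_rate(1.2, 33.0)},
                            label="control OS")
    pfs_c = TrueSurvivalSpec("weibull-ph",
                             {"shape": 0.85, "rate": _weibull_ph_rate(0.85, 9.0)},
                             label="control PFS")
    return TrialPreset(
        os_control=os_c,
        pfs_control=pfs_c,
        os_intervention=replace(os_c.with_hazard_ratio(hazard_ratio),
                                label="intervention OS"),
        pfs_intervention=replace(pfs_c.with_hazard_ratio(hazard_ratio),
                                 label="intervention PFS"),
        n_per_arm=n_per_arm,
        censor_rate=censor_rate,
        admin_censor=admin_censor,
    )
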