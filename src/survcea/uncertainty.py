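"""Deterministic and probabilistic sensitivity analysis, CEAC, EVPI.

Parameter uncertainty is described by :class:`ParamSpec` (base value plus
a low-high interval and a distribution family).  For probabilistic
analysis the interval is treated as a 95% range, giving a standard error
se = (high - low)/3.92 which is moment-matched to the stated family:
Gamma for costs (mean = base), Beta for utilities and disutilities, and
a Beta rescaled to its bounded support for the discount rate.  Each
parameter samples from its own named random stream derived from the
master seed, so adding or removing a parameter never shuffles the draws
of the others, and extending the number of draws reproduces the original
prefix exactly.

Survival-curve uncertainty is deliberately not re-sampled: the analysis
varies cost, utility and discount parameters around fixed fitted curves.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cea_outcomes import compute_icer

__all__ = ["ParamSpec", "moment_match", "sample_param", "one_way_dsa",
           "run_psa", "PSAResult", "ceac", "evpi"]


@dataclass(frozen=True)
class ParamSpec:
    """One uncertain model parameter.

    dist is one of ``"gamma"`` (costs), ``"beta"`` (utilities,
    disutilities) or ``"scaled-beta"`` (parameters with a bounded
    support other than [0, 1], such as the discount rate on [0, 0.08]).
    """

    name: str
    base: float
    low: float
    high: float
    dist: str = "gamma"

    def __post_init__(self):
        if not (self.low <= self.base <= self.high):
            raise ValueError(
                f"{self.name}: require low <= base <= high "
                f"({self.low}, {self.base}, {self.high})")
        if self.dist not in ("gamma", "beta", "scaled-beta"):
            raise ValueError(f"{self.name}: unknown distribution {self.dist!r}")

    @property
    def se(self) -> float:
        """Standard error treating [low, high] as a 95% interval."""
        return (self.high - self.low) / 3.92


def moment_match(spec: ParamSpec, se_rule: str = "interval95") -> dict:
    """Distribution parameters matching the spec's mean and spread.

    ``se_rule="interval95"`` uses se = (high - low)/3.92;
    ``se_rule="prop20"`` uses se = 0.2 * base.  A zero spread returns a
    degenerate point-mass flag.
    """
    if se_rule == "interval95":
        se = spec.se
    elif se_rule == "prop20":
        se = 0.2 * spec.base
    else:
        raise ValueError(f"unknown se_rule {se_rule!r}")
    if se == 0:
        return {"dist": "degenerate", "value": spec.base}
    if spec.dist == "gamma":
        return {"dist": "gamma",
                "shape": spec.base ** 2 / se ** 2,
                "rate": spec.base / se ** 2}
    if spec.dist == "beta":
        return {"dist": "beta", **_beta_shapes(spec.base, se)}
    # scaled beta on [low, high] with mean = base
    width = spec.high - spec.low
    m = (spec.base - spec.low) / width
    return {"dist": "scaled-beta", "lo": spec.low, "hi": spec.high,
            **_beta_shapes(m, se / width)}


def _beta_shapes(mean: float, se: float) -> dict:
    var = min(se ** 2, mean * (1.0 - mean) * 0.999)  # Beta feasibility bound
    common = mean * (1.0 - mean) / var - 1.0
    return {"shape1": mean * common, "shape2": (1.0 - mean) * common}


def sample_param(spec: ParamSpec, rng: np.random.Generator,
                 size: int, se_rule: str = "interval95") -> np.ndarray:
    mm = moment_match(spec, se_rule)
    if mm["dist"] == "degenerate":
        return np.full(size, mm["value"])
    if mm["dist"] == "gamma":
        return rng.gamma(mm["shape"], 1.0 / mm["rate"], size)
    draws = rng.beta(mm["shape1"], mm["shape2"], size)
    if mm["dist"] == "scaled-beta":
        draws = mm["lo"] + draws * (mm["hi"] - mm["lo"])
    return draws


def _param_rng(master_seed: int, name: str) -> np.random.Generator:
    # one named stream per parameter: stable under parameter-set changes
    return np.random.default_rng(
        np.random.SeedSequence([master_seed, zlib.crc32(name.encode())]))


# ---------------------------------------------------------------------------
# one-way deterministic sensitivity analysis
# ---------------------------------------------------------------------------

def one_way_dsa(model, specs: Mapping[str, ParamSpec] | Sequence[ParamSpec],
                wtp: float) -> pd.DataFrame:
    """Tornado table: ICER with each parameter at its low and high bound.

    Rows are sorted by descending ICER range; a model failure on one
    parameter is recorded in its row rather than aborting the analysis.
    """
    if not isinstance(specs, Mapping):
        specs = {s.name: s for s in specs}
    base = model.cea(wtp)
    rows = []
    for name, spec in specs.items():
        row = {"parameter": name, "base": spec.base, "low": spec.low,
               "high": spec.high, "icer_low": np.nan, "icer_high": np.nan,
               "range": np.nan, "error": ""}
        try:
            icer_lo = model.cea(wtp, overrides={name: spec.low}).icer
            icer_hi = model.cea(wtp, overrides={name: spec.high}).icer
            if isinstance(icer_lo, str) or isinstance(icer_hi, str):
                row["error"] = f"non-numeric ICER ({icer_lo!r}, {icer_hi!r})"
            else:
                row.update(icer_low=icer_lo, icer_high=icer_hi,
                           range=abs(icer_hi - icer_lo))
        except Exception as exc:  # recorded per-row, not fatal
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    df = pd.DataFrame(rows)
    df["base_icer"] = base.icer if not isinstance(base.icer, str) else np.nan
    return df.sort_values("range", ascending=False,
                          na_position="last").reset_index(drop=True)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PSAResult:
    """Monte-Carlo draws of parameters and per-arm outcomes.

    ``samples`` has one row per draw with the sampled parameter values
    and columns ``cost0``, ``qaly0``, ``cost1``, ``qaly1``.
    """

    samples: pd.DataFrame
    seed: int

    @property
    def n_draws(self) -> int:
        return len(self.samples)

    def inmb(self, wtp: float) -> np.ndarray:
        s = self.samples
        return (wtp * (s["qaly1"] - s["qaly0"])
                - (s["cost1"] - s["cost0"])).to_numpy()

    def quadrant_counts(self) -> dict[str, int]:
        """CE-plane quadrant counts under the explicit convention:
        x = incremental QALY, y = incremental cost; NE means costlier
        and more effective."""
        s = self.samples
        dq = (s["qaly1"] - s["qaly0"]).to_numpy()
        dc = (s["cost1"] - s["cost0"]).to_numpy()
        return {
            "NE": int(((dq > 0) & (dc > 0)).sum()),
            "NW": int(((dq < 0) & (dc > 0)).sum()),
            "SW": int(((dq < 0) & (dc < 0)).sum()),
            "SE": int(((dq > 0) & (dc < 0)).sum()),
        }


def run_psa(model, specs: Mapping[str, ParamSpec] | Sequence[ParamSpec],
            n_draws: int = 1000, seed: int = 0,
            se_rule: str = "interval95") -> PSAResult:
    """Monte-Carlo propagation of parameter uncertainty through the model."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if not isinstance(specs, Mapping):
        specs = {s.name: s for s in specs}
    draws = {
        name: sample_param(spec, _param_rng(seed, name), n_draws, se_rule)
        for name, spec in specs.items()
    }
    records = []
    for i in range(n_draws):
        overrides = {name: float(vals[i]) for name, vals in draws.items()}
        totals = model.evaluate(overrides)
        c, t = totals["control"], totals["intervention"]
        records.append({"draw": i, **overrides,
                        "cost0": c.cost, "qaly0": c.qaly,
                        "cost1": t.cost, "qaly1": t.qaly})
    samples = pd.DataFrame(records)
    if not np.all(np.isfinite(samples.drop(columns="draw").to_numpy())):
        raise RuntimeError("non-finite outcomes in PSA draws")
    return PSAResult(samples=samples, seed=seed)


def ceac(result: PSAResult, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve for the intervention.

    At each WTP, the fraction of draws whose incremental net monetary
    benefit is positive.
    """
    if result.n_draws == 0:
        raise ValueError("CEAC requires at least one draw")
    rows = [{"wtp": w, "p_cost_effective": float((result.inmb(w) > 0).mean())}
            for w in wtp_grid]
    return pd.DataFrame(rows)


def evpi(result: PSAResult, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Expected value of perfect information per decision.

    EVPI(wtp) = E[max_s NMB_s] - max_s E[NMB_s] over the two strategies;
    non-negative by Jensen's inequality.
    """
    if result.n_draws == 0:
        raise ValueError("EVPI requires at least one draw")
    s = result.samples
    rows = []
    for w in wtp_grid:
        nmb0 = (w * s["qaly0"] - s["cost0"]).to_numpy()
        nmb1 = (w * s["qaly1"] - s["cost1"]).to_numpy()
        value = float(np.maximum(nmb0, nmb1).mean()
                      - max(nmb0.mean(), nmb1.mean()))
        rows.append({"wtp": w, "evpi": max(value, 0.0)})
    return pd.DataFrame(rows)
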