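"""Scenario transforms, value-based price inversion, subgroup runner.

Three stock scenario shapes are supported, mirroring the common policy
questions for a high-price consolidation therapy: a negotiated price cut
on the intervention drug, alternative health-state utilities, and a cap
on treatment duration.  Value-based pricing inverts the (monotone)
ICER-versus-price map to find the per-cycle price at which the
intervention meets a willingness-to-pay threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping

import pandas as pd
from scipy import optimize

from .cea_outcomes import CEAResult, compute_icer
from .markov_engine import DecisionModel

__all__ = ["ScenarioSpec", "apply_scenario", "scenario_model",
           "run_scenarios", "threshold_price", "run_subgroup"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScenarioSpec:
    """One scenario: price multiplier, optional utility overrides,
    optional treatment-duration cap (cycles)."""

    name: str
    price_multiplier: float = 1.0
    utility_override: tuple[float, float] | None = None  # (u_pfs, u_pd)
    treatment_cap_cycles: int | None = None

    def __post_init__(self):
        if self.price_multiplier <= 0:
            raise ValueError("price_multiplier must be positive")
        if self.utility_override is not None:
            u_pfs, u_pd = self.utility_override
            if not (0.0 <= u_pfs <= 1.0 and 0.0 <= u_pd <= 1.0):
                raise ValueError("override utilities must lie in [0, 1]")


def apply_scenario(params: Mapping[str, float],
                   spec: ScenarioSpec) -> dict[str, float]:
    """A new parameter mapping with the scenario applied; the input is
    left untouched.  The price multiplier applies to the intervention
    drug only."""
    out = dict(params)
    out["durvalumab"] = out["durvalumab"] * spec.price_multiplier
    if spec.utility_override is not None:
        out["utility_pfs"], out["utility_pd"] = spec.utility_override
    return out


def scenario_model(model: DecisionModel, spec: ScenarioSpec) -> DecisionModel:
    """A new model with the scenario's parameters and treatment cap."""
    new = replace(model, params=apply_scenario(model.params, spec))
    if spec.treatment_cap_cycles is not None:
        new = replace(new, treatment_cap_cycles=spec.treatment_cap_cycles)
    return new


def default_scenarios() -> list[ScenarioSpec]:
    """The stock scenario set: 30% price cut; literature utilities
    (PFS 0.86, PD 0.77); 24-month treatment cap."""
    return [
        ScenarioSpec("price_cut_30pct", price_multiplier=0.7),
        ScenarioSpec("alternative_utilities", utility_override=(0.86, 0.77)),
        ScenarioSpec("treatment_cap_24mo", treatment_cap_cycles=24),
    ]


def run_scenarios(model: DecisionModel, specs: list[ScenarioSpec],
                  wtp: float) -> pd.DataFrame:
    """Scenario results table (one block per scenario, base case first)."""
    frames = []
    base = model.cea(wtp).to_table()
    base.insert(0, "scenario", "base_case")
    frames.append(base)
    for spec in specs:
        tbl = scenario_model(model, spec).cea(wtp).to_table()
        tbl.insert(0, "scenario", spec.name)
        frames.append(tbl)
    return pd.concat(frames, ignore_index=True)


def threshold_price(model: DecisionModel, wtp: float,
                    price_bracket: tuple[float, float],
                    tol: float = 0.01) -> float:
    """Per-cycle intervention-drug price at which the ICER equals the WTP.

    The ICER is strictly monotone in the drug price for a fixed positive
    QALY increment, so the root is found by bracketed bisection (Brent);
    the bracket ICERs must straddle the target.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    lo, hi = price_bracket

    def gap(price: float) -> float:
        icer = model.cea(wtp, overrides={"durvalumab": price}).icer
        if isinstance(icer, str):
            raise ValueError(
                f"ICER is {icer} at price {price:.2f}; threshold search "
                "requires a positive QALY increment")
        return icer - wtp

    g_lo, g_hi = gap(lo), gap(hi)
    if g_lo * g_hi > 0:
        raise ValueError(
            "price bracket does not straddle the target WTP: "
            f"ICER({lo:.2f}) = {g_lo + wtp:.2f}, "
            f"ICER({hi:.2f}) = {g_hi + wtp:.2f}, target {wtp:.2f}")
    return float(optimize.brentq(gap, lo, hi, xtol=tol))


def run_subgroup(model: DecisionModel,
                 subgroup_overrides: Mapping[str, Mapping],
                 wtp: float) -> pd.DataFrame:
    """Full pipeline re-run per subgroup.

    Each override may contain hazard-ratio adjustments
    (``hr_os_intervention``, ``hr_pfs_intervention``, ``hr_os_control``,
    ``hr_pfs_control``; S -> S**hr on the stored curves), parameter
    overrides under ``params``, and/or replacement survival arrays under
    ``surv``.  A subgroup whose ``surv`` entry is incomplete is skipped
    with a logged reason; results keep the input order.
    """
    rows = []
    for name, ov in subgroup_overrides.items():
        sub = model
        try:
            if "surv" in ov:
                surv = ov["surv"]
                missing = {"control", "intervention"} - set(surv)
                if missing:
                    raise KeyError(
                        f"missing survival inputs for arms {sorted(missing)}")
                sub = replace(sub, surv=surv)
            for key, (arm, endpoint) in (
                ("hr_os_control", ("control", "os")),
                ("hr_pfs_control", ("control", "pfs")),
                ("hr_os_intervention", ("intervention", "os")),
                ("hr_pfs_intervention", ("intervention", "pfs")),
            ):
                if key in ov:
                    sub = sub.with_hazard_ratio(arm, endpoint, ov[key])
            if "params" in ov:
                sub = replace(sub, params={**sub.params, **ov["params"]})
            r = sub.cea(wtp)
            rows.append({"subgroup": name, "status": "ok",
                         "cost0": r.cost0, "qaly0": r.qaly0,
                         "cost1": r.cost1, "qaly1": r.qaly1,
                         "d_cost": r.d_cost, "d_qaly": r.d_qaly,
                         "icer": r.icer, "inmb": r.inmb})
        except Exception as exc:
            log.warning("subgroup %s skipped: %s", name, exc)
            rows.append({"subgroup": name,
                         "status": f"skipped: {type(exc).__name__}: {exc}"})
    return pd.DataFrame(rows)
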