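"""Pairwise economic outcomes: ICER, net monetary benefit, dominance.

All arithmetic is in USD.  Inputs priced in CNY are converted once at the
configuration boundary using the 2024 average exchange rate of
7.11 CNY/USD; nothing downstream ever sees mixed currencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["CNY_PER_USD", "CHINA_GDP_PER_CAPITA_2024", "WTPPolicy",
           "threshold_set", "compute_icer", "compute_nmb", "CEAResult",
           "DOMINANT", "DOMINATED", "UNDEFINED"]

CNY_PER_USD = 7.11
#: 2024 per-capita GDP in USD; 1-3x this is the willingness-to-pay range.
CHINA_GDP_PER_CAPITA_2024 = 12_569.82

DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined"


def cny_to_usd(amount_cny: float) -> float:
    return amount_cny / CNY_PER_USD


@dataclass(frozen=True)
class WTPPolicy:
    """Willingness-to-pay policy: multiples of per-capita GDP."""

    gdp_per_capita: float = CHINA_GDP_PER_CAPITA_2024
    multipliers: tuple[float, ...] = (1.0, 2.0, 3.0)


def threshold_set(policy: WTPPolicy) -> tuple[float, ...]:
    """The WTP thresholds implied by a policy (USD per QALY, ascending)."""
    if policy.gdp_per_capita <= 0:
        raise ValueError("gdp_per_capita must be positive")
    return tuple(m * policy.gdp_per_capita for m in policy.multipliers)


def compute_icer(cost0: float, qaly0: float, cost1: float, qaly1: float):
    """Incremental cost-effectiveness ratio of strategy 1 vs strategy 0.

    Returns the ratio d_cost/d_qaly, or a dominance flag: ``"dominant"``
    when strategy 1 is cheaper and more effective, ``"dominated"`` when
    costlier and less effective, ``"undefined"`` when the QALY increment
    is zero (no division is attempted).
    """
    d_cost = cost1 - cost0
    d_qaly = qaly1 - qaly0
    if d_qaly == 0:
        return UNDEFINED
    if d_cost < 0 and d_qaly > 0:
        return DOMINANT
    if d_cost > 0 and d_qaly < 0:
        return DOMINATED
    return d_cost / d_qaly


def compute_nmb(cost: float, qaly: float, wtp: float) -> float:
    """Net monetary benefit wtp*qaly - cost."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return wtp * qaly - cost


@dataclass(frozen=True)
class CEAResult:
    """Per-arm discounted totals plus pairwise outcomes at one WTP.

    The identity inmb == nmb1 - nmb0 == wtp*d_qaly - d_cost holds by
    construction and is asserted when the object is built.
    """

    cost0: float
    qaly0: float
    cost1: float
    qaly1: float
    wtp: float
    ly0: float = float("nan")
    ly1: float = float("nan")
    d_cost: float = field(init=False)
    d_qaly: float = field(init=False)
    icer: object = field(init=False)
    nmb0: float = field(init=False)
    nmb1: float = field(init=False)
    inmb: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "d_cost", self.cost1 - self.cost0)
        object.__setattr__(self, "d_qaly", self.qaly1 - self.qaly0)
        object.__setattr__(self, "icer",
                           compute_icer(self.cost0, self.qaly0,
                                        self.cost1, self.qaly1))
        object.__setattr__(self, "nmb0",
                           compute_nmb(self.cost0, self.qaly0, self.wtp))
        object.__setattr__(self, "nmb1",
                           compute_nmb(self.cost1, self.qaly1, self.wtp))
        object.__setattr__(self, "inmb", self.nmb1 - self.nmb0)
        assert abs(self.inmb - (self.wtp * self.d_qaly - self.d_cost)) <= 1e-6 * (
            1.0 + abs(self.inmb))

    def to_table(self, label0: str = "control",
                 label1: str = "intervention") -> pd.DataFrame:
        """Two-row results table: total costs/QALYs, increments, ICER, NMB."""
        icer = self.icer if isinstance(self.icer, str) else round(self.icer, 2)
        return pd.DataFrame(
            [
                {"treatment": label0, "total_costs": round(self.cost0, 2),
                 "total_qalys": round(self.qaly0, 4), "incre_costs": None,
                 "incre_qalys": None, "icer": None,
                 "nmb": round(self.nmb0, 2), "inmb": None},
                {"treatment": label1, "total_costs": round(self.cost1, 2),
                 "total_qalys": round(self.qaly1, 4),
                 "incre_costs": round(self.d_cost, 2),
                 "incre_qalys": round(self.d_qaly, 4), "icer": icer,
                 "nmb": round(self.nmb1, 2), "inmb": round(self.inmb, 2)},
            ]
        )
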