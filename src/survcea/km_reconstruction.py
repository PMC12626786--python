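"""Pseudo individual-patient data from digitized Kaplan-Meier curves.

Published survival figures report the KM estimate on a coarse grid plus a
number-at-risk table.  :func:`reconstruct` inverts the product-limit
construction interval by interval, in the style of the published
KM-to-IPD reconstruction algorithms: within each inter-risk-reading
interval the number of events at each digitized point is chosen so the
implied KM step ratio matches the digitized ratio, and the number of
censored subjects is iterated until the implied number at risk matches
the next at-risk reading.  Event counts are rounded to integers with a
carried residual so cumulative counts track the curve over many
intervals.  The procedure is fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["KMCurve", "IPDRecord", "reconstruct",
           "read_km_csv", "write_km_csv", "read_ipd_csv", "write_ipd_csv"]

log = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass(frozen=True)
class IPDRecord:
    """One (possibly censored) subject: time in months, event indicator."""

    time: float
    event: int


@dataclass
class KMCurve:
    """A digitized KM curve plus its number-at-risk table.

    ``times``/``surv`` are the digitized coordinates (months, probability);
    ``at_risk_times``/``at_risk`` the at-risk readings.  Survival must be
    non-increasing in [0, 1] and at-risk counts non-increasing.
    """

    times: np.ndarray
    surv: np.ndarray
    at_risk_times: np.ndarray
    at_risk: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.surv = np.asarray(self.surv, float)
        self.at_risk_times = np.asarray(self.at_risk_times, float)
        self.at_risk = np.asarray(self.at_risk, int)

    def validate(self) -> None:
        if self.times.size == 0:
            raise ValueError("empty KM curve")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("KM times must be increasing")
        if self.surv[0] > 1.0 + 1e-12 or np.any(self.surv < -1e-12) or np.any(self.surv > 1 + 1e-12):
            raise ValueError("KM survival probabilities must lie in [0, 1]")
        if np.any(np.diff(self.surv) > 1e-9):
            raise ValueError("KM survival must be non-increasing over time")
        if np.any(np.diff(self.at_risk) > 0):
            raise ValueError("at-risk counts must be non-increasing over time")
        if self.at_risk_times.size < 2:
            raise ValueError("at least two at-risk readings are required")


def reconstruct(curve: KMCurve, total_events: int | None = None) -> pd.DataFrame:
    """Invert a digitized KM curve into pseudo individual-patient data.

    Parameters
    ----------
    curve
        Digitized curve with at least two at-risk readings.  When the
        at-risk table holds only the initial count, censoring is assumed
        to occur only at the administrative tail (flagged in ``df.attrs``).
    total_events
        Optional published total event count; reconstructed per-interval
        event counts are rescaled toward it in a second pass.

    Returns
    -------
    DataFrame with columns ``time`` and ``event`` (1 = event,
    0 = censored), sorted by time.  ``df.attrs["tail_censoring_only"]``
    records the fallback mode.
    """
    curve.validate()
    df = _reconstruct_pass(curve, event_multiplier=1.0)
    if total_events is not None:
        got = int(df["event"].sum())
        if got > 0 and got != total_events:
            df = _reconstruct_pass(curve, event_multiplier=total_events / got)
    return df


def _reconstruct_pass(curve: KMCurve, event_multiplier: float) -> pd.DataFrame:
    t = curve.times
    s = np.clip(curve.surv, 0.0, 1.0)
    # prepend the origin if absent
    if t[0] > 0:
        t = np.concatenate([[0.0], t])
        s = np.concatenate([[1.0], s])
    rt, rn = curve.at_risk_times, curve.at_risk
    tail_only = rt.size < 2
    if tail_only:
        rt = np.array([t[0], t[-1] + 1e-9])
        rn = np.array([rn[0], 0])

    event_times: list[float] = []
    censor_times: list[float] = []

    n_cur = int(rn[0])
    s_prev = 1.0
    residual = 0.0

    n_intervals = len(rt)
    for i in range(n_intervals):
        lo = rt[i]
        hi = rt[i + 1] if i + 1 < n_intervals else np.inf
        mask = (t >= lo) & (t < hi) if np.isfinite(hi) else (t >= lo)
        idx = np.nonzero(mask)[0]
        last = not np.isfinite(hi)
        target_next = None if last else int(rn[i + 1])

        if last:
            ev, ce, n_cur, s_prev, residual = _walk_interval(
                t, s, idx, n_cur, s_prev, residual, 0, lo, t[-1],
                event_multiplier)
            event_times += ev
            censor_times += ce
            # administrative censoring of everyone still at risk
            censor_times += [float(t[-1])] * n_cur
            n_cur = 0
        else:
            c = max(0, n_cur - target_next)  # initial guess: no events
            best = None
            for _ in range(30):
                ev, ce, n_end, s_end, res_end = _walk_interval(
                    t, s, idx, n_cur, s_prev, residual, c, lo, hi,
                    event_multiplier)
                gap = n_end - target_next
                best = (ev, ce, n_end, s_end, res_end)
                if gap == 0 or (gap < 0 and c == 0):
                    break
                c = max(0, c + gap)
            ev, ce, n_cur, s_prev, residual = best
            event_times += ev
            censor_times += ce

    df = pd.DataFrame(
        {
            "time": event_times + censor_times,
            "event": [1] * len(event_times) + [0] * len(censor_times),
        }
    ).sort_values(["time", "event"], ascending=[True, False]).reset_index(drop=True)
    df.attrs["tail_censoring_only"] = tail_only
    if tail_only:
        log.warning("no usable at-risk table for %s: assuming censoring only "
                    "at the administrative tail", curve.label or "curve")
    return df


def _walk_interval(t, s, idx, n_cur, s_prev, residual, n_cens, lo, hi,
                   event_multiplier):
    """Process digitized points in one at-risk interval with n_cens censors
    spread uniformly over the interval.  Returns event times, censor times,
    the number still at risk, the implied KM level, and the carry residual."""
    width = (hi - lo) if np.isfinite(hi) else max(t[-1] - lo, 0.0)
    if n_cens > 0 and width > 0:
        cens_times = lo + (np.arange(n_cens) + 0.5) / n_cens * width
    else:
        cens_times = np.full(n_cens, lo)
    events: list[float] = []
    censors: list[float] = []
    ci = 0
    for k in idx:
        while ci < n_cens and cens_times[ci] < t[k] and n_cur > 0:
            censors.append(float(cens_times[ci]))
            n_cur -= 1
            ci += 1
        if n_cur <= 0 or s_prev <= 0:
            continue
        d_exact = n_cur * (1.0 - s[k] / s_prev) * event_multiplier
        d = int(np.floor(d_exact + residual + 0.5))
        d = min(max(d, 0), n_cur)
        residual += d_exact - d
        if event_multiplier == 1.0:
            # track the implied KM so integer rounding self-corrects
            if d > 0:
                s_prev *= 1.0 - d / n_cur
        else:
            # rescaling mode: follow the digitized curve, otherwise the
            # self-correction would undo the multiplier
            s_prev = max(s[k], _EPS)
        if d > 0:
            events += [float(t[k])] * d
            n_cur -= d
    while ci < n_cens and n_cur > 0:
        censors.append(float(cens_times[ci]))
        n_cur -= 1
        ci += 1
    return events, censors, n_cur, s_prev, residual


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def write_km_csv(curve: KMCurve, km_path, at_risk_path) -> None:
    pd.DataFrame({"time_months": curve.times, "survival": curve.surv}).to_csv(
        km_path, index=False)
    pd.DataFrame({"time_months": curve.at_risk_times,
                  "n_risk": curve.at_risk}).to_csv(at_risk_path, index=False)


def read_km_csv(km_path, at_risk_path, label: str = "") -> KMCurve:
    km = pd.read_csv(km_path)
    ar = pd.read_csv(at_risk_path)
    return KMCurve(km["time_months"].to_numpy(), km["survival"].to_numpy(),
                   ar["time_months"].to_numpy(), ar["n_risk"].to_numpy(),
                   label=label)


def write_ipd_csv(ipd: pd.DataFrame, path, arm: str = "") -> None:
    out = pd.DataFrame({"time_months": ipd["time"], "event": ipd["event"]})
    if arm:
        out["arm"] = arm
    out.to_csv(path, index=False)


def read_ipd_csv(path, arm: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if arm is not None and "arm" in df.columns:
        df = df[df["arm"] == arm]
    return pd.DataFrame({"time": df["time_months"], "event": df["event"]}).reset_index(drop=True)
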