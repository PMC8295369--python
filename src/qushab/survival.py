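"""Recurrence-free survival analysis for the response cohorts.

Kaplan–Meier product-limit curves per cohort and the two-group
log-rank test, both delegated to :mod:`lifelines`.  Follow-up is
administratively truncated at the 10-year study horizon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

__all__ = ["KMEstimate", "kaplan_meier", "log_rank", "truncate_follow_up"]

FOLLOW_UP_YEARS = 10.0


@dataclass
class KMEstimate:
    """Step-function survival estimate with at-risk counts."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def at(self, t: float) -> float:
        """S(t), right-continuous."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def truncate_follow_up(
    times: np.ndarray, events: np.ndarray, horizon: float = FOLLOW_UP_YEARS
) -> tuple[np.ndarray, np.ndarray]:
    """Administrative censoring at the follow-up horizon."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    over = times > horizon
    return np.where(over, horizon, times), np.where(over, 0, events)


def kaplan_meier(times: np.ndarray, events: np.ndarray) -> KMEstimate:
    """Product-limit survival estimate; S(0) = 1, non-increasing steps."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("need at least one record")
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tbl = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"].to_numpy()
    return KMEstimate(
        times=kmf.survival_function_.index.to_numpy(dtype=float),
        survival=surv,
        at_risk=tbl["at_risk"].to_numpy(dtype=float),
    )


def log_rank(
    times: np.ndarray,
    events: np.ndarray,
    groups: np.ndarray,
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size != 2:
        raise ValueError("log-rank requires exactly 2 non-empty cohorts")
    if events.sum() < 1:
        raise ValueError("log-rank requires at least one event")
    a = groups == uniq[0]
    res = logrank_test(times[a], times[~a], events[a], events[~a])
    return float(res.test_statistic), float(res.p_value)


def survival_by_cohort(df: pd.DataFrame, group_col: str = "response") -> dict:
    """KM curves per cohort plus the log-rank comparison, as plain data."""
    times, events = truncate_follow_up(df["time"].to_numpy(), df["event"].to_numpy())
    chi2, p = log_rank(times, events, df[group_col].to_numpy())
    curves = {}
    for g in np.unique(df[group_col]):
        sel = df[group_col].to_numpy() == g
        km = kaplan_meier(times[sel], events[sel])
        curves[str(g)] = {
            "times": km.times.tolist(),
            "survival": km.survival.tolist(),
            "at_risk": km.at_risk.tolist(),
        }
    return {"chi2": chi2, "p": p, "curves": curves}
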