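"""Recurrence-free survival: Kaplan-Meier curves and log-rank comparison.

Time is measured in months throughout.  Tied event and censoring times
follow the standard convention (events precede censorings).  The estimator
and the two-group test delegate to lifelines; Greenwood variance and
fixed-horizon lookups are assembled from the fitted event table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .errors import ValidationError


@dataclass
class KMCurve:
    """Right-continuous product-limit estimate with Greenwood variance."""

    times: np.ndarray       # distinct event times, ascending
    survival: np.ndarray    # S(t) just after each time
    variance: np.ndarray    # Greenwood variance of S(t)
    max_followup: float

    def at(self, horizon: float) -> tuple[float, bool]:
        """S(horizon) by step lookup; flag True when extrapolating beyond
        the last observed follow-up."""
        if horizon <= 0:
            raise ValidationError("horizon must be positive")
        extrapolated = horizon > self.max_followup
        idx = np.searchsorted(self.times, horizon, side="right") - 1
        s = 1.0 if idx < 0 else float(self.survival[idx])
        return s, extrapolated


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier estimate of recurrence-free survival."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValidationError("need at least one subject")
    if np.any(t <= 0):
        raise ValidationError("nonpositive follow-up time")
    kmf = KaplanMeierFitter().fit(t, e)
    table = kmf.event_table
    mask = table["observed"] > 0
    ev_times = table.index[mask].to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].reindex(table.index[mask]) \
        .to_numpy(dtype=float)
    # Greenwood: Var S(t) = S(t)^2 * sum_{t_i<=t} d_i / (n_i (n_i - d_i))
    d = table.loc[mask, "observed"].to_numpy(dtype=float)
    n = table.loc[mask, "at_risk"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where(n > d, d / (n * (n - d)), np.inf)
    var = surv**2 * np.cumsum(inc)
    return KMCurve(times=ev_times, survival=surv, variance=var,
                   max_followup=float(t.max()))


def survival_at(km: KMCurve, horizon: float) -> dict:
    s, extrapolated = km.at(horizon)
    return {"survival": s, "extrapolated": extrapolated}


def logrank_test(times, events, groups) -> dict:
    """Two-group log-rank test (chi-square, df=1).

    Returns statistic 0 / p = 1 when no events are observed.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(groups)
    labels = pd.unique(g)
    if len(labels) != 2:
        raise ValidationError(f"need exactly 2 groups, got {list(labels)}")
    a = g == labels[0]
    if a.all() or (~a).all():
        raise ValidationError("both groups must be nonempty")
    if not e.any():
        return {"chi_square": 0.0, "p": 1.0, "n_events": 0}
    res = _ll_logrank(t[a], t[~a], event_observed_A=e[a], event_observed_B=e[~a])
    return {"chi_square": float(res.test_statistic), "p": float(res.p_value),
            "n_events": int(e.sum())}
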