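"""Kaplan-Meier estimation, log-rank testing and ratio-cutoff stratification.

Overall survival is the time from surgery to death; censored records carry
the last follow-up time with event = False.  Estimation and testing are
delegated to lifelines and wrapped in the light containers the rest of the
pipeline uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = ["KmFit", "LogrankResult", "km_estimate", "logrank_test",
           "stratify_by_ratio", "stratify_by_median"]


@dataclass
class KmFit:
    """Product-limit estimate: step times, survival, numbers at risk, median.

    The median is the earliest time with survival <= 0.5 and is ``inf`` when
    the curve never reaches 0.5.
    """

    times: np.ndarray = field(repr=False)
    survival: np.ndarray = field(repr=False)
    n_at_risk: np.ndarray = field(repr=False)
    median_os: float = float("inf")

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogrankResult:
    statistic: float
    p_value: float


def km_estimate(os_days, events) -> KmFit:
    """Kaplan-Meier product-limit estimator.

    Ties of deaths and censorings at the same time follow the standard
    convention: deaths are processed first, censored specimens at that time
    still count as at risk.
    """
    t = np.asarray(os_days, dtype=float)
    e = np.asarray(events, dtype=bool)
    if len(t) == 0:
        raise ValueError("no survival records")
    if (t < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    sf = kmf.survival_function_["KM_estimate"]
    times = sf.index.to_numpy(dtype=float)
    surv = sf.to_numpy(dtype=float)
    at_risk = table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    median = float(kmf.median_survival_time_)
    return KmFit(times=times, survival=surv, n_at_risk=at_risk, median_os=median)


def logrank_test(os_days, events, groups) -> LogrankResult:
    """Two-group log-rank test.

    At each event time the observed deaths in group 1 are compared with the
    hypergeometric expectation; the summed discrepancy over its summed
    variance is chi-square with 1 df, read two-sided from the upper tail.
    """
    t = np.asarray(os_days, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(groups)
    labels = pd.unique(g)
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(labels)}")
    if e.sum() == 0:
        raise ValueError("no events: log-rank test undefined")
    m0, m1 = g == labels[0], g == labels[1]
    res = _ll_logrank(t[m0], t[m1], event_observed_A=e[m0], event_observed_B=e[m1])
    return LogrankResult(statistic=float(res.test_statistic), p_value=float(res.p_value))


def stratify_by_ratio(values, cutoff: float) -> pd.Series:
    """Label specimens 'above' when the marker exceeds the cutoff, else 'below'.

    Exact equality counts as 'below' (the rule is strictly "above" the cutoff).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    v = pd.Series(values)
    return pd.Series(np.where(v > cutoff, "above", "below"), index=v.index, name="group")


def stratify_by_median(values) -> pd.Series:
    """Median split: 'high' at or above the median, 'low' below (the same
    >=-at-median convention as the network discretization)."""
    v = pd.Series(values, dtype=float)
    med = float(np.median(v))
    return pd.Series(np.where(v >= med, "high", "low"), index=v.index, name="group")
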