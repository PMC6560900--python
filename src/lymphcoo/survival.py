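"""Overall-survival comparison of cell-of-origin groups.

Kaplan-Meier product-limit curves per predicted group and the two-sample
log-rank test (pooled hypergeometric variance at each distinct event time,
chi-square with 1 df, no continuity correction — the defaults of the
standard survival tools). p < 0.05 is the conventional significance level.

Estimation is delegated to lifelines behind this module's interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank

from .cohort import Cohort

ALPHA = 0.05


class SurvivalError(ValueError):
    pass


@dataclass
class KMCurve:
    """Product-limit estimate: distinct event times, survival after each,
    and the number at risk just before each."""

    times: np.ndarray        # distinct event (death) times
    survival: np.ndarray     # S(t) just after each event time
    at_risk: np.ndarray      # risk-set size just before each event time
    events: np.ndarray       # deaths at each event time
    censor_times: np.ndarray
    n: int

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        s = 1.0
        for time, surv in zip(self.times, self.survival):
            if time <= t:
                s = surv
            else:
                break
        return s


@dataclass
class LogRankResult:
    statistic: Optional[float]
    p_value: Optional[float]
    df: int = 1

    @property
    def significant(self) -> Optional[bool]:
        return None if self.p_value is None else self.p_value < ALPHA


def _check_arrays(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.shape != events.shape:
        raise SurvivalError("times and events must have equal length")
    if (times < 0).any():
        raise SurvivalError("negative survival time")
    if not np.isin(events, [0, 1]).all():
        raise SurvivalError("event flags must be 0 or 1")
    return times, events.astype(int)


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Censored subjects at exactly an event time remain in the risk set at
    that time (standard convention).
    """
    times, events = _check_arrays(times, events)
    if len(times) == 0:
        raise SurvivalError("no subjects")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    ts = event_rows.index.to_numpy(dtype=float)
    surv = np.array([float(kmf.survival_function_.loc[t].iloc[0]) for t in ts])
    return KMCurve(
        times=ts,
        survival=surv,
        at_risk=event_rows["at_risk"].to_numpy(dtype=int),
        events=event_rows["observed"].to_numpy(dtype=int),
        censor_times=np.sort(times[events == 0]),
        n=len(times),
    )


def logrank_test(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Two-sample log-rank test; undefined (with a warning) when neither
    group has any event."""
    times_a, events_a = _check_arrays(times_a, events_a)
    times_b, events_b = _check_arrays(times_b, events_b)
    if len(times_a) == 0 or len(times_b) == 0:
        raise SurvivalError("both groups must be non-empty")
    if events_a.sum() + events_b.sum() == 0:
        warnings.warn("log-rank undefined: no events in either group")
        return LogRankResult(statistic=None, p_value=None)
    res = _lifelines_logrank(times_a, times_b, event_observed_A=events_a,
                             event_observed_B=events_b)
    return LogRankResult(
        statistic=float(res.test_statistic), p_value=float(res.p_value)
    )


def km_by_group(cohort: Cohort, labels) -> dict[str, KMCurve]:
    """KM curve per predicted class label over a cohort with survival data."""
    times, events = cohort.survival_arrays()
    labels = np.asarray(list(labels))
    if len(labels) != len(times):
        raise SurvivalError("labels must match cohort size")
    return {
        lab: km_estimate(times[labels == lab], events[labels == lab])
        for lab in sorted(set(labels))
    }


def logrank_by_group(cohort: Cohort, labels) -> LogRankResult:
    """Log-rank test between the two predicted classes of a cohort."""
    times, events = cohort.survival_arrays()
    labels = np.asarray(list(labels))
    groups = sorted(set(labels))
    if len(groups) != 2:
        raise SurvivalError(f"need exactly two groups, got {groups}")
    a = labels == groups[0]
    return logrank_test(times[a], events[a], times[~a], events[~a])
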