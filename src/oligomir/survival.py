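"""Recurrence-free survival stratified by mean microRNA expression.

Patients are scored by the arithmetic mean of a small miRNA panel
(canonically miR-127-5p, miR-369-3p, miR-544a, miR-655-3p), split at the
cohort median (strictly-greater goes high; ties at the median go low), and
the two groups are compared by Kaplan-Meier curves and a log-rank test.
The product-limit and log-rank machinery is delegated to lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "LogRankResult",
    "median_split",
    "km_curve",
    "survival_at",
    "logrank",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient: follow-up time (months), event flag, per-miR expression."""

    patient_id: str
    time: float
    event: int
    expr: dict[str, float]

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"{self.patient_id}: negative time {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"{self.patient_id}: event must be 0 or 1")


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier step function with Greenwood confidence band.

    ``survival[i]`` is S(t) just after ``event_times[i]``; before the first
    event S = 1.  ``at_risk[i]`` counts subjects at risk at that event time
    (censoring at an event time leaves the subject in the risk set for it).
    """

    event_times: tuple[float, ...]
    survival: tuple[float, ...]
    at_risk: tuple[int, ...]
    censor_times: tuple[float, ...]
    ci_lower: tuple[float, ...] = ()
    ci_upper: tuple[float, ...] = ()


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    df: int
    p: float


def median_split(
    records: list[SurvivalRecord], mir_subset: list[str] | tuple[str, ...]
) -> dict[str, str]:
    """Assign each patient to 'high'/'low' by mean expression vs the median.

    The score is the arithmetic mean over ``mir_subset``; 'high' requires
    a score strictly greater than the joint cohort median, so ties at the
    median fall to 'low'.
    """
    if not mir_subset:
        raise ValueError("mir_subset must be non-empty")
    scores = {}
    for r in records:
        missing = [m for m in mir_subset if m not in r.expr]
        if missing:
            raise ValueError(
                f"patient {r.patient_id} lacks expression for {missing}"
            )
        scores[r.patient_id] = float(np.mean([r.expr[m] for m in mir_subset]))
    med = float(np.median(list(scores.values())))
    return {pid: ("high" if s > med else "low") for pid, s in scores.items()}


def km_curve(records: list[SurvivalRecord]) -> KMCurve:
    """Product-limit survival estimate for one group."""
    if not records:
        raise ValueError("need at least one record")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)

    tbl = kmf.event_table
    event_rows = tbl[tbl["observed"] > 0]
    event_times = tuple(float(t) for t in event_rows.index)
    sf = kmf.survival_function_["KM_estimate"]
    survival = tuple(float(sf.loc[t]) for t in event_rows.index)
    at_risk = tuple(int(v) for v in event_rows["at_risk"])
    ci = kmf.confidence_interval_
    lo = tuple(float(ci.loc[t].iloc[0]) for t in event_rows.index)
    hi = tuple(float(ci.loc[t].iloc[1]) for t in event_rows.index)
    censor_times = tuple(sorted(float(t) for t, e in zip(times, events) if e == 0))
    return KMCurve(
        event_times=event_times,
        survival=survival,
        at_risk=at_risk,
        censor_times=censor_times,
        ci_lower=lo,
        ci_upper=hi,
    )


def survival_at(curve: KMCurve, t: float) -> float:
    """Right-continuous step-function value S(t)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    s = 1.0
    for et, sv in zip(curve.event_times, curve.survival):
        if et <= t:
            s = sv
        else:
            break
    return s


def logrank(
    group_a: list[SurvivalRecord], group_b: list[SurvivalRecord]
) -> LogRankResult:
    """Two-group log-rank test (chi-squared, df 1, upper tail)."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    ev_total = sum(r.event for r in group_a) + sum(r.event for r in group_b)
    if ev_total == 0:
        raise ValueError("no events in either group; log-rank undefined")
    res = logrank_test(
        np.array([r.time for r in group_a]),
        np.array([r.time for r in group_b]),
        event_observed_A=np.array([r.event for r in group_a]),
        event_observed_B=np.array([r.event for r in group_b]),
    )
    return LogRankResult(
        statistic=float(res.test_statistic), df=1, p=float(res.p_value)
    )
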