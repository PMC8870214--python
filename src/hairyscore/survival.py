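"""Survival endpoints, product-limit estimation and the log-rank test.

Endpoints follow the clinical definitions: TTNT runs from the end of the
first treatment to the start of the second (event) or last follow-up
(censored); OS from diagnosis to death or last follow-up; PFS from
diagnosis to the earliest of progression, relapse or death, else last
follow-up.  Durations are reported in months of 30.4375 days.

The Kaplan-Meier estimator and the two-group log-rank test are implemented
directly (they are the analysis primitives here, not library calls): the
product-limit curve uses the events-before-censorings tie convention, and
the log-rank statistic sums observed-minus-hypergeometric-expected events
with the usual variance, referred to a chi-square with 1 df.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Sequence

import numpy as np
from scipy import stats

DAYS_PER_MONTH = 30.4375


@dataclass
class SurvivalInput:
    durations: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if self.durations.shape != self.events.shape:
            raise ValueError("durations and events must have equal length")
        if not np.isfinite(self.durations).all():
            raise ValueError("durations must be finite")
        if (self.durations < 0).any():
            raise ValueError("durations must be >= 0")
        if not np.isin(self.events, (0, 1)).all():
            raise ValueError("event flags must be 0 or 1")

    def __len__(self) -> int:
        return len(self.durations)


@dataclass
class SurvivalCurve:
    event_times: np.ndarray  # strictly increasing distinct event times
    survival: np.ndarray  # S(t) at each event time, nonincreasing from 1
    at_risk: np.ndarray  # risk-set size just before each event time

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    chi_square: float
    degrees_of_freedom: int
    p_value: float


# ---------------------------------------------------------------------------
# endpoint derivation


@dataclass
class ClinicalDates:
    """Raw date fields of one patient's follow-up."""

    diagnosis: date
    last_followup: date
    first_treatment_end: date | None = None
    second_treatment_start: date | None = None
    progression: date | None = None
    death: date | None = None


def _months(a: date, b: date) -> float:
    return (b - a).days / DAYS_PER_MONTH


def compute_endpoints(dates: ClinicalDates) -> dict[str, tuple[float, int]]:
    """Per-endpoint (duration in months, event flag) from date fields.

    TTNT is only defined for treated patients (``first_treatment_end``
    present).  Raises on a second treatment dated before the end of the
    first.
    """
    out: dict[str, tuple[float, int]] = {}
    if dates.first_treatment_end is not None:
        if dates.second_treatment_start is not None:
            if dates.second_treatment_start < dates.first_treatment_end:
                raise ValueError("second treatment before end of first treatment")
            out["ttnt"] = (
                _months(dates.first_treatment_end, dates.second_treatment_start),
                1,
            )
        else:
            out["ttnt"] = (_months(dates.first_treatment_end, dates.last_followup), 0)
    if dates.death is not None:
        out["os"] = (_months(dates.diagnosis, dates.death), 1)
    else:
        out["os"] = (_months(dates.diagnosis, dates.last_followup), 0)
    pfs_events = [d for d in (dates.progression, dates.death) if d is not None]
    if pfs_events:
        out["pfs"] = (_months(dates.diagnosis, min(pfs_events)), 1)
    else:
        out["pfs"] = (_months(dates.diagnosis, dates.last_followup), 0)
    return out


# ---------------------------------------------------------------------------
# product-limit estimator


def km_fit(data: SurvivalInput) -> SurvivalCurve:
    """Kaplan-Meier product-limit curve.

    At each distinct event time t with d events among n at risk the curve
    multiplies by (1 - d/n); subjects censored at t remain at risk for the
    events at t (events before censorings).
    """
    if len(data) == 0:
        raise ValueError("at least one subject required")
    order = np.lexsort((1 - data.events, data.durations))
    t = data.durations[order]
    e = data.events[order]
    n_at_risk = len(t)
    surv = 1.0
    times, survs, risks = [], [], []
    i = 0
    while i < len(t):
        j = i
        while j < len(t) and t[j] == t[i]:
            j += 1
        d = int(e[i:j].sum())
        if d > 0:
            times.append(float(t[i]))
            risks.append(n_at_risk)
            surv *= 1.0 - d / n_at_risk
            survs.append(surv)
        n_at_risk -= j - i
        i = j
    return SurvivalCurve(np.asarray(times), np.asarray(survs), np.asarray(risks))


def km_median(curve: SurvivalCurve) -> float | None:
    """Smallest event time with S(t) <= 0.5; None if never reached."""
    below = np.flatnonzero(curve.survival <= 0.5)
    return float(curve.event_times[below[0]]) if below.size else None


# ---------------------------------------------------------------------------
# log-rank test


def logrank(group_a: SurvivalInput, group_b: SurvivalInput) -> LogRankResult:
    """Two-group log-rank test.

    At each distinct event time the observed events in group A are compared
    with their hypergeometric expectation given the pooled risk sets; the
    summed (O-E)^2/V is referred to chi-square with 1 df.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be nonempty")
    durations = np.concatenate([group_a.durations, group_b.durations])
    events = np.concatenate([group_a.events, group_b.events])
    in_a = np.concatenate(
        [np.ones(len(group_a), dtype=bool), np.zeros(len(group_b), dtype=bool)]
    )
    if events.sum() == 0:
        raise ValueError("no events in either group")
    event_times = np.unique(durations[events == 1])
    o_minus_e = 0.0
    variance = 0.0
    for t in event_times:
        at_risk = durations >= t
        n = int(at_risk.sum())
        n_a = int((at_risk & in_a).sum())
        dying = at_risk & (durations == t) & (events == 1)
        d = int(dying.sum())
        d_a = int((dying & in_a).sum())
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            variance += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if variance == 0.0:
        return LogRankResult(0.0, 1, 1.0)
    chi2 = o_minus_e**2 / variance
    p = float(stats.chi2.sf(chi2, df=1))
    return LogRankResult(float(chi2), 1, max(p, np.finfo(float).tiny))


def compare_strata(
    durations: Sequence[float],
    events: Sequence[int],
    strata: Sequence[str],
) -> dict:
    """Fit KM per stratum and log-rank the first two strata.

    Returns curves and medians keyed by stratum plus the test result
    (None when fewer than two strata are present).
    """
    by: dict[str, list[int]] = {}
    for i, s in enumerate(strata):
        by.setdefault(s, []).append(i)
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=int)
    curves = {}
    medians = {}
    inputs = {}
    for s, idx in by.items():
        inputs[s] = SurvivalInput(durations[idx], events[idx])
        curves[s] = km_fit(inputs[s])
        medians[s] = km_median(curves[s])
    test = None
    names = sorted(by)
    if len(names) >= 2:
        test = logrank(inputs[names[0]], inputs[names[1]])
    return {"curves": curves, "medians": medians, "logrank": test}


def month_duration(days: float) -> float:
    return days / DAYS_PER_MONTH


__all__ = [
    "ClinicalDates",
    "DAYS_PER_MONTH",
    "LogRankResult",
    "SurvivalCurve",
    "SurvivalInput",
    "compare_strata",
    "compute_endpoints",
    "km_fit",
    "km_median",
    "logrank",
    "month_duration",
]
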