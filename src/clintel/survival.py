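"""Time from cohort index to first subsequent target event.

Durations are whole days from each member's index date to their first
event matching a target criterion; members with no such event inside the
analysis horizon are right-censored at min(horizon, coverage end - index).
The survival summary is the product-limit (Kaplan-Meier) estimator, with
the standard convention that events precede censorings at tied times; a
target event on the index day itself is a time-0 event (calendar-date
resolution cannot order same-day events, and e.g. a same-day post-operative
echocardiogram is clinically real).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort, Criterion
from .data_model import Dataset

DEFAULT_HORIZON_DAYS = 28


@dataclass(frozen=True)
class DurationRecord:
    patient_id: str
    time: float  # days since index, >= 0
    event: bool  # True = target observed, False = censored


@dataclass
class SurvivalCurve:
    """Product-limit step function: S(0)=1, non-increasing."""

    times: np.ndarray       # distinct event times, ascending
    survival: np.ndarray    # S just after each event time
    at_risk: np.ndarray     # n at risk at each event time
    events: np.ndarray      # events at each event time

    def evaluate(self, t) -> np.ndarray | float:
        """S(t) as a right-continuous step function."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        s = np.where(idx < 0, 1.0, np.concatenate([[1.0], self.survival])[idx + 1])
        return s if s.ndim else float(s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival,
             "at_risk": self.at_risk, "events": self.events}
        )


def time_to_first_event(
    dataset: Dataset,
    cohort: Cohort,
    target: Criterion,
    horizon: float = DEFAULT_HORIZON_DAYS,
) -> list[DurationRecord]:
    """Per-member days to first target event on/after index, censored at
    min(horizon, administrative coverage end)."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    from .cohort import _matching_events  # shared criterion matching

    matches = _matching_events(dataset, target)[["patient_id", "event_date"]]
    idx = cohort.members.set_index("patient_id")["index_date"]
    matches = matches[matches["patient_id"].isin(idx.index)]
    matches = matches[matches["event_date"] >= matches["patient_id"].map(idx)]
    first = matches.groupby("patient_id")["event_date"].min()

    cov_end = dataset.coverage_window[1] if dataset.coverage_window else None
    records = []
    for pid, index_date in idx.items():
        cens = float(horizon)
        if cov_end is not None:
            cens = min(cens, float((cov_end - index_date).days))
        cens = max(cens, 0.0)
        if pid in first.index:
            t = float((first[pid] - index_date).days)
            if t <= cens:
                records.append(DurationRecord(pid, t, True))
                continue
        records.append(DurationRecord(pid, cens, False))
    return records


def kaplan_meier(records: list[DurationRecord]) -> SurvivalCurve:
    """Product-limit estimate S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    if not records:
        raise ValueError("no duration records")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    if (times < 0).any():
        raise ValueError("negative duration")

    order = np.lexsort((~events, times))  # by time, events before censorings
    times, events = times[order], events[order]
    n = len(times)
    ev_times, at_risk, d_counts, surv = [], [], [], []
    s = 1.0
    i = 0
    while i < n:
        t = times[i]
        j = i
        d = c = 0
        while j < n and times[j] == t:
            if events[j]:
                d += 1
            else:
                c += 1
            j += 1
        if d > 0:
            risk = n - i
            s *= 1.0 - d / risk
            ev_times.append(t)
            at_risk.append(risk)
            d_counts.append(d)
            surv.append(s)
        i = j
    return SurvivalCurve(
        times=np.array(ev_times), survival=np.array(surv),
        at_risk=np.array(at_risk, dtype=int), events=np.array(d_counts, dtype=int),
    )


@dataclass
class TTESummary:
    median: float | None        # first t with S(t) <= 0.5; None if not reached
    median_reached: bool
    cumulative_incidence: dict[float, float]  # day -> 1 - S(day)
    n: int | None = None

    def to_dict(self) -> dict:
        return {
            "median_days": self.median,
            "median_reached": self.median_reached,
            "cumulative_incidence": {str(k): v for k, v in self.cumulative_incidence.items()},
            "n": self.n,
        }


def tte_summary(curve: SurvivalCurve, days_of_interest: list[float] = (3, 7, 14, 28)) -> TTESummary:
    """Median time-to-event and cumulative incidence at requested days."""
    below = np.nonzero(curve.survival <= 0.5)[0]
    if len(below):
        median, reached = float(curve.times[below[0]]), True
    else:
        median, reached = None, False
    ci = {float(d): float(1.0 - curve.evaluate(d)) for d in days_of_interest}
    n = int(curve.at_risk[0]) if len(curve.at_risk) else None
    return TTESummary(median=median, median_reached=reached, cumulative_incidence=ci, n=n)


__all__ = [
    "DurationRecord",
    "SurvivalCurve",
    "TTESummary",
    "time_to_first_event",
    "kaplan_meier",
    "tte_summary",
    "DEFAULT_HORIZON_DAYS",
]
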