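"""Built-in analytics library exposed through the module registry.

Calling convention for registered modules: ``impl(dataset, cohorts,
**params)`` where ``cohorts`` is the list of resolved Cohort objects named
by the pipeline step.  Every wrapper returns a ResultTable, so every
pipeline output is suppression-aware and renderable by the report layer.
"""

from __future__ import annotations

import pandas as pd

from .cohort import Cohort, Criterion
from .comparative import age_at_entry_comparison, relative_risk_scan, rr_scan_table
from .data_model import Dataset
from .descriptive import demographics_overview, frequency_analysis
from .registry import AnalyticsModuleSpec
from .survival import kaplan_meier, time_to_first_event, tte_summary
from .tables import DEFAULT_SUPPRESSION_THRESHOLD, ResultTable, suppress_small_counts


def _one(cohorts: list[Cohort], module: str) -> Cohort:
    if len(cohorts) != 1:
        raise ValueError(f"module {module!r} takes exactly one cohort, got {len(cohorts)}")
    return cohorts[0]


def run_demographics(dataset: Dataset, cohorts: list[Cohort], *,
                     threshold: int = DEFAULT_SUPPRESSION_THRESHOLD) -> ResultTable:
    return demographics_overview(dataset, cohorts, threshold=threshold)


def run_frequency(dataset: Dataset, cohorts: list[Cohort], *, domain: str = "medication",
                  group_by: str = "display", window: str = "after_index",
                  top_k: int = 15,
                  threshold: int = DEFAULT_SUPPRESSION_THRESHOLD) -> ResultTable:
    return frequency_analysis(dataset, _one(cohorts, "frequency"), domain=domain,
                              group_by=group_by, window=window, top_k=top_k,
                              threshold=threshold)


def run_rr_scan(dataset: Dataset, cohorts: list[Cohort], *,
                domain: str = "diagnosis", exclude_prefixes: list[str] | None = None,
                top_k: int = 10, alpha: float = 0.05,
                threshold: int = DEFAULT_SUPPRESSION_THRESHOLD) -> ResultTable:
    if len(cohorts) != 2:
        raise ValueError("relative_risk_scan needs exactly two cohorts (exposed, comparator)")
    estimates = relative_risk_scan(dataset, cohorts[0], cohorts[1], domain=domain,
                                   exclude_prefixes=exclude_prefixes, top_k=top_k,
                                   alpha=alpha)
    return rr_scan_table(estimates, threshold=threshold)


def run_age_comparison(dataset: Dataset, cohorts: list[Cohort], *,
                       threshold: int = DEFAULT_SUPPRESSION_THRESHOLD) -> ResultTable:
    cmp = age_at_entry_comparison(dataset, cohorts, threshold=threshold)
    table = cmp.summaries
    if cmp.kw is not None:
        table.footnotes.append(
            f"Kruskal-Wallis H = {cmp.kw.H:.4g}, df = {cmp.kw.df}, p = {cmp.kw.p:.3g}"
        )
    return table


def run_time_to_event(dataset: Dataset, cohorts: list[Cohort], *,
                      target: dict | Criterion, horizon: float = 28.0,
                      days_of_interest: list[float] = (3, 7, 14, 28),
                      threshold: int = DEFAULT_SUPPRESSION_THRESHOLD) -> ResultTable:
    if isinstance(target, dict):
        target = Criterion.model_validate(target)
    records = time_to_first_event(dataset, _one(cohorts, "time_to_event"), target,
                                  horizon=horizon)
    curve = kaplan_meier(records)
    summary = tte_summary(curve, days_of_interest=days_of_interest)
    rows = [{"measure": "n members", "count": len(records)},
            {"measure": "events observed", "count": sum(r.event for r in records)},
            {"measure": "median days to event",
             "statistic": summary.median if summary.median_reached else None}]
    for d, ci in summary.cumulative_incidence.items():
        rows.append({"measure": f"cumulative incidence by day {d:g} (%)",
                     "statistic": 100.0 * ci})
    table = ResultTable(
        title=f"Time to first {target.prefixes[0]} event (horizon {horizon:g} d)",
        data=pd.DataFrame(rows, columns=["measure", "count", "statistic"]),
        count_columns=("count",),
    )
    return suppress_small_counts(table, threshold)


BUILTIN_MODULES = [
    (AnalyticsModuleSpec(
        name="demographics", version="1.0", inputs=["Dataset", "Cohort"],
        doc="Per-cohort n, sex split, age at entry and follow-up span.",
        test_ref="tests.test_descriptive"), run_demographics),
    (AnalyticsModuleSpec(
        name="frequency", version="1.0", inputs=["Dataset", "Cohort"],
        doc="Patient-level event frequency by code/display/vocabulary.",
        test_ref="tests.test_descriptive"), run_frequency),
    (AnalyticsModuleSpec(
        name="relative_risk_scan", version="1.0", inputs=["Dataset", "Cohort", "Cohort"],
        doc="Comorbidity relative-risk scan between two disjoint cohorts.",
        test_ref="tests.test_comparative"), run_rr_scan),
    (AnalyticsModuleSpec(
        name="age_comparison", version="1.0", inputs=["Dataset", "Cohort"],
        doc="Age-at-entry distributions with Kruskal-Wallis rank test.",
        test_ref="tests.test_comparative"), run_age_comparison),
    (AnalyticsModuleSpec(
        name="time_to_event", version="1.0", inputs=["Dataset", "Cohort"],
        doc="Product-limit time from index to first target event.",
        test_ref="tests.test_time_to_event"), run_time_to_event),
]

__all__ = ["BUILTIN_MODULES"]
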