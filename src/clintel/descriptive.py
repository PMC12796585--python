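"""Descriptive analytics: demographics overview and event-frequency tables.

Frequencies are *patient-level*: each member contributes at most once per
group value regardless of how many matching events they have, matching the
"percentage of patients who ever receive the medication at least once"
reading used for medication-frequency summaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import Dataset
from .cohort import Cohort
from .tables import DEFAULT_SUPPRESSION_THRESHOLD, ResultTable, suppress_small_counts

DAYS_PER_YEAR = 365.25

FREQUENCY_GROUPINGS = ("code", "display", "generic_name", "therapeutic_class")


def age_at(date_of_birth: pd.Series, at: pd.Series) -> pd.Series:
    """Age in decimal years: calendar days / 365.25."""
    return (pd.to_datetime(at).to_numpy() - pd.to_datetime(date_of_birth).to_numpy()) / np.timedelta64(1, "D") / DAYS_PER_YEAR


def _member_frame(dataset: Dataset, cohort: Cohort) -> pd.DataFrame:
    pats = dataset.patients.set_index("patient_id")
    m = cohort.members.copy()
    m["date_of_birth"] = m["patient_id"].map(pats["date_of_birth"])
    m["sex"] = m["patient_id"].map(pats["sex"])
    m["age_at_entry"] = age_at(m["date_of_birth"], m["index_date"])
    return m


def demographics_overview(
    dataset: Dataset,
    cohorts: list[Cohort],
    threshold: int = DEFAULT_SUPPRESSION_THRESHOLD,
) -> ResultTable:
    """Per-cohort summary: n, sex split, age at entry, follow-up span.

    One row per (cohort, measure); sex rows carry counts and percentages
    and are subject to small-cell suppression.  An empty cohort yields
    empty-valued rows rather than an error.
    """
    if not cohorts:
        raise ValueError("at least one cohort required")
    rows = []
    for cohort in cohorts:
        m = _member_frame(dataset, cohort)
        n = len(m)
        rows.append({"cohort": cohort.name, "measure": "n", "count": n})
        for sex in ("female", "male", "other/unknown"):
            c = int((m["sex"] == sex).sum()) if n else 0
            if sex == "other/unknown" and c == 0:
                continue
            rows.append(
                {"cohort": cohort.name, "measure": f"sex: {sex}", "count": c,
                 "percent": 100.0 * c / n if n else np.nan}
            )
        if n:
            ages = m["age_at_entry"]
            q1, med, q3 = ages.quantile([0.25, 0.5, 0.75])
            rows.append({"cohort": cohort.name, "measure": "age at entry, median (years)",
                         "statistic": float(med)})
            rows.append({"cohort": cohort.name, "measure": "age at entry, IQR (years)",
                         "statistic": float(q3 - q1)})
            if dataset.coverage_window is not None:
                fu = (dataset.coverage_window[1] - m["index_date"]).dt.days / DAYS_PER_YEAR
                rows.append({"cohort": cohort.name,
                             "measure": "follow-up to coverage end, median (years)",
                             "statistic": float(fu.median())})
        else:
            rows.append({"cohort": cohort.name, "measure": "age at entry, median (years)",
                         "statistic": np.nan})
    data = pd.DataFrame(rows, columns=["cohort", "measure", "count", "percent", "statistic"])
    table = ResultTable(
        title="Demographics overview",
        data=data,
        count_columns=("count",),
        derived={"percent": "count"},
    )
    return suppress_small_counts(table, threshold)


def frequency_analysis(
    dataset: Dataset,
    cohort: Cohort,
    domain: str = "medication",
    group_by: str = "display",
    window: str = "after_index",
    top_k: int = 15,
    threshold: int = DEFAULT_SUPPRESSION_THRESHOLD,
) -> ResultTable:
    """Percentage of cohort members with >=1 matching event per group value.

    ``group_by``: ``code`` or ``display`` group raw event rows;
    ``generic_name`` / ``therapeutic_class`` restrict to that vocabulary
    first and group by display label.  ``window``: ``after_index`` keeps
    events on/after each member's index date (to the dataset coverage end);
    ``ever`` keeps all.  Output sorted by frequency descending (ties
    alphabetical) and truncated to ``top_k``.
    """
    if group_by not in FREQUENCY_GROUPINGS:
        raise ValueError(f"unknown group_by {group_by!r}; valid: {FREQUENCY_GROUPINGS}")
    if window not in ("after_index", "ever"):
        raise ValueError(f"unknown window {window!r}; valid: after_index, ever")
    if not len(cohort):
        raise ValueError("cohort has no members")

    ev = dataset.events_for(domain)
    ev = ev[ev["patient_id"].isin(set(cohort.patient_ids))].copy()
    if group_by in ("generic_name", "therapeutic_class"):
        ev = ev[ev["code_system"] == group_by]
        label_col = "display"
    else:
        label_col = group_by
    if window == "after_index":
        idx = cohort.members.set_index("patient_id")["index_date"]
        ev = ev[ev["event_date"] >= ev["patient_id"].map(idx)]

    n = len(cohort)
    counts = (
        ev.drop_duplicates(["patient_id", label_col])
        .groupby(label_col)["patient_id"]
        .count()
        .rename("n_patients")
        .reset_index()
        .rename(columns={label_col: "label"})
    )
    counts["percent"] = 100.0 * counts["n_patients"] / n
    counts = counts.sort_values(
        ["percent", "label"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    if top_k is not None:
        counts = counts.head(top_k).reset_index(drop=True)
    table = ResultTable(
        title=f"Frequency of {domain} by {group_by} ({window}), n={n}",
        data=counts,
        count_columns=("n_patients",),
        derived={"percent": "n_patients"},
        footnotes=["Patient-level frequencies: each member counted once per item."],
    )
    return suppress_small_counts(table, threshold)


__all__ = [
    "age_at",
    "demographics_overview",
    "frequency_analysis",
    "FREQUENCY_GROUPINGS",
]
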