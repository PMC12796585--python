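"""Two-cohort comparison: relative-risk scans, rank tests, age distributions.

Relative risk uses the Katz log-normal interval,

    CI = exp( ln RR  +/-  z_{1-a/2} * sqrt(1/a - 1/n1 + 1/b - 1/n2) ),

with the conventional 0.5/1 continuity correction (add 0.5 to both event
counts and 1 to both denominators, flagged) when either event count is
zero.  The scan is a descriptive screen, not an adjusted analysis: no
multiple-testing correction is applied and the output notes as much.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, code_matches
from .data_model import Dataset
from .descriptive import _member_frame
from .tables import DEFAULT_SUPPRESSION_THRESHOLD, ResultTable, suppress_small_counts


@dataclass(frozen=True)
class RREstimate:
    """Relative risk from a 2x2 table with its Katz confidence interval."""

    code: str
    a: int            # exposed members with the event
    n1: int           # exposed total
    b: int            # comparator members with the event
    n2: int           # comparator total
    rr: float
    ci_low: float
    ci_high: float
    alpha: float
    corrected: bool = False
    display: str = ""

    def to_dict(self) -> dict:
        return {
            "code": self.code, "display": self.display,
            "a": self.a, "n1": self.n1, "b": self.b, "n2": self.n2,
            "rr": self.rr, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "alpha": self.alpha, "corrected": self.corrected,
        }


@dataclass(frozen=True)
class KWResult:
    """Kruskal-Wallis rank-sum statistic with its chi-square p-value."""

    H: float
    df: int
    p: float


def relative_risk(a: int, n1: int, b: int, n2: int, alpha: float = 0.05,
                  code: str = "", display: str = "") -> RREstimate:
    """Point estimate (a/n1)/(b/n2) with the Katz log interval."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("cohort sizes n1, n2 must be positive")
    if not (0 <= a <= n1 and 0 <= b <= n2):
        raise ValueError("event counts must satisfy 0 <= a <= n1, 0 <= b <= n2")
    corrected = a == 0 or b == 0
    if corrected:
        ae, be, n1e, n2e = a + 0.5, b + 0.5, n1 + 1.0, n2 + 1.0
    else:
        ae, be, n1e, n2e = float(a), float(b), float(n1), float(n2)
    rr = (ae / n1e) / (be / n2e)
    se = np.sqrt(1.0 / ae - 1.0 / n1e + 1.0 / be - 1.0 / n2e)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    ci_low = float(rr * np.exp(-z * se))
    ci_high = float(rr * np.exp(z * se))
    return RREstimate(code=code, a=a, n1=n1, b=b, n2=n2, rr=float(rr),
                      ci_low=ci_low, ci_high=ci_high, alpha=alpha,
                      corrected=corrected, display=display)


def relative_risk_scan(
    dataset: Dataset,
    exposed: Cohort,
    comparator: Cohort,
    domain: str = "diagnosis",
    exclude_prefixes: list[str] | None = None,
    top_k: int = 10,
    alpha: float = 0.05,
    code_level: int = 3,
) -> list[RREstimate]:
    """One RR per observed code category, sorted by RR descending.

    Codes are truncated to ``code_level`` characters (3 = ICD-10 category);
    counting is patient-level.  The cohort-defining code itself should be
    passed in ``exclude_prefixes`` so it does not trivially top the list.
    Ties in RR are broken by narrower CI, then alphabetically.
    """
    overlap = set(exposed.patient_ids) & set(comparator.patient_ids)
    if overlap:
        raise ValueError(
            f"cohorts overlap on {len(overlap)} patient(s); an RR scan needs disjoint arms"
        )
    exclude_prefixes = [p.upper().replace(".", "") for p in (exclude_prefixes or [])]
    ev = dataset.events_for(domain).copy()
    ev["category"] = ev["code"].str[:code_level]
    display_of = ev.drop_duplicates("category").set_index("category")["display"].to_dict()

    def carriers(cohort: Cohort) -> pd.Series:
        sub = ev[ev["patient_id"].isin(set(cohort.patient_ids))]
        return sub.drop_duplicates(["patient_id", "category"]).groupby("category").size()

    ca, cb = carriers(exposed), carriers(comparator)
    categories = sorted(set(ca.index) | set(cb.index))
    out = []
    for cat in categories:
        if any(code_matches(cat, p) or code_matches(p, cat) for p in exclude_prefixes):
            continue
        est = relative_risk(
            int(ca.get(cat, 0)), len(exposed), int(cb.get(cat, 0)), len(comparator),
            alpha=alpha, code=cat, display=str(display_of.get(cat, cat)),
        )
        out.append(est)
    out.sort(key=lambda e: (-e.rr, e.ci_high - e.ci_low, e.code))
    return out[:top_k] if top_k is not None else out


def rr_scan_table(estimates: list[RREstimate],
                  threshold: int = DEFAULT_SUPPRESSION_THRESHOLD) -> ResultTable:
    """Render a scan as a suppression-aware table for reports."""
    data = pd.DataFrame([e.to_dict() for e in estimates])
    table = ResultTable(
        title="Relative-risk scan (exposed vs comparator)",
        data=data,
        count_columns=("a", "b"),
        derived={"rr": "a", "ci_low": "a", "ci_high": "a"},
        footnotes=[
            "Unadjusted descriptive relative risks; no multiple-testing correction.",
            "Associations only - not evidence of causation.",
        ],
    )
    return suppress_small_counts(table, threshold)


def kruskal_wallis(groups: list) -> KWResult:
    """Rank-sum H with mid-rank tie correction and chi-square p-value.

    H = [12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2] / [1 - sum(t^3-t)/(N^3-N)]
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group must contain at least one observation")
    pooled = np.concatenate(arrays)
    N = len(pooled)
    ranks = stats.rankdata(pooled)  # mid-ranks for ties
    H = 0.0
    start = 0
    for a in arrays:
        r = ranks[start:start + len(a)]
        start += len(a)
        H += len(a) * (r.mean() - (N + 1) / 2.0) ** 2
    H *= 12.0 / (N * (N + 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = 1.0 - np.sum(counts**3 - counts) / (N**3 - N)
    if tie_term <= 0:  # all values identical
        return KWResult(H=0.0, df=len(groups) - 1, p=1.0)
    H /= tie_term
    df = len(groups) - 1
    p = float(stats.chi2.sf(H, df)) if H > 0 else 1.0
    return KWResult(H=float(H), df=df, p=p)


@dataclass
class AgeComparison:
    """Per-cohort age-at-entry summaries, shared-grid densities, rank test."""

    summaries: ResultTable
    density_grid: np.ndarray
    densities: dict[str, np.ndarray]
    kw: KWResult | None  # None when fewer than two non-empty cohorts
    dropped: dict[str, int]  # members without date_of_birth, per cohort


def age_at_entry_comparison(
    dataset: Dataset,
    cohorts: list[Cohort],
    bandwidth: str | float = "silverman",
    grid_size: int = 512,
    threshold: int = DEFAULT_SUPPRESSION_THRESHOLD,
) -> AgeComparison:
    """Compare the age at cohort entry across cohorts.

    Ages in decimal years at each member's index date; Gaussian KDE with a
    normal-reference (Silverman) bandwidth on a shared grid; Kruskal-Wallis
    across cohorts.  Members with no recorded date of birth are dropped and
    counted in ``dropped``.
    """
    ages: dict[str, np.ndarray] = {}
    dropped: dict[str, int] = {}
    for cohort in cohorts:
        m = _member_frame(dataset, cohort)
        missing = m["date_of_birth"].isna()
        dropped[cohort.name] = int(missing.sum())
        ages[cohort.name] = m.loc[~missing, "age_at_entry"].to_numpy()

    rows = []
    for name, a in ages.items():
        q1, med, q3 = (np.percentile(a, [25, 50, 75]) if len(a) else (np.nan,) * 3)
        rows.append({"cohort": name, "n": len(a), "median_age": med,
                     "iqr": q3 - q1, "dropped_missing_dob": dropped[name]})
    summaries = suppress_small_counts(
        ResultTable(
            title="Age at cohort entry",
            data=pd.DataFrame(rows),
            count_columns=("n",),
            derived={"median_age": "n", "iqr": "n"},
        ),
        threshold,
    )

    pooled = np.concatenate([a for a in ages.values() if len(a)]) if ages else np.array([])
    lo = float(pooled.min()) if len(pooled) else 0.0
    hi = float(pooled.max()) if len(pooled) else 1.0
    pad = 0.05 * (hi - lo) if hi > lo else 1.0
    grid = np.linspace(max(0.0, lo - pad), hi + pad, grid_size)
    densities = {}
    for name, a in ages.items():
        if len(a) > 1 and np.ptp(a) > 0:
            kde = stats.gaussian_kde(a, bw_method=bandwidth)
            densities[name] = kde(grid)
        else:
            # degenerate: all mass at one point
            d = np.zeros_like(grid)
            if len(a):
                d[np.argmin(np.abs(grid - a[0]))] = 1.0
            densities[name] = d
    nonempty = [a for a in ages.values() if len(a)]
    kw = kruskal_wallis(nonempty) if len(nonempty) >= 2 else None
    return AgeComparison(summaries=summaries, density_grid=grid,
                         densities=densities, kw=kw, dropped=dropped)


__all__ = [
    "RREstimate",
    "KWResult",
    "relative_risk",
    "relative_risk_scan",
    "rr_scan_table",
    "kruskal_wallis",
    "AgeComparison",
    "age_at_entry_comparison",
]
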