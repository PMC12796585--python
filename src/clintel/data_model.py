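"""Event-level clinical common data model.

A dataset is a patients table plus one event table per clinical domain
(diagnoses, procedures, medications, observations), stored on disk as one
Parquet file per table with a JSON metadata sidecar carrying the coverage
window.  All analytics in this package are written against this layout, so
they are reusable across any cohort drawn from any conforming dataset.

Codes are normalized to uppercase with dots stripped ("M01.2" -> "M012");
hierarchical vocabularies such as ICD-10 and OPCS-4 are prefix-structured,
so chapter- and category-level filters reduce to prefix matches on the
normalized form.  Dates are held at calendar-date resolution.
"""

from __future__ import annotations

import hashlib
import hmac
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

DOMAINS: tuple[str, ...] = ("diagnosis", "procedure", "medication", "observation")

#: on-disk table name per domain
TABLE_NAMES: dict[str, str] = {
    "diagnosis": "diagnoses",
    "procedure": "procedures",
    "medication": "medications",
    "observation": "observations",
}

EVENT_COLUMNS = ["patient_id", "code_system", "code", "display", "event_date"]
OBSERVATION_COLUMNS = EVENT_COLUMNS + ["value", "unit"]
PATIENT_COLUMNS = ["patient_id", "date_of_birth", "sex"]

SEXES = ("female", "male", "other/unknown")

CODE_SYSTEMS = (
    "ICD-10",
    "OPCS-4",
    "generic_name",
    "therapeutic_class",
    "observation_concept",
)


class DatasetLoadError(Exception):
    """A table required by the on-disk layout is missing or unreadable."""


class DatasetValidationError(Exception):
    """The dataset violates a structural invariant (e.g. orphan patient ids)."""

    def __init__(self, issues: list[str]):
        self.issues = issues
        super().__init__("; ".join(issues))


class PseudonymizationError(Exception):
    """Disclosure-control violation while pseudonymizing (empty salt, collision)."""


def normalize_code(code: str) -> str:
    """Uppercase and strip dots so hierarchy filters are plain prefix matches."""
    return str(code).replace(".", "").strip().upper()


def _empty_events(domain: str) -> pd.DataFrame:
    cols = OBSERVATION_COLUMNS if domain == "observation" else EVENT_COLUMNS
    df = pd.DataFrame({c: pd.Series(dtype="object") for c in cols})
    df["event_date"] = pd.Series(dtype="datetime64[ns]")
    if domain == "observation":
        df["value"] = pd.Series(dtype="float64")
    return df


@dataclass
class Dataset:
    """Patients plus domain-partitioned clinical events with a coverage window.

    ``patients``: DataFrame(patient_id, date_of_birth, sex).
    ``events``: mapping domain -> DataFrame(patient_id, code_system, code,
    display, event_date[, value, unit]).  ``coverage_window`` is the
    administrative observation period; time-to-event censoring uses its end.
    """

    patients: pd.DataFrame
    events: dict[str, pd.DataFrame] = field(default_factory=dict)
    coverage_window: tuple[pd.Timestamp, pd.Timestamp] | None = None

    def __post_init__(self) -> None:
        for d in DOMAINS:
            if d not in self.events:
                self.events[d] = _empty_events(d)

    def events_for(self, domain: str) -> pd.DataFrame:
        if domain not in DOMAINS:
            raise KeyError(f"unknown event domain {domain!r}; expected one of {DOMAINS}")
        return self.events[domain]

    @property
    def patient_ids(self) -> pd.Index:
        return pd.Index(self.patients["patient_id"])

    def n_patients(self) -> int:
        return len(self.patients)

    def equals(self, other: "Dataset") -> bool:
        if not _frames_equal(_canon_patients(self.patients), _canon_patients(other.patients)):
            return False
        for d in DOMAINS:
            if not _frames_equal(_canon_events(self.events[d], d), _canon_events(other.events[d], d)):
                return False
        return self.coverage_window == other.coverage_window

    def copy(self) -> "Dataset":
        return Dataset(
            patients=self.patients.copy(),
            events={d: df.copy() for d, df in self.events.items()},
            coverage_window=self.coverage_window,
        )

    def content_hash(self) -> str:
        """Stable hash of the sorted table contents, for provenance records."""
        h = hashlib.sha256()
        h.update(_canon_patients(self.patients).to_csv(index=False).encode())
        for d in DOMAINS:
            h.update(_canon_events(self.events[d], d).to_csv(index=False).encode())
        if self.coverage_window is not None:
            h.update(repr(tuple(str(t.date()) for t in self.coverage_window)).encode())
        return h.hexdigest()[:16]


def _canon_patients(df: pd.DataFrame) -> pd.DataFrame:
    out = df.loc[:, PATIENT_COLUMNS].copy()
    out["date_of_birth"] = pd.to_datetime(out["date_of_birth"]).dt.normalize()
    return out.sort_values("patient_id", kind="mergesort").reset_index(drop=True)

def _canon_events(df: pd.DataFrame, domain: str) -> pd.DataFrame:
    cols = OBSERVATION_COLUMNS if domain == "observation" else EVENT_COLUMNS
    out = df.loc[:, cols].copy()
    out["event_date"] = pd.to_datetime(out["event_date"]).dt.normalize()
    return out.sort_values(
        ["patient_id", "event_date", "code"], kind="mergesort"
    ).reset_index(drop=True)

def _frames_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    if list(a.columns) != list(b.columns) or len(a) != len(b):
        return False
    if len(a) == 0:
        return True
    try:
        pd.testing.assert_frame_equal(a, b, check_dtype=False)
        return True
    except AssertionError:
        return False


# ---------------------------------------------------------------------------
# on-disk layout

def write_dataset(dataset: Dataset, path: str | Path) -> Path:
    """Write one Parquet file per table plus ``metadata.json``.

    Rows are sorted (patient_id, event_date, code) so repeated writes of the
    same dataset produce identical logical tables.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    _canon_patients(dataset.patients).to_parquet(path / "patients.parquet", index=False)
    for domain, table in TABLE_NAMES.items():
        _canon_events(dataset.events[domain], domain).to_parquet(
            path / f"{table}.parquet", index=False
        )
    meta: dict = {"layout_version": 1}
    if dataset.coverage_window is not None:
        start, end = dataset.coverage_window
        meta["coverage_window"] = [str(start.date()), str(end.date())]
    (path / "metadata.json").write_text(json.dumps(meta, indent=2))
    return path


def read_dataset(path: str | Path) -> Dataset:
    """Load a dataset directory, normalize codes/dates and check integrity.

    Raises :class:`DatasetLoadError` naming any missing table and
    :class:`DatasetValidationError` listing orphan patient ids.
    """
    path = Path(path)
    missing = [
        t
        for t in ["patients", *TABLE_NAMES.values()]
        if not (path / f"{t}.parquet").is_file()
    ]
    if missing:
        raise DatasetLoadError(
            f"dataset at {path} is missing table(s): {', '.join(missing)}"
        )
    patients = pd.read_parquet(path / "patients.parquet")
    patients["date_of_birth"] = pd.to_datetime(patients["date_of_birth"]).dt.normalize()
    events: dict[str, pd.DataFrame] = {}
    for domain, table in TABLE_NAMES.items():
        df = pd.read_parquet(path / f"{table}.parquet")
        df["event_date"] = pd.to_datetime(df["event_date"]).dt.normalize()
        df["code"] = df["code"].map(normalize_code)
        events[domain] = df
    coverage = None
    meta_path = path / "metadata.json"
    if meta_path.is_file():
        meta = json.loads(meta_path.read_text())
        if "coverage_window" in meta:
            s, e = meta["coverage_window"]
            coverage = (pd.Timestamp(s), pd.Timestamp(e))
    ds = Dataset(patients=patients, events=events, coverage_window=coverage)
    orphans = _orphan_ids(ds)
    if orphans:
        raise DatasetValidationError(
            [f"event references unknown patient_id {pid!r}" for pid in orphans]
        )
    return ds


def _orphan_ids(dataset: Dataset) -> list[str]:
    known = set(dataset.patients["patient_id"])
    orphans: set[str] = set()
    for d in DOMAINS:
        ev = dataset.events[d]
        if len(ev):
            orphans.update(set(ev["patient_id"]) - known)
    return sorted(orphans)


# ---------------------------------------------------------------------------
# pseudonymization

def pseudonymize(dataset: Dataset, salt: str) -> tuple[Dataset, dict[str, str]]:
    """Replace every patient id with a keyed-hash study pseudonym.

    The pseudonym is HMAC-SHA256 of the raw id under ``salt``, truncated to
    16 hex characters.  The same (id, salt) pair always yields the same
    pseudonym, so re-runs are stable; a different salt yields an unlinkable
    id space.  Collisions are checked and rejected.
    """
    if not salt:
        raise PseudonymizationError("empty salt refused: pseudonyms would be unkeyed")
    raw_ids = list(dict.fromkeys(dataset.patients["patient_id"]))
    mapping = {
        rid: hmac.new(salt.encode(), str(rid).encode(), hashlib.sha256).hexdigest()[:16]
        for rid in raw_ids
    }
    if len(set(mapping.values())) != len(mapping):
        raise PseudonymizationError("pseudonym collision detected; choose another salt")
    out = dataset.copy()
    out.patients["patient_id"] = out.patients["patient_id"].map(mapping)
    for d in DOMAINS:
        if len(out.events[d]):
            out.events[d]["patient_id"] = out.events[d]["patient_id"].map(mapping)
    return out, mapping


# ---------------------------------------------------------------------------
# validation report

@dataclass
class ValidationReport:
    row_counts: dict[str, int]
    issues: list[str]

    @property
    def ok(self) -> bool:
        return not self.issues

    def to_dict(self) -> dict:
        return {"row_counts": self.row_counts, "issues": self.issues, "ok": self.ok}


def validate_dataset(dataset: Dataset) -> ValidationReport:
    """Profile the dataset and list every invariant violation (never raises).

    Checks: unique patient ids, referential integrity, event dates not before
    birth and inside the coverage window, non-empty codes, observation values
    present exactly on the observation domain.
    """
    issues: list[str] = []
    counts = {"patients": len(dataset.patients)}
    pats = dataset.patients
    dup = pats["patient_id"][pats["patient_id"].duplicated()]
    for pid in dup.unique():
        issues.append(f"duplicate patient_id {pid!r}")
    if pats["date_of_birth"].isna().any():
        issues.append("missing date_of_birth")
    bad_sex = set(pats["sex"].dropna()) - set(SEXES)
    if bad_sex:
        issues.append(f"unknown sex categories: {sorted(bad_sex)}")

    dob = pats.set_index("patient_id")["date_of_birth"]
    for pid in _orphan_ids(dataset):
        issues.append(f"event references unknown patient_id {pid!r}")
    for d in DOMAINS:
        ev = dataset.events[d]
        counts[TABLE_NAMES[d]] = len(ev)
        if not len(ev):
            continue
        if (ev["code"].astype(str).str.len() == 0).any():
            issues.append(f"{d}: empty code string")
        known = ev["patient_id"].isin(dob.index)
        ev_dob = ev.loc[known, "patient_id"].map(dob)
        before_birth = ev.loc[known, "event_date"] < ev_dob
        for pid in ev.loc[known].loc[before_birth.to_numpy(), "patient_id"].unique():
            issues.append(f"{d}: event before date_of_birth for patient {pid!r}")
        if dataset.coverage_window is not None:
            start, end = dataset.coverage_window
            outside = (ev["event_date"] < start) | (ev["event_date"] > end)
            if outside.any():
                issues.append(f"{d}: {int(outside.sum())} event(s) outside coverage window")
        if d == "observation":
            if ev["value"].isna().any():
                issues.append("observation: missing value")
        elif "value" in ev.columns and ev["value"].notna().any():
            issues.append(f"{d}: value present on non-observation event")
    return ValidationReport(row_counts=counts, issues=issues)


__all__ = [
    "DOMAINS",
    "TABLE_NAMES",
    "SEXES",
    "CODE_SYSTEMS",
    "Dataset",
    "DatasetLoadError",
    "DatasetValidationError",
    "PseudonymizationError",
    "ValidationReport",
    "normalize_code",
    "read_dataset",
    "write_dataset",
    "pseudonymize",
    "validate_dataset",
]
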