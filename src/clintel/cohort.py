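"""Computable-phenotype cohort definitions and their evaluation.

A cohort definition is a declarative list of criteria over coded events.
Include criteria are intersected (a member must satisfy all of them); a
criterion may list alternative code prefixes, which gives OR within one
criterion.  The criteria flagged ``role="index_candidate"`` define cohort
entry: a member's index date is the date of their *first* event matching
any of them.  Temporal clauses (``ever``, ``on_or_after_index``,
``before_index``) are evaluated relative to that index date; because events
carry calendar dates only, same-day ties count as "on or after" — the
conservative reading when an exclusion targets subsequent events.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, Field, ValidationError, field_validator

from .data_model import DOMAINS, Dataset, normalize_code


class CohortDefinitionError(Exception):
    """The definition document is malformed or semantically invalid."""


class Criterion(BaseModel):
    """One include/exclude clause over a code prefix (or list of prefixes)."""

    domain: Literal["diagnosis", "procedure", "medication", "observation"]
    code_system: Optional[str] = None  # None matches any vocabulary
    code_prefix: str | list[str]
    mode: Literal["include", "exclude"] = "include"
    temporal: Literal["ever", "on_or_after_index", "before_index"] = "ever"
    role: Literal["plain", "index_candidate"] = "plain"

    @field_validator("code_prefix")
    @classmethod
    def _norm(cls, v):
        if isinstance(v, str):
            v = [v]
        v = [normalize_code(p) for p in v]
        if any(not p for p in v):
            raise ValueError("code_prefix must be non-empty")
        return v

    @property
    def prefixes(self) -> list[str]:
        return self.code_prefix if isinstance(self.code_prefix, list) else [self.code_prefix]


class CohortDefinition(BaseModel):
    name: str
    criteria: list[Criterion] = Field(min_length=1)

    @property
    def index_criteria(self) -> list[Criterion]:
        return [c for c in self.criteria if c.mode == "include" and c.role == "index_candidate"]

    @property
    def includes(self) -> list[Criterion]:
        return [c for c in self.criteria if c.mode == "include"]

    @property
    def excludes(self) -> list[Criterion]:
        return [c for c in self.criteria if c.mode == "exclude"]


@dataclass(frozen=True)
class Cohort:
    """Resolved member set: unique patient ids with their entry dates."""

    name: str
    members: pd.DataFrame  # columns: patient_id, index_date (sorted by patient_id)

    def __len__(self) -> int:
        return len(self.members)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.members["patient_id"])

    def index_date_of(self, patient_id: str) -> pd.Timestamp:
        row = self.members.loc[self.members["patient_id"] == patient_id]
        if not len(row):
            raise KeyError(f"{patient_id!r} is not a cohort member")
        return row["index_date"].iloc[0]

    def to_frame(self) -> pd.DataFrame:
        return self.members.copy()

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        out = self.members.copy()
        out["index_date"] = out["index_date"].dt.strftime("%Y-%m-%d")
        if path.suffix == ".parquet":
            self.members.to_parquet(path, index=False)
        else:
            out.to_csv(path, index=False)
        return path

    @classmethod
    def read(cls, path: str | Path, name: str | None = None) -> "Cohort":
        path = Path(path)
        df = pd.read_parquet(path) if path.suffix == ".parquet" else pd.read_csv(path)
        df["index_date"] = pd.to_datetime(df["index_date"])
        return cls(name=name or path.stem, members=df.reset_index(drop=True))


def parse_cohort_definition(document: str | dict) -> CohortDefinition:
    """Parse and validate a JSON cohort-definition document.

    Codes are normalized; a definition without at least one include
    criterion in the index_candidate role is rejected (no entry event means
    no index date, so membership would be ill-defined).
    """
    if isinstance(document, str):
        try:
            document = json.loads(document)
        except json.JSONDecodeError as e:
            raise CohortDefinitionError(f"invalid JSON: {e}") from e
    try:
        definition = CohortDefinition.model_validate(document)
    except ValidationError as e:
        first = e.errors()[0]
        pointer = "/" + "/".join(str(p) for p in first["loc"])
        raise CohortDefinitionError(f"at {pointer}: {first['msg']}") from e
    if not definition.index_criteria:
        raise CohortDefinitionError(
            "definition needs >=1 include criterion with role='index_candidate'"
        )
    return definition


def code_matches(code: str, prefix: str) -> bool:
    """Prefix match on normalized codes; hierarchy filters reduce to this."""
    return code.startswith(prefix)


def _criterion_mask(events: pd.DataFrame, criterion: Criterion) -> pd.Series:
    mask = pd.Series(False, index=events.index)
    for p in criterion.prefixes:
        mask |= events["code"].str.startswith(p)
    if criterion.code_system is not None:
        mask &= events["code_system"] == criterion.code_system
    return mask


def _matching_events(dataset: Dataset, criterion: Criterion) -> pd.DataFrame:
    if criterion.domain not in DOMAINS:
        raise CohortDefinitionError(f"unknown event domain {criterion.domain!r}")
    ev = dataset.events_for(criterion.domain)
    if not len(ev):
        return ev
    return ev.loc[_criterion_mask(ev, criterion)]


def evaluate_cohort(dataset: Dataset, definition: CohortDefinition) -> Cohort:
    """Resolve a definition to members and index dates.

    A patient is a member iff (i) every include criterion has >=1 matching
    event inside its temporal clause, (ii) their index date is the earliest
    event matching any index_candidate criterion, and (iii) no exclude
    criterion has a matching event inside its temporal clause, where
    on_or_after_index includes the index date itself.
    """
    # earliest index-candidate match per patient
    idx_frames = [
        _matching_events(dataset, c)[["patient_id", "event_date"]]
        for c in definition.index_criteria
    ]
    idx_events = pd.concat(idx_frames, ignore_index=True)
    if not len(idx_events):
        return Cohort(definition.name, pd.DataFrame(columns=["patient_id", "index_date"]))
    index_dates = (
        idx_events.groupby("patient_id")["event_date"].min().rename("index_date")
    )

    member = pd.Series(True, index=index_dates.index)
    for criterion in definition.criteria:
        matches = _matching_events(dataset, criterion)[["patient_id", "event_date"]]
        matches = matches[matches["patient_id"].isin(index_dates.index)]
        idx = matches["patient_id"].map(index_dates)
        if criterion.temporal == "on_or_after_index":
            matches = matches[matches["event_date"] >= idx]
        elif criterion.temporal == "before_index":
            matches = matches[matches["event_date"] < idx]
        hit = member.index.isin(set(matches["patient_id"]))
        if criterion.mode == "include":
            member &= hit
        else:
            member &= ~hit

    kept = index_dates[member[member].index].reset_index()
    kept.columns = ["patient_id", "index_date"]
    kept = kept.sort_values("patient_id", kind="mergesort").reset_index(drop=True)
    return Cohort(definition.name, kept)


# ---------------------------------------------------------------------------
# the four shipped study definitions

EXAMPLE_DEFINITIONS: dict[str, dict] = {
    # successful kidney transplants: entered at first M01, no subsequent X40
    "transplant_success": {
        "name": "Transplant Success",
        "criteria": [
            {"domain": "procedure", "code_system": "OPCS-4", "code_prefix": "M01",
             "mode": "include", "role": "index_candidate"},
            {"domain": "procedure", "code_system": "OPCS-4", "code_prefix": "X40",
             "mode": "exclude", "temporal": "on_or_after_index"},
        ],
    },
    # haemodialysis with chronic kidney disease, never transplanted
    "dialysis_patients": {
        "name": "Dialysis Patients",
        "criteria": [
            {"domain": "procedure", "code_system": "OPCS-4", "code_prefix": "X40",
             "mode": "include", "role": "index_candidate"},
            {"domain": "diagnosis", "code_system": "ICD-10", "code_prefix": "N18",
             "mode": "include"},
            {"domain": "procedure", "code_system": "OPCS-4", "code_prefix": "M01",
             "mode": "exclude"},
        ],
    },
    # cardiac surgery (heart-chapter prefix K) with pleural effusion
    "pleural_effusion": {
        "name": "Pleural Effusion",
        "criteria": [
            {"domain": "procedure", "code_system": "OPCS-4", "code_prefix": "K",
             "mode": "include", "role": "index_candidate"},
            {"domain": "diagnosis", "code_system": "ICD-10", "code_prefix": "J90",
             "mode": "include"},
        ],
    },
    # cardiac surgery without pleural effusion, ever
    "effusion_others": {
        "name": "Others",
        "criteria": [
            {"domain": "procedure", "code_system": "OPCS-4", "code_prefix": "K",
             "mode": "include", "role": "index_candidate"},
            {"domain": "diagnosis", "code_system": "ICD-10", "code_prefix": "J90",
             "mode": "exclude"},
        ],
    },
    # interventricular septum defect repair
    "defect_repair": {
        "name": "Defect Repair",
        "criteria": [
            {"domain": "procedure", "code_system": "OPCS-4", "code_prefix": "K11",
             "mode": "include", "role": "index_candidate"},
        ],
    },
}


def example_definition(key: str) -> CohortDefinition:
    if key not in EXAMPLE_DEFINITIONS:
        raise KeyError(f"unknown definition {key!r}; valid: {', '.join(EXAMPLE_DEFINITIONS)}")
    return parse_cohort_definition(EXAMPLE_DEFINITIONS[key])


__all__ = [
    "Criterion",
    "CohortDefinition",
    "CohortDefinitionError",
    "Cohort",
    "parse_cohort_definition",
    "code_matches",
    "evaluate_cohort",
    "EXAMPLE_DEFINITIONS",
    "example_definition",
]
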