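"""Shared fixtures: hand-built datasets, random-definition generation, and
an independent brute-force cohort filter used as the engine's oracle."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from clintel.cohort import CohortDefinition
from clintel.data_model import Dataset
from clintel.synthetic import (
    AgeMixtureComponent,
    CodePanelItem,
    GroupSpec,
    SimulationConfig,
    WaitingTime,
    simulate_dataset,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


def make_dataset(patients, events, coverage=("2018-01-01", "2024-12-31")) -> Dataset:
    """Hand-build a dataset from terse tuples.

    patients: (pid, dob, sex); events: (pid, domain, code_system, code, date)
    or (pid, 'observation', system, code, date, value).
    """
    pat = pd.DataFrame(
        [{"patient_id": p, "date_of_birth": pd.Timestamp(d), "sex": s}
         for p, d, s in patients],
        columns=["patient_id", "date_of_birth", "sex"],
    )
    pat["date_of_birth"] = pd.to_datetime(pat["date_of_birth"])
    ev: dict[str, list[dict]] = {d: [] for d in ("diagnosis", "procedure", "medication", "observation")}
    for row in events:
        pid, domain, system, code, date = row[:5]
        rec = {"patient_id": pid, "code_system": system, "code": code,
               "display": code, "event_date": pd.Timestamp(date)}
        if domain == "observation":
            rec["value"] = float(row[5])
            rec["unit"] = "u"
        ev[domain].append(rec)
    frames = {}
    for d, rows in ev.items():
        cols = ["patient_id", "code_system", "code", "display", "event_date"]
        if d == "observation":
            cols += ["value", "unit"]
        frames[d] = pd.DataFrame(rows, columns=cols)
        frames[d]["event_date"] = pd.to_datetime(frames[d]["event_date"])
    return Dataset(patients=pat, events=frames,
                   coverage_window=(pd.Timestamp(coverage[0]), pd.Timestamp(coverage[1])))


@pytest.fixture
def example1_dataset() -> Dataset:
    """Three-patient transplant fixture: P1 success, P2 later failure, P3 neither."""
    return make_dataset(
        patients=[("P1", "2010-05-01", "female"),
                  ("P2", "2012-03-01", "male"),
                  ("P3", "2011-01-01", "female")],
        events=[("P1", "procedure", "OPCS-4", "M012", "2022-01-01"),
                ("P2", "procedure", "OPCS-4", "M011", "2022-01-01"),
                ("P2", "procedure", "OPCS-4", "X401", "2022-06-01"),
                ("P3", "diagnosis", "ICD-10", "N18", "2022-02-01")],
    )


# ---------------------------------------------------------------------------
# independent brute-force cohort filter (the oracle)

def _event_matches(event, criterion) -> bool:
    if event["domain"] != criterion.domain:
        return False
    if criterion.code_system is not None and event["code_system"] != criterion.code_system:
        return False
    return any(event["code"].startswith(p) for p in criterion.prefixes)


def _in_window(date, temporal, index_date) -> bool:
    if temporal == "ever":
        return True
    if temporal == "on_or_after_index":
        return date >= index_date
    return date < index_date


def brute_force_cohort(dataset: Dataset, definition: CohortDefinition) -> dict[str, pd.Timestamp]:
    """Naive per-patient double loop, written independently of the engine."""
    per_patient: dict[str, list[dict]] = {}
    for domain in ("diagnosis", "procedure", "medication", "observation"):
        for row in dataset.events[domain].itertuples():
            per_patient.setdefault(row.patient_id, []).append(
                {"domain": domain, "code_system": row.code_system,
                 "code": row.code, "date": row.event_date}
            )
    members: dict[str, pd.Timestamp] = {}
    for pid in dataset.patients["patient_id"]:
        evs = per_patient.get(pid, [])
        index_dates = [
            e["date"] for e in evs
            for c in definition.index_criteria if _event_matches(e, c)
        ]
        if not index_dates:
            continue
        index_date = min(index_dates)
        ok = True
        for c in definition.criteria:
            hits = [e for e in evs
                    if _event_matches(e, c) and _in_window(e["date"], c.temporal, index_date)]
            if c.mode == "include" and not hits:
                ok = False
            if c.mode == "exclude" and hits:
                ok = False
        if ok:
            members[pid] = index_date
    return members


# ---------------------------------------------------------------------------
# randomized instances for the oracle equivalence study

CODE_UNIVERSE = [
    ("procedure", "OPCS-4", "M01"), ("procedure", "OPCS-4", "X40"),
    ("procedure", "OPCS-4", "K11"), ("procedure", "OPCS-4", "K45"),
    ("procedure", "OPCS-4", "U20"), ("diagnosis", "ICD-10", "N18"),
    ("diagnosis", "ICD-10", "J90"), ("diagnosis", "ICD-10", "I10"),
    ("diagnosis", "ICD-10", "S25"), ("medication", "generic_name", "HEPARIN"),
]


def random_simulation_config(rng: np.random.Generator, n_patients: int = 200) -> SimulationConfig:
    """A randomized generator config with diverse codes, timings and rates."""
    panel = []
    for domain, system, code in CODE_UNIVERSE:
        if code == "M01":
            continue  # reserved as the index procedure
        panel.append(CodePanelItem(
            domain=domain, code_system=system, code=code,
            prevalence=float(rng.uniform(0.05, 0.9)),
            timing=str(rng.choice(["after_index", "before_index"])),
            waiting=WaitingTime(dist="exponential", mean=float(rng.uniform(5, 200))),
        ))
    return SimulationConfig(
        n_patients=n_patients,
        seed=int(rng.integers(0, 2**31 - 1)),
        index_code="M01",
        groups=[GroupSpec(
            label="g", proportion=1.0,
            age_mixture=[AgeMixtureComponent(weight=1.0, meanlog=1.8, sdlog=0.6)],
            code_panel=panel,
        )],
    )


def random_definition(rng: np.random.Generator) -> CohortDefinition:
    """A random 1-4 criterion definition over the shared code universe."""
    criteria = [{
        "domain": "procedure", "code_system": "OPCS-4", "code_prefix": "M01",
        "mode": "include", "role": "index_candidate",
        "temporal": "ever",
    }]
    n_extra = int(rng.integers(0, 3))
    choices = [c for c in CODE_UNIVERSE if c[2] != "M01"]
    for _ in range(n_extra):
        domain, system, code = choices[int(rng.integers(0, len(choices)))]
        prefix = code if rng.random() < 0.7 else code[: max(1, len(code) - 1)]
        criteria.append({
            "domain": domain,
            "code_system": system if rng.random() < 0.8 else None,
            "code_prefix": prefix,
            "mode": str(rng.choice(["include", "exclude"])),
            "temporal": str(rng.choice(["ever", "on_or_after_index", "before_index"])),
            "role": "plain",
        })
    return CohortDefinition.model_validate({"name": "random", "criteria": criteria})


@pytest.fixture(scope="session")
def oracle_dataset():
    """A 200-patient randomized dataset shared by the oracle tests."""
    rng = np.random.default_rng(20240917)
    config = random_simulation_config(rng)
    dataset, truth = simulate_dataset(config)
    return dataset
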