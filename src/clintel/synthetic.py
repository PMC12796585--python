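"""Synthetic EHR generator.

Stands in for a hospital data warehouse: emits datasets in the common data
model with *known* statistical structure — latent patient groups, coded
event panels with configured prevalences and waiting-time laws, and
longitudinal numeric observations drawn from a time-varying sinh-arcsinh
distribution — plus the ground truth needed for recovery tests.

Every patient owns an independent substream spawned from the global seed,
so generation is deterministic and stable under patient reordering.

The four ready-made scenarios (:func:`make_example_scenario`) structurally
mirror common paediatric nephrology/cardiology questions: a kidney-transplant
creatinine consult, medication frequencies under haemodialysis, comorbidity
risk after cardiac surgery with and without pleural effusion, and time to
first echocardiogram after septal-defect repair.
"""

from __future__ import annotations

from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .data_model import Dataset, normalize_code
from .shash import sample_shash

DAYS_PER_YEAR = 365.25


class WaitingTime(BaseModel):
    """First-occurrence waiting time after index, in days."""

    dist: Literal["exponential", "weibull"] = "exponential"
    mean: float = 30.0          # exponential mean
    shape: float = 1.0          # weibull shape k
    scale: float = 30.0         # weibull scale

    def sample(self, rng: np.random.Generator) -> float:
        if self.dist == "exponential":
            return float(rng.exponential(self.mean))
        return float(self.scale * rng.weibull(self.shape))


class CodePanelItem(BaseModel):
    """One coded event type carried by a fraction ``prevalence`` of the group."""

    domain: Literal["diagnosis", "procedure", "medication", "observation"]
    code_system: str
    code: str
    display: str = ""
    prevalence: float = Field(ge=0.0, le=1.0)
    timing: Literal["after_index", "before_index"] = "after_index"
    waiting: WaitingTime = Field(default_factory=WaitingTime)

    @field_validator("code")
    @classmethod
    def _norm(cls, v: str) -> str:
        return normalize_code(v)


class TrajectorySpec(BaseModel):
    """Longitudinal numeric observation model.

    mu(t) and sigma(t) are piecewise-linear in days since index over
    ``t_knots``; values at irregular visit times (homogeneous Poisson
    process at ``visits_per_day``) are drawn from SHASH(mu(t), sigma(t),
    nu, tau).
    """

    code: str = "CREAT"
    display: str = "Serum creatinine"
    unit: str = "umol/L"
    t_knots: list[float]
    mu_knots: list[float]
    sigma_knots: list[float]
    nu: float = 0.0
    tau: float = 1.0
    visits_per_day: float = Field(default=1 / 14, gt=0)
    t_start: float = 0.0
    t_end: float = 730.0

    @model_validator(mode="after")
    def _check(self) -> "TrajectorySpec":
        if not (len(self.t_knots) == len(self.mu_knots) == len(self.sigma_knots)):
            raise ValueError("t_knots, mu_knots, sigma_knots must have equal length")
        if any(s <= 0 for s in self.sigma_knots):
            raise ValueError("sigma_knots must be positive everywhere")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        return self

    def mu(self, t):
        return np.interp(t, self.t_knots, self.mu_knots)

    def sigma(self, t):
        return np.interp(t, self.t_knots, self.sigma_knots)


class AgeMixtureComponent(BaseModel):
    """Lognormal component of the age-at-index law (years)."""

    weight: float = Field(gt=0)
    meanlog: float
    sdlog: float = Field(gt=0)


class GroupSpec(BaseModel):
    """Latent patient group: demographics plus its own code panels."""

    label: str
    proportion: float = Field(gt=0, le=1.0)
    sex_probs: dict[str, float] = Field(
        default_factory=lambda: {"female": 0.5, "male": 0.5}
    )
    age_mixture: list[AgeMixtureComponent] = Field(
        default_factory=lambda: [AgeMixtureComponent(weight=1.0, meanlog=1.5, sdlog=0.6)]
    )
    code_panel: list[CodePanelItem] = Field(default_factory=list)
    trajectories: list[TrajectorySpec] = Field(default_factory=list)


class SimulationConfig(BaseModel):
    """Full generator configuration; YAML-serializable."""

    n_patients: int = Field(gt=0)
    seed: int = 0
    coverage_window: tuple[str, str] = ("2021-07-01", "2023-06-30")
    index_code: str = "M01"
    index_display: str = "Index procedure"
    index_code_system: str = "OPCS-4"
    followup_reserve_days: int = 365
    groups: list[GroupSpec]

    @field_validator("index_code")
    @classmethod
    def _norm(cls, v: str) -> str:
        return normalize_code(v)

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        total = sum(g.proportion for g in self.groups)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"group proportions must sum to 1, got {total}")
        start, end = (pd.Timestamp(d) for d in self.coverage_window)
        if end <= start:
            raise ValueError("coverage_window end must follow start")
        if end - start <= pd.Timedelta(days=self.followup_reserve_days):
            raise ValueError("coverage window shorter than follow-up reserve")
        return self

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        return cls.model_validate(yaml.safe_load(text))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False)


class GroundTruth(BaseModel):
    """What the generator actually used, for recovery tests."""

    model_config = {"arbitrary_types_allowed": True}

    assignments: pd.DataFrame  # patient_id, group, age_at_index_years, index_date
    prevalence: dict[str, float]  # "group|domain|code" -> configured prevalence
    waiting: dict[str, WaitingTime]  # "group|domain|code" -> waiting-time law
    trajectories: dict[str, TrajectorySpec]  # "group|code" -> observation law
    config: SimulationConfig

    def group_of(self, patient_id: str) -> str:
        row = self.assignments.loc[self.assignments["patient_id"] == patient_id]
        return str(row["group"].iloc[0])


def _sample_age_years(mix: list[AgeMixtureComponent], rng: np.random.Generator) -> float:
    w = np.array([c.weight for c in mix], dtype=float)
    comp = mix[int(rng.choice(len(mix), p=w / w.sum()))]
    return float(np.exp(rng.normal(comp.meanlog, comp.sdlog)))


def simulate_dataset(config: SimulationConfig) -> tuple[Dataset, GroundTruth]:
    """Generate a dataset plus its ground truth; deterministic given config.

    Every patient receives the index procedure at their index date (time
    zero); panel events are Bernoulli(prevalence) with the configured
    waiting-time law after index (clamped to the coverage end so a carrier
    is always observable in-window) or uniform in the year before index;
    observation trajectories are sampled at Poisson visit times.
    """
    start, end = (pd.Timestamp(d) for d in config.coverage_window)
    index_hi = (end - start).days - config.followup_reserve_days
    labels = [g.label for g in config.groups]
    props = np.array([g.proportion for g in config.groups], dtype=float)
    props = props / props.sum()

    children = np.random.SeedSequence(config.seed).spawn(config.n_patients)
    pat_rows, assign_rows = [], []
    ev_rows: dict[str, list[dict]] = {d: [] for d in ("diagnosis", "procedure", "medication", "observation")}

    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        pid = f"P{i:06d}"
        group = config.groups[int(rng.choice(len(labels), p=props))]
        age = _sample_age_years(group.age_mixture, rng)
        index_date = start + pd.Timedelta(days=int(rng.integers(0, index_hi + 1)))
        dob = (index_date - pd.Timedelta(days=round(age * DAYS_PER_YEAR))).normalize()
        sexes = list(group.sex_probs)
        sp = np.array([group.sex_probs[s] for s in sexes], dtype=float)
        sex = sexes[int(rng.choice(len(sexes), p=sp / sp.sum()))]
        pat_rows.append({"patient_id": pid, "date_of_birth": dob, "sex": sex})
        assign_rows.append(
            {"patient_id": pid, "group": group.label,
             "age_at_index_years": age, "index_date": index_date}
        )
        ev_rows["procedure"].append(
            {"patient_id": pid, "code_system": config.index_code_system,
             "code": config.index_code, "display": config.index_display,
             "event_date": index_date}
        )
        max_fu_days = (end - index_date).days
        for item in group.code_panel:
            if rng.random() >= item.prevalence:
                continue
            if item.timing == "after_index":
                delay = min(item.waiting.sample(rng), float(max_fu_days))
                date = index_date + pd.Timedelta(days=round(delay))
            else:
                back = int(rng.integers(1, 366))
                # never before birth or before the coverage window opens
                date = max(index_date - pd.Timedelta(days=back), start, dob)
            ev_rows[item.domain].append(
                {"patient_id": pid, "code_system": item.code_system,
                 "code": item.code, "display": item.display or item.code,
                 "event_date": min(date, end)}
            )
        for traj in group.trajectories:
            t0, t1 = traj.t_start, min(traj.t_end, float(max_fu_days))
            if t1 <= t0:
                continue
            n_visits = rng.poisson(traj.visits_per_day * (t1 - t0))
            if n_visits == 0:
                continue
            times = np.sort(rng.uniform(t0, t1, size=n_visits))
            values = np.array(
                [sample_shash(traj.mu(t), traj.sigma(t), traj.nu, traj.tau, 1, rng)[0]
                 for t in times]
            )
            for t, v in zip(times, values):
                ev_rows["observation"].append(
                    {"patient_id": pid, "code_system": "observation_concept",
                     "code": traj.code, "display": traj.display,
                     "event_date": index_date + pd.Timedelta(days=round(t)),
                     "value": float(v), "unit": traj.unit}
                )

    patients = pd.DataFrame(pat_rows)
    events = {}
    for d, rows in ev_rows.items():
        cols = ["patient_id", "code_system", "code", "display", "event_date"]
        if d == "observation":
            cols += ["value", "unit"]
        events[d] = pd.DataFrame(rows, columns=cols)
        events[d]["event_date"] = pd.to_datetime(events[d]["event_date"])

    dataset = Dataset(patients=patients, events=events, coverage_window=(start, end))
    truth = GroundTruth(
        assignments=pd.DataFrame(assign_rows),
        prevalence={
            f"{g.label}|{it.domain}|{it.code}": it.prevalence
            for g in config.groups for it in g.code_panel
        },
        waiting={
            f"{g.label}|{it.domain}|{it.code}": it.waiting
            for g in config.groups for it in g.code_panel
        },
        trajectories={f"{g.label}|{t.code}": t for g in config.groups for t in g.trajectories},
        config=config,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# ready-made scenarios

SCENARIOS = ("transplant_consult", "dialysis_meds", "effusion_rr", "echo_tte")

# Fig-4b-style generic-name frequencies for the dialysis scenario
_DIALYSIS_MEDS = [
    ("HEPARIN", "Heparin", 0.96),
    ("PARACETAMOL", "Paracetamol", 0.90),
    ("SODIUMCHLORIDE", "Sodium chloride", 0.89),
    ("ALFACALCIDOL", "Alfacalcidol", 0.84),
    ("LEVOBUPIVACAINE", "Levobupivacaine", 0.81),
    ("ONDANSETRON", "Ondansetron", 0.70),
    ("AMOXICILLIN", "Amoxicillin", 0.55),
    ("FUROSEMIDE", "Furosemide", 0.45),
]
_DIALYSIS_CLASSES = [
    ("ANTICOAG", "Anticoagulants and protamine", 0.97),
    ("FLUIDS", "Fluids and electrolytes", 0.95),
    ("ANAEMIA", "Anaemias and other blood disorders", 0.93),
    ("VITAMINS", "Vitamins", 0.92),
    ("ANALGESICS", "Analgesics", 0.91),
]


def make_example_scenario(name: str, n_patients: Optional[int] = None, seed: int = 0) -> SimulationConfig:
    """Return the configuration for one of the four shipped study scenarios."""
    if name == "transplant_consult":
        # kidney transplant; creatinine falls from ~150 to a ~70 umol/L plateau
        traj = TrajectorySpec(
            code="CREAT", display="Serum creatinine", unit="umol/L",
            t_knots=[0.0, 7.0, 90.0, 365.0, 730.0],
            mu_knots=[160.0, 150.0, 95.0, 72.0, 70.0],
            sigma_knots=[20.0, 18.0, 14.0, 11.0, 10.0],
            nu=0.5, tau=1.0, visits_per_day=1 / 10, t_start=0.0, t_end=730.0,
        )
        groups = [
            GroupSpec(
                label="transplant", proportion=1.0,
                age_mixture=[AgeMixtureComponent(weight=1.0, meanlog=2.2, sdlog=0.5)],
                code_panel=[
                    CodePanelItem(domain="procedure", code_system="OPCS-4", code="X40",
                                  display="Compensation for renal failure", prevalence=0.15,
                                  waiting=WaitingTime(dist="exponential", mean=180.0)),
                    CodePanelItem(domain="diagnosis", code_system="ICD-10", code="N18",
                                  display="Chronic kidney disease", prevalence=0.9,
                                  timing="before_index"),
                ],
                trajectories=[traj],
            )
        ]
        return SimulationConfig(
            n_patients=n_patients or 150, seed=seed, index_code="M01",
            index_display="Transplantation of kidney",
            coverage_window=("2019-07-01", "2023-06-30"), followup_reserve_days=730,
            groups=groups,
        )

    if name == "dialysis_meds":
        meds = [
            CodePanelItem(domain="medication", code_system="generic_name", code=c,
                          display=d, prevalence=p,
                          waiting=WaitingTime(dist="exponential", mean=45.0))
            for c, d, p in _DIALYSIS_MEDS
        ] + [
            CodePanelItem(domain="medication", code_system="therapeutic_class", code=c,
                          display=d, prevalence=p,
                          waiting=WaitingTime(dist="exponential", mean=45.0))
            for c, d, p in _DIALYSIS_CLASSES
        ]
        groups = [
            GroupSpec(
                label="dialysis", proportion=0.9,
                age_mixture=[AgeMixtureComponent(weight=1.0, meanlog=2.0, sdlog=0.6)],
                code_panel=meds + [
                    CodePanelItem(domain="diagnosis", code_system="ICD-10", code="N18",
                                  display="Chronic kidney disease", prevalence=0.95,
                                  timing="before_index"),
                ],
            ),
            GroupSpec(
                label="transplanted", proportion=0.1,
                age_mixture=[AgeMixtureComponent(weight=1.0, meanlog=2.0, sdlog=0.6)],
                code_panel=[
                    CodePanelItem(domain="procedure", code_system="OPCS-4", code="M01",
                                  display="Transplantation of kidney", prevalence=1.0,
                                  waiting=WaitingTime(dist="exponential", mean=120.0)),
                    CodePanelItem(domain="diagnosis", code_system="ICD-10", code="N18",
                                  display="Chronic kidney disease", prevalence=0.95,
                                  timing="before_index"),
                ],
            ),
        ]
        return SimulationConfig(
            n_patients=n_patients or 1000, seed=seed, index_code="X40",
            index_display="Compensation for renal failure", groups=groups,
        )

    if name == "effusion_rr":
        # bimodal ages: surgery peaks near 1 y in both arms, second peak near
        # 15 y only in the no-effusion arm; lognormal mode = exp(meanlog - sdlog^2)
        common = dict(domain="diagnosis", code_system="ICD-10",
                      waiting=WaitingTime(dist="exponential", mean=60.0))
        groups = [
            GroupSpec(
                label="effusion", proportion=0.32,
                age_mixture=[AgeMixtureComponent(weight=1.0, meanlog=0.25, sdlog=0.5)],
                code_panel=[
                    CodePanelItem(code="J90", display="Pleural effusion", prevalence=1.0, **common),
                    CodePanelItem(code="I10", display="Essential hypertension", prevalence=0.30, **common),
                    CodePanelItem(code="S25", display="Injury of blood vessels of thorax", prevalence=0.04, **common),
                    CodePanelItem(code="K31", display="Other diseases of stomach and duodenum", prevalence=0.04, **common),
                    CodePanelItem(code="F19", display="Disorders due to multiple drug use", prevalence=0.03, **common),
                    CodePanelItem(code="E87", display="Fluid and electrolyte disorders", prevalence=0.25, **common),
                ],
            ),
            GroupSpec(
                label="others", proportion=0.68,
                age_mixture=[
                    AgeMixtureComponent(weight=0.55, meanlog=0.25, sdlog=0.5),
                    AgeMixtureComponent(weight=0.45, meanlog=2.798, sdlog=0.3),
                ],
                code_panel=[
                    CodePanelItem(code="I10", display="Essential hypertension", prevalence=0.10, **common),
                    CodePanelItem(code="S25", display="Injury of blood vessels of thorax", prevalence=0.002, **common),
                    CodePanelItem(code="K31", display="Other diseases of stomach and duodenum", prevalence=0.002, **common),
                    CodePanelItem(code="F19", display="Disorders due to multiple drug use", prevalence=0.002, **common),
                    CodePanelItem(code="E87", display="Fluid and electrolyte disorders", prevalence=0.20, **common),
                ],
            ),
        ]
        return SimulationConfig(
            n_patients=n_patients or 2000, seed=seed, index_code="K45",
            index_display="Cardiac surgery (heart chapter)", groups=groups,
        )

    if name == "echo_tte":
        # median time to first echo = 3*ln 2 ~ 2.08 days under mean-3 waiting
        groups = [
            GroupSpec(
                label="defect_repair", proportion=1.0,
                age_mixture=[AgeMixtureComponent(weight=1.0, meanlog=0.25, sdlog=0.5)],
                code_panel=[
                    CodePanelItem(domain="procedure", code_system="OPCS-4", code="U20",
                                  display="Transthoracic echocardiography", prevalence=1.0,
                                  waiting=WaitingTime(dist="exponential", mean=3.0)),
                ],
            )
        ]
        return SimulationConfig(
            n_patients=n_patients or 1000, seed=seed, index_code="K11",
            index_display="Repair of defect of interventricular septum", groups=groups,
        )

    raise ValueError(f"unknown scenario {name!r}; valid names: {', '.join(SCENARIOS)}")


__all__ = [
    "WaitingTime",
    "CodePanelItem",
    "TrajectorySpec",
    "AgeMixtureComponent",
    "GroupSpec",
    "SimulationConfig",
    "GroundTruth",
    "simulate_dataset",
    "make_example_scenario",
    "SCENARIOS",
]
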