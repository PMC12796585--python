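"""Pipeline execution: cohort evaluation, analytics steps, report bundles.

A pipeline config (YAML/JSON) names a dataset (a directory in the on-disk
layout, or a shipped synthetic scenario), one or more cohort definitions,
and an ordered list of registered analytics modules with parameters.  The
run resolves cohorts, executes each step, and collects everything into a
:class:`ReportBundle` with a provenance block (dataset content hash, config
hash, seed, package version).  A failing stage marks the bundle failed but
preserves the outputs of the stages that already ran; given the same
dataset, config and seed, serialized outputs are identical run to run
(timestamps aside).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Optional

import yaml
from pydantic import BaseModel, Field

from .cohort import (
    Cohort,
    CohortDefinition,
    EXAMPLE_DEFINITIONS,
    evaluate_cohort,
    parse_cohort_definition,
)
from .data_model import Dataset, read_dataset
from .registry import ModuleRegistry, default_registry
from .synthetic import make_example_scenario, simulate_dataset
from .tables import DEFAULT_SUPPRESSION_THRESHOLD, ResultTable


class CohortConfig(BaseModel):
    key: str
    definition: Optional[dict] = None   # inline definition document
    example: Optional[str] = None       # key into the shipped definitions
    file: Optional[str] = None          # path to a JSON definition


class StepConfig(BaseModel):
    module: str
    version: Optional[str] = None
    cohorts: list[str] = Field(min_length=1)
    params: dict[str, Any] = Field(default_factory=dict)
    label: Optional[str] = None


class ScenarioConfig(BaseModel):
    name: str
    n_patients: Optional[int] = None


class PipelineConfig(BaseModel):
    title: str = "Analytics report"
    dataset: Optional[str] = None          # directory in the on-disk layout
    scenario: Optional[ScenarioConfig] = None
    seed: int = 0
    suppression_threshold: int = DEFAULT_SUPPRESSION_THRESHOLD
    cohorts: list[CohortConfig] = Field(min_length=1)
    steps: list[StepConfig] = Field(min_length=1)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(text))


@dataclass
class ReportBundle:
    title: str
    definitions: dict[str, CohortDefinition] = field(default_factory=dict)
    cohorts: dict[str, Cohort] = field(default_factory=dict)
    tables: dict[str, ResultTable] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    failed: bool = False
    error: str | None = None

    def serialized(self, include_timestamp: bool = False) -> str:
        """Canonical JSON of all contents; the determinism test surface."""
        prov = dict(self.provenance)
        if not include_timestamp:
            prov.pop("timestamp", None)
        return json.dumps({
            "title": self.title,
            "definitions": {k: d.model_dump() for k, d in self.definitions.items()},
            "cohorts": {
                k: [[r.patient_id, str(r.index_date.date())]
                    for r in c.members.itertuples()]
                for k, c in self.cohorts.items()
            },
            "tables": {k: json.loads(t.to_json()) for k, t in self.tables.items()},
            "provenance": prov,
            "failed": self.failed,
            "error": self.error,
        }, indent=2, sort_keys=True)

    def write(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "bundle.json").write_text(self.serialized(include_timestamp=True))
        for k, t in self.tables.items():
            t.to_csv(out_dir / f"{k}.csv")
        return out_dir


def _resolve_definition(cc: CohortConfig, base_dir: Path) -> CohortDefinition:
    sources = [s for s in (cc.definition, cc.example, cc.file) if s is not None]
    if len(sources) != 1:
        raise ValueError(
            f"cohort {cc.key!r} must give exactly one of definition/example/file"
        )
    if cc.definition is not None:
        return parse_cohort_definition(cc.definition)
    if cc.example is not None:
        if cc.example not in EXAMPLE_DEFINITIONS:
            raise ValueError(f"unknown example definition {cc.example!r}")
        return parse_cohort_definition(EXAMPLE_DEFINITIONS[cc.example])
    return parse_cohort_definition((base_dir / cc.file).read_text())


def load_pipeline_dataset(config: PipelineConfig, base_dir: str | Path = ".") -> Dataset:
    if (config.dataset is None) == (config.scenario is None):
        raise ValueError("config must give exactly one of 'dataset' or 'scenario'")
    if config.dataset is not None:
        return read_dataset(Path(base_dir) / config.dataset)
    sim = make_example_scenario(
        config.scenario.name, n_patients=config.scenario.n_patients, seed=config.seed
    )
    dataset, _ = simulate_dataset(sim)
    return dataset


def run_pipeline(
    config: PipelineConfig | dict | str,
    registry: ModuleRegistry | None = None,
    base_dir: str | Path = ".",
    dataset: Dataset | None = None,
) -> ReportBundle:
    """Execute cohort evaluation then each analytics step in order."""
    if isinstance(config, str):
        config = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = PipelineConfig.model_validate(config)
    registry = registry or default_registry()
    base_dir = Path(base_dir)

    bundle = ReportBundle(title=config.title)
    try:
        if dataset is None:
            dataset = load_pipeline_dataset(config, base_dir)
    except Exception as e:  # noqa: BLE001 - stage failures are reported, not raised
        bundle.failed, bundle.error = True, f"dataset stage: {e}"
        return bundle

    bundle.provenance = {
        "dataset_hash": dataset.content_hash(),
        "config_hash": hashlib.sha256(
            json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()
        ).hexdigest()[:16],
        "seed": config.seed,
        "package_version": _package_version(),
        "suppression_threshold": config.suppression_threshold,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }

    try:
        for cc in config.cohorts:
            definition = _resolve_definition(cc, base_dir)
            bundle.definitions[cc.key] = definition
            bundle.cohorts[cc.key] = evaluate_cohort(dataset, definition)
    except Exception as e:  # noqa: BLE001
        bundle.failed, bundle.error = True, f"cohort stage: {e}"
        return bundle

    for i, step in enumerate(config.steps):
        label = step.label or f"{i + 1:02d}_{step.module}"
        try:
            entry = registry.get(step.module, step.version)
            missing = [k for k in step.cohorts if k not in bundle.cohorts]
            if missing:
                raise KeyError(f"step references undefined cohort(s) {missing}")
            cohorts = [bundle.cohorts[k] for k in step.cohorts]
            params = dict(step.params)
            params.setdefault("threshold", config.suppression_threshold)
            table = entry.implementation(dataset, cohorts, **params)
            if not isinstance(table, ResultTable):
                raise TypeError(
                    f"module {step.module!r} returned {type(table).__name__}, "
                    "expected ResultTable"
                )
            bundle.tables[label] = table
        except Exception as e:  # noqa: BLE001
            bundle.failed, bundle.error = True, f"step {label} ({step.module}): {e}"
            return bundle
    return bundle


def _package_version() -> str:
    from . import __version__

    return __version__


__all__ = [
    "PipelineConfig",
    "CohortConfig",
    "StepConfig",
    "ScenarioConfig",
    "ReportBundle",
    "run_pipeline",
    "load_pipeline_dataset",
]
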