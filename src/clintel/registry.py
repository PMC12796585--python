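"""Analytics-module registry enforcing the reproducible-pipeline contract.

Any analytics routine that wants to be callable from pipeline configs or
the CLI must be registered with a spec declaring its name, version, inputs
drawn from the common-data-model vocabulary, and a ``ResultTable`` output.
Duplicate name+version pairs and undeclared types are rejected at
registration time, so the pipeline only ever runs modules with a known
contract.
"""

from __future__ import annotations

import inspect
from dataclasses import dataclass, field
from typing import Callable

from pydantic import BaseModel, Field

KNOWN_INPUT_TYPES = ("Dataset", "Cohort", "CohortDefinition", "Criterion", "ResultTable")
KNOWN_OUTPUT_TYPES = ("ResultTable",)


class RegistrationError(Exception):
    """The module spec or implementation violates the plugin contract."""


def n_call_args(spec: "AnalyticsModuleSpec") -> int:
    """Positional arguments the pipeline passes: the dataset, then one
    argument carrying the step's resolved cohorts, then any other declared
    input.  Multiple Cohort declarations still arrive as the one list."""
    n = int("Dataset" in spec.inputs)
    n += int("Cohort" in spec.inputs)
    n += sum(1 for t in spec.inputs if t not in ("Dataset", "Cohort"))
    return n


class AnalyticsModuleSpec(BaseModel):
    name: str
    version: str = "1.0"
    inputs: list[str] = Field(min_length=1)
    output: str = "ResultTable"
    doc: str = ""
    test_ref: str = ""  # dotted path of the module's test coverage


@dataclass
class RegistryEntry:
    spec: AnalyticsModuleSpec
    implementation: Callable


@dataclass
class ModuleRegistry:
    entries: dict[tuple[str, str], RegistryEntry] = field(default_factory=dict)

    def register(self, spec: AnalyticsModuleSpec, implementation: Callable) -> RegistryEntry:
        key = (spec.name, spec.version)
        if key in self.entries:
            raise RegistrationError(f"module {spec.name!r} version {spec.version!r} already registered")
        unknown_in = [t for t in spec.inputs if t not in KNOWN_INPUT_TYPES]
        if unknown_in:
            raise RegistrationError(
                f"unknown input type(s) {unknown_in}; declared inputs must come "
                f"from {KNOWN_INPUT_TYPES}"
            )
        if spec.output not in KNOWN_OUTPUT_TYPES:
            raise RegistrationError(
                f"unknown output type {spec.output!r}; must be one of {KNOWN_OUTPUT_TYPES}"
            )
        sig = inspect.signature(implementation)
        positional = [
            p for p in sig.parameters.values()
            if p.kind in (p.POSITIONAL_ONLY, p.POSITIONAL_OR_KEYWORD)
        ]
        needed = n_call_args(spec)
        if len(positional) < needed:
            raise RegistrationError(
                f"implementation of {spec.name!r} accepts {len(positional)} positional "
                f"parameter(s) but its contract requires {needed} "
                f"(declared inputs: {spec.inputs})"
            )
        entry = RegistryEntry(spec=spec, implementation=implementation)
        self.entries[key] = entry
        return entry

    def get(self, name: str, version: str | None = None) -> RegistryEntry:
        matches = [e for (n, v), e in self.entries.items() if n == name]
        if not matches:
            raise KeyError(f"no registered module named {name!r}")
        if version is None:
            return sorted(matches, key=lambda e: e.spec.version)[-1]
        try:
            return self.entries[(name, version)]
        except KeyError:
            raise KeyError(f"module {name!r} has no version {version!r}") from None

    def list_modules(self) -> list[AnalyticsModuleSpec]:
        return [e.spec for _, e in sorted(self.entries.items())]


def default_registry() -> ModuleRegistry:
    """Registry pre-loaded with the built-in analytics library."""
    from . import pipeline_modules as pm

    registry = ModuleRegistry()
    for spec, impl in pm.BUILTIN_MODULES:
        registry.register(spec, impl)
    return registry


__all__ = [
    "AnalyticsModuleSpec",
    "ModuleRegistry",
    "RegistryEntry",
    "RegistrationError",
    "default_registry",
    "KNOWN_INPUT_TYPES",
    "KNOWN_OUTPUT_TYPES",
]
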