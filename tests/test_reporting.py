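"""Plugin registry contract, pipeline determinism and report disclosure scan."""

import re

import pandas as pd
import pytest

from clintel.pipeline import PipelineConfig, run_pipeline
from clintel.registry import (
    AnalyticsModuleSpec,
    ModuleRegistry,
    RegistrationError,
    default_registry,
)
from clintel.report import DISCLAIMER, render_report
from clintel.tables import ResultTable


def spec(**kw):
    base = dict(name="demo", version="1.0", inputs=["Dataset", "Cohort"])
    base.update(kw)
    return AnalyticsModuleSpec(**base)


def impl(dataset, cohorts, **params):
    return ResultTable(title="demo", data=pd.DataFrame({"label": [], "count": []}))


class TestRegistry:
    def test_registered_module_listed(self):
        reg = ModuleRegistry()
        reg.register(spec(), impl)
        assert [s.name for s in reg.list_modules()] == ["demo"]

    def test_duplicate_name_version_rejected(self):
        reg = ModuleRegistry()
        reg.register(spec(), impl)
        with pytest.raises(RegistrationError, match="already registered"):
            reg.register(spec(), impl)
        reg.register(spec(version="2.0"), impl)  # new version is fine

    def test_unknown_input_type_rejected(self):
        reg = ModuleRegistry()
        with pytest.raises(RegistrationError, match="unknown input"):
            reg.register(spec(inputs=["Spreadsheet"]), impl)

    def test_signature_mismatch_rejected(self):
        reg = ModuleRegistry()
        with pytest.raises(RegistrationError, match="positional"):
            reg.register(spec(), lambda dataset: None)

    def test_builtin_library_registered(self):
        names = {s.name for s in default_registry().list_modules()}
        assert {"demographics", "frequency", "relative_risk_scan",
                "age_comparison", "time_to_event"} <= names


DIALYSIS_PIPELINE = {
    "title": "Dialysis medication report",
    "scenario": {"name": "dialysis_meds", "n_patients": 300},
    "seed": 5,
    "cohorts": [{"key": "dialysis", "example": "dialysis_patients"}],
    "steps": [
        {"module": "demographics", "cohorts": ["dialysis"]},
        {"module": "frequency", "cohorts": ["dialysis"],
         "params": {"domain": "medication", "group_by": "generic_name", "top_k": 15}},
    ],
}


class TestPipeline:
    def test_dialysis_frequency_pipeline(self):
        bundle = run_pipeline(DIALYSIS_PIPELINE)
        assert not bundle.failed
        freq = bundle.tables["02_frequency"]
        assert len(freq.data) <= 15
        assert freq.data.iloc[0]["label"] == "Heparin"

    def test_repeat_run_identical_serialization(self):
        b1 = run_pipeline(DIALYSIS_PIPELINE)
        b2 = run_pipeline(DIALYSIS_PIPELINE)
        assert b1.serialized() == b2.serialized()

    def test_unknown_module_fails_bundle_preserving_prior_stages(self):
        cfg = dict(DIALYSIS_PIPELINE)
        cfg["steps"] = [
            {"module": "demographics", "cohorts": ["dialysis"]},
            {"module": "does_not_exist", "cohorts": ["dialysis"]},
        ]
        bundle = run_pipeline(cfg)
        assert bundle.failed
        assert "does_not_exist" in bundle.error
        assert "01_demographics" in bundle.tables  # earlier output preserved

    def test_yaml_config_parses(self):
        text = """
title: t
scenario: {name: echo_tte, n_patients: 50}
seed: 2
cohorts:
  - {key: repair, example: defect_repair}
steps:
  - module: time_to_event
    cohorts: [repair]
    params:
      target: {domain: procedure, code_system: OPCS-4, code_prefix: U20}
      horizon: 28
"""
        bundle = run_pipeline(text)
        assert not bundle.failed
        assert "01_time_to_event" in bundle.tables


class TestRendering:
    def test_html_contains_values_and_disclaimer(self, tmp_path):
        bundle = run_pipeline(DIALYSIS_PIPELINE)
        out = render_report(bundle, "html", tmp_path / "r.html")
        text = out.read_text()
        assert "Heparin" in text
        assert DISCLAIMER[:40] in text
        assert bundle.provenance["dataset_hash"] in text

    def test_pdf_renders(self, tmp_path):
        bundle = run_pipeline(DIALYSIS_PIPELINE)
        out = render_report(bundle, "pdf", tmp_path / "r.pdf")
        assert out.read_bytes()[:5] == b"%PDF-"

    def test_unsupported_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            render_report(run_pipeline(DIALYSIS_PIPELINE), "docx", tmp_path / "r.docx")

    def test_empty_bundle_renders_provenance_only(self, tmp_path):
        from clintel.pipeline import ReportBundle

        bundle = ReportBundle(title="empty", provenance={"seed": 0})
        out = render_report(bundle, "html", tmp_path / "e.html")
        assert "No analytics outputs" in out.read_text()

    def test_no_small_count_ever_rendered(self, tmp_path):
        """Disclosure scan: rendered reports never show a count in 1..k-1."""
        threshold = 5
        for seed in range(10):
            cfg = dict(DIALYSIS_PIPELINE)
            cfg["seed"] = seed
            cfg["scenario"] = {"name": "dialysis_meds", "n_patients": 40}
            cfg["suppression_threshold"] = threshold
            bundle = run_pipeline(cfg)
            assert not bundle.failed
            for name, table in bundle.tables.items():
                rendered = table.rendered()
                for col in table.count_columns:
                    for cell in rendered[col]:
                        if re.fullmatch(r"\d+", cell):
                            assert not (0 < int(cell) < threshold), (name, col, cell)


class TestCLI:
    def test_simulate_build_analyze_round_trip(self, tmp_path):
        import json

        from typer.testing import CliRunner

        from clintel.cli import app

        runner = CliRunner()
        data = tmp_path / "data"
        res = runner.invoke(app, ["simulate", "--scenario", "dialysis_meds",
                                  "--n-patients", "120", "--seed", "3",
                                  "--out", str(data)])
        assert res.exit_code == 0, res.output

        definition = tmp_path / "dialysis.json"
        from clintel.cohort import EXAMPLE_DEFINITIONS

        definition.write_text(json.dumps(EXAMPLE_DEFINITIONS["dialysis_patients"]))
        cohort_file = tmp_path / "cohort.csv"
        res = runner.invoke(app, ["build-cohort", "--data", str(data),
                                  "--definition", str(definition),
                                  "--out", str(cohort_file)])
        assert res.exit_code == 0, res.output
        assert "members" in res.output

        out = tmp_path / "freq.csv"
        res = runner.invoke(app, ["analyze", "frequency", "--data", str(data),
                                  "--cohort", str(cohort_file),
                                  "--params", '{"domain": "medication", "group_by": "generic_name"}',
                                  "--out", str(out)])
        assert res.exit_code == 0, res.output
        assert "label" in out.read_text()

    def test_list_modules_names_builtins(self):
        from typer.testing import CliRunner

        from clintel.cli import app

        res = CliRunner().invoke(app, ["list-modules"])
        assert res.exit_code == 0
        assert "frequency" in res.output and "time_to_event" in res.output
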