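"""Demographics tables, patient-level frequencies and disclosure control."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from clintel.cohort import Cohort
from clintel.descriptive import age_at, demographics_overview, frequency_analysis
from clintel.synthetic import make_example_scenario, simulate_dataset
from clintel.cohort import evaluate_cohort, example_definition
from clintel.tables import ResultTable, suppress_small_counts

from conftest import make_dataset


def cohort_of(members):
    return Cohort("test", pd.DataFrame(
        [{"patient_id": p, "index_date": pd.Timestamp(d)} for p, d in members]
    ))


@pytest.fixture
def ten_patient_dataset():
    patients = [(f"P{i}", "2000-01-01", "female" if i < 6 else "male")
                for i in range(10)]
    events = [(f"P{i}", "procedure", "OPCS-4", "K11", "2020-01-01") for i in range(10)]
    return make_dataset(patients=patients, events=events)


class TestDemographics:
    def test_sex_counts_and_percentages(self, ten_patient_dataset):
        cohort = cohort_of([(f"P{i}", "2020-01-01") for i in range(10)])
        table = demographics_overview(ten_patient_dataset, [cohort], threshold=5)
        rows = table.data.set_index("measure")
        assert rows.loc["sex: female", "count"] == 6
        assert rows.loc["sex: female", "percent"] == pytest.approx(60.0)
        assert rows.loc["sex: male", "count"] == 4
        assert rows.loc["sex: male", "percent"] == pytest.approx(40.0)

    def test_small_sex_count_suppressed(self, ten_patient_dataset):
        cohort = cohort_of([("P0", "2020-01-01"), ("P1", "2020-01-01"),
                            ("P2", "2020-01-01"), ("P6", "2020-01-01")])
        table = demographics_overview(ten_patient_dataset, [cohort], threshold=5)
        rendered = table.rendered().set_index("measure")
        assert rendered.loc["sex: female", "count"] == "<5"
        assert rendered.loc["sex: female", "percent"] == "<5"

    def test_age_at_entry_calendar_arithmetic(self):
        # 2000-01-01 -> 2010-01-01 is 3653 days = 10.0014 years
        dob = pd.Series([pd.Timestamp("2000-01-01")])
        ages = age_at(dob, pd.Series([pd.Timestamp("2010-01-01")]))
        assert ages[0] == pytest.approx(3653 / 365.25)

    def test_empty_cohort_yields_rows_not_error(self, ten_patient_dataset):
        empty = Cohort("none", pd.DataFrame(columns=["patient_id", "index_date"]))
        table = demographics_overview(ten_patient_dataset, [empty])
        assert (table.data["cohort"] == "none").any()


class TestFrequency:
    def test_after_index_window_patient_level(self):
        ds = make_dataset(
            patients=[(f"P{i}", "2000-01-01", "female") for i in range(4)],
            events=[
                ("P0", "medication", "generic_name", "DRUGA", "2020-02-01"),
                ("P1", "medication", "generic_name", "DRUGA", "2020-03-01"),
                ("P2", "medication", "generic_name", "DRUGA", "2020-04-01"),
                ("P3", "medication", "generic_name", "DRUGA", "2019-06-01"),  # pre-index only
            ],
        )
        cohort = cohort_of([(f"P{i}", "2020-01-01") for i in range(4)])
        table = frequency_analysis(ds, cohort, "medication", "code",
                                   window="after_index", top_k=10, threshold=1)
        row = table.data.set_index("label").loc["DRUGA"]
        assert row["n_patients"] == 3 and row["percent"] == pytest.approx(75.0)

    def test_repetition_does_not_inflate_frequency(self):
        events = [("P0", "medication", "generic_name", "DRUGB", f"2020-02-{d:02d}")
                  for d in range(1, 29)]
        ds = make_dataset(
            patients=[("P0", "2000-01-01", "male"), ("P1", "2000-01-01", "male")],
            events=events,
        )
        cohort = cohort_of([("P0", "2020-01-01"), ("P1", "2020-01-01")])
        table = frequency_analysis(ds, cohort, "medication", "code", threshold=1)
        assert table.data.set_index("label").loc["DRUGB", "percent"] == pytest.approx(50.0)

    def test_dialysis_scenario_recovers_configured_96pct(self):
        dataset, _ = simulate_dataset(make_example_scenario("dialysis_meds", n_patients=1000))
        cohort = evaluate_cohort(dataset, example_definition("dialysis_patients"))
        table = frequency_analysis(dataset, cohort, "medication", "generic_name",
                                   window="after_index", top_k=15)
        top = table.data.iloc[0]
        assert top["label"] == "Heparin"
        assert abs(top["percent"] / 100.0 - 0.96) < 0.02

    def test_top_k_is_prefix_of_full_ranking(self):
        dataset, _ = simulate_dataset(make_example_scenario("dialysis_meds", n_patients=300))
        cohort = evaluate_cohort(dataset, example_definition("dialysis_patients"))
        full = frequency_analysis(dataset, cohort, "medication", "generic_name", top_k=None)
        head = frequency_analysis(dataset, cohort, "medication", "generic_name", top_k=3)
        pd.testing.assert_frame_equal(head.data, full.data.head(3))

    def test_unknown_group_by_rejected(self, ten_patient_dataset):
        cohort = cohort_of([("P0", "2020-01-01")])
        with pytest.raises(ValueError, match="group_by"):
            frequency_analysis(ten_patient_dataset, cohort, "medication", "route")

    @given(dup=st.integers(min_value=1, max_value=30))
    def test_percent_invariant_to_event_duplication(self, dup):
        events = [("P0", "medication", "generic_name", "DRUGC", "2020-02-01")] * dup
        ds = make_dataset(
            patients=[("P0", "2000-01-01", "male"), ("P1", "2000-01-01", "male")],
            events=events,
        )
        cohort = cohort_of([("P0", "2020-01-01"), ("P1", "2020-01-01")])
        table = frequency_analysis(ds, cohort, "medication", "code", threshold=1)
        assert (table.data["percent"] <= 100).all()
        assert table.data.set_index("label").loc["DRUGC", "percent"] == pytest.approx(50.0)


class TestSuppression:
    def make_table(self, counts):
        return ResultTable(
            title="t",
            data=pd.DataFrame({"count": counts,
                               "percent": [10.0 * c for c in counts]}),
            count_columns=("count",),
            derived={"percent": "count"},
        )

    def test_rule_masks_only_1_to_threshold_minus_1(self):
        table = suppress_small_counts(self.make_table([0, 3, 5, 12]), 5)
        assert list(table.suppressed["count"]) == [False, True, False, False]
        assert list(table.suppressed["percent"]) == [False, True, False, False]
        rendered = table.rendered()
        assert rendered.loc[1, "count"] == "<5"
        assert rendered.loc[0, "count"] == "0"  # zero never masked

    def test_idempotent(self):
        once = suppress_small_counts(self.make_table([0, 3, 5, 12]), 5)
        twice = suppress_small_counts(once, 5)
        pd.testing.assert_frame_equal(once.suppressed, twice.suppressed)
        assert once.rendered().equals(twice.rendered())

    def test_threshold_one_masks_nothing(self):
        table = suppress_small_counts(self.make_table([1, 2, 3]), 1)
        assert not table.suppressed.any().any()

    @given(counts=st.lists(st.integers(min_value=0, max_value=30), min_size=1, max_size=12),
           t1=st.integers(min_value=1, max_value=10), t2=st.integers(min_value=1, max_value=10))
    def test_monotone_in_threshold(self, counts, t1, t2):
        lo, hi = sorted((t1, t2))
        masked_lo = suppress_small_counts(self.make_table(counts), lo).suppressed["count"]
        masked_hi = suppress_small_counts(self.make_table(counts), hi).suppressed["count"]
        assert (masked_lo <= masked_hi).all()  # higher threshold never unmasks
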