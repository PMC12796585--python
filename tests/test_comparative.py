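"""Relative risk, Katz intervals, Kruskal-Wallis and age comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clintel.cohort import Cohort, evaluate_cohort, example_definition
from clintel.comparative import (
    age_at_entry_comparison,
    kruskal_wallis,
    relative_risk,
    relative_risk_scan,
)
from clintel.synthetic import make_example_scenario, simulate_dataset

from conftest import make_dataset


def cohort_of(name, members):
    return Cohort(name, pd.DataFrame(
        [{"patient_id": p, "index_date": pd.Timestamp(d)} for p, d in members]
    ))


class TestRelativeRisk:
    def test_point_estimate_closed_form(self):
        est = relative_risk(4, 10, 2, 20)
        assert est.rr == pytest.approx(4.0)
        assert not est.corrected

    def test_katz_interval_hand_computed(self):
        # exp(ln 4 +/- 1.96 * sqrt(1/4 - 1/10 + 1/2 - 1/20)) = (0.877, 18.26)
        est = relative_risk(4, 10, 2, 20, alpha=0.05)
        se = np.sqrt(0.25 - 0.1 + 0.5 - 0.05)
        z = stats.norm.ppf(0.975)
        assert est.ci_low == pytest.approx(4.0 * np.exp(-z * se), rel=1e-12)
        assert est.ci_high == pytest.approx(4.0 * np.exp(z * se), rel=1e-12)
        assert est.ci_low == pytest.approx(0.877, abs=5e-3)
        assert est.ci_high == pytest.approx(18.26, abs=5e-2)

    def test_both_risks_one_gives_rr_one(self):
        est = relative_risk(10, 10, 20, 20)
        assert est.rr == pytest.approx(1.0)

    def test_zero_cell_correction_flagged(self):
        est = relative_risk(0, 100, 5, 100)
        assert est.corrected and est.rr > 0 and est.ci_low > 0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            relative_risk(1, 0, 1, 10)
        with pytest.raises(ValueError):
            relative_risk(11, 10, 1, 10)

    def test_ci_coverage_at_true_rr_2(self):
        """2000 simulated 2x2 tables, n=500 per arm, RR=2: ~95% coverage."""
        rng = np.random.default_rng(123)
        p2, p1 = 0.1, 0.2
        a = rng.binomial(500, p1, size=2000)
        b = rng.binomial(500, p2, size=2000)
        covered = 0
        for ai, bi in zip(a, b):
            est = relative_risk(int(ai), 500, int(bi), 500)
            covered += est.ci_low <= 2.0 <= est.ci_high
        assert abs(covered / 2000 - 0.95) <= 0.015


class TestScan:
    def make_two_arm_dataset(self):
        patients = [(f"E{i}", "2000-01-01", "female") for i in range(8)] + \
                   [(f"C{i}", "2000-01-01", "male") for i in range(8)]
        events = [(f"E{i}", "diagnosis", "ICD-10", "I101", "2020-06-01") for i in range(8)]
        events += [(f"C{i}", "diagnosis", "ICD-10", "I109", "2020-06-01") for i in range(4)]
        events += [("E0", "diagnosis", "ICD-10", "J90", "2020-06-01")]
        return make_dataset(patients=patients, events=events)

    def exposed(self):
        return cohort_of("exposed", [(f"E{i}", "2020-01-01") for i in range(8)])

    def comparator(self):
        return cohort_of("comparator", [(f"C{i}", "2020-01-01") for i in range(8)])

    def test_constructed_rr_2(self):
        out = relative_risk_scan(self.make_two_arm_dataset(), self.exposed(),
                                 self.comparator(), exclude_prefixes=["J90"])
        by_code = {e.code: e for e in out}
        assert by_code["I10"].rr == pytest.approx(2.0)  # 8/8 vs 4/8, 3-char category

    def test_defining_code_excluded(self):
        out = relative_risk_scan(self.make_two_arm_dataset(), self.exposed(),
                                 self.comparator(), exclude_prefixes=["J90"])
        assert all(e.code != "J90" for e in out)

    def test_overlapping_cohorts_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            relative_risk_scan(self.make_two_arm_dataset(), self.exposed(), self.exposed())

    def test_row_order_invariance(self):
        ds = self.make_two_arm_dataset()
        shuffled = ds.copy()
        shuffled.events["diagnosis"] = shuffled.events["diagnosis"].sample(
            frac=1.0, random_state=5
        ).reset_index(drop=True)
        a = relative_risk_scan(ds, self.exposed(), self.comparator())
        b = relative_risk_scan(shuffled, self.exposed(), self.comparator())
        assert [e.to_dict() for e in a] == [e.to_dict() for e in b]

    def test_scenario_estimate_covers_truth(self):
        """effusion_rr scenario: I10 at 0.30 vs 0.10 -> true RR 3."""
        dataset, truth = simulate_dataset(make_example_scenario("effusion_rr", n_patients=1600))
        eff = evaluate_cohort(dataset, example_definition("pleural_effusion"))
        oth = evaluate_cohort(dataset, example_definition("effusion_others"))
        out = relative_risk_scan(dataset, eff, oth, exclude_prefixes=["J90"], top_k=None)
        i10 = next(e for e in out if e.code == "I10")
        assert i10.ci_low <= 3.0 <= i10.ci_high


class TestKruskalWallis:
    def test_worked_example(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert res.H == pytest.approx(27 / 7)
        assert res.df == 1

    def test_identical_groups_H_zero(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert res.H == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(size=20), rng.normal(1, 1, size=15), rng.normal(size=10)]
        res1 = kruskal_wallis(groups)
        res2 = kruskal_wallis([np.exp(g) for g in groups])
        assert res1.H == pytest.approx(res2.H, abs=1e-12)

    def test_agrees_with_reference_implementation(self):
        """100 random small datasets with ties vs scipy.stats.kruskal."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            k = int(rng.integers(2, 5))
            groups = [rng.integers(0, 8, size=int(rng.integers(2, 15))).astype(float)
                      for _ in range(k)]
            if all(np.all(g == groups[0][0]) for g in groups):
                continue
            mine = kruskal_wallis(groups)
            ref_H, ref_p = stats.kruskal(*groups)
            assert mine.H == pytest.approx(ref_H, abs=1e-10)
            assert mine.p == pytest.approx(ref_p, abs=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])


class TestAgeComparison:
    def test_degenerate_cohort_peaks_at_common_age(self):
        ds = make_dataset(
            patients=[(f"P{i}", "2019-01-01", "female") for i in range(6)],
            events=[],
        )
        cohort = cohort_of("one", [(f"P{i}", "2020-01-01") for i in range(6)])
        cmp = age_at_entry_comparison(ds, [cohort, cohort_of("one2", [("P0", "2020-01-01")])])
        med = cmp.summaries.data.set_index("cohort").loc["one", "median_age"]
        assert med == pytest.approx(1.0, abs=0.01)

    def test_bimodal_mixture_recovers_both_modes(self):
        dataset, _ = simulate_dataset(make_example_scenario("effusion_rr", n_patients=4000))
        oth = evaluate_cohort(dataset, example_definition("effusion_others"))
        # bandwidth factor giving ~0.5-year kernel width: modes 14 years
        # apart need that resolution; the default normal-reference rule
        # over-smooths a wide bimodal mixture
        cmp = age_at_entry_comparison(dataset, [oth], bandwidth=0.07)
        dens = cmp.densities["Others"]
        grid = cmp.density_grid
        # local maxima of the fitted density
        peaks = grid[1:-1][(dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])]
        assert any(abs(p - 1.0) < 0.5 for p in peaks), peaks
        assert any(abs(p - 15.0) < 0.5 for p in peaks), peaks

    def test_null_kw_p_uniform(self):
        """Two cohorts from one age law: KW p-values ~ U(0,1) over replicates."""
        rng = np.random.default_rng(6)
        pvals = [kruskal_wallis([rng.normal(size=500), rng.normal(size=500)]).p
                 for _ in range(200)]
        stat, p = stats.kstest(pvals, "uniform")
        assert p > 0.01
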