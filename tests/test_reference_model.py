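"""Penalized-likelihood reference-model fitting, centiles and consults."""

import json

import numpy as np
import pytest

from clintel.cohort import Cohort, evaluate_cohort, example_definition
from clintel.refmodel import (
    ReferenceModel,
    SmoothSpec,
    consult,
    fit_reference_model,
    predict_centiles,
    zscore,
)
from clintel.shash import sample_shash
from clintel.synthetic import make_example_scenario, simulate_dataset

FIXED = SmoothSpec(lambda_mu=100.0, lambda_sigma=100.0)


def shash_training_data(n=500, seed=42):
    """Draws from SHASH(mu = 50 + 10 t, sigma = 5, nu = 0.5, tau = 1)."""
    rng = np.random.default_rng(seed)
    t = rng.uniform(0.0, 2.0, n)
    y = np.array([sample_shash(50 + 10 * ti, 5.0, 0.5, 1.0, 1, rng)[0] for ti in t])
    return t, y


class TestFitting:
    def test_constant_data_logistic_location_is_constant(self):
        t = np.linspace(0, 10, 80)
        y = np.full_like(t, 42.0)
        model = fit_reference_model(t, y, "Logistic", FIXED)
        mu = model.params_at(np.linspace(0, 10, 25))["mu"]
        assert np.max(np.abs(mu - 42.0)) < 1e-6

    def test_shash_parameter_recovery(self):
        t, y = shash_training_data()
        model = fit_reference_model(t, y, "SHASH")
        grid = np.linspace(t.min(), t.max(), 50)
        fitted_median = model.quantile(0.5, grid)
        true_median = 50 + 10 * grid + 5 * np.sinh(0.5)  # SHASH median
        rmse = float(np.sqrt(np.mean((fitted_median - true_median) ** 2)))
        assert rmse <= 1.0
        assert abs(model.nu - 0.5) <= 0.25

    def test_too_few_observations_for_shash_refused(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="Logistic"):
            fit_reference_model(rng.uniform(0, 1, 10), rng.normal(size=10), "SHASH")

    def test_fewer_observations_than_basis_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="basis"):
            fit_reference_model(rng.uniform(0, 1, 12), rng.normal(size=12), "Logistic",
                                SmoothSpec(n_basis=20, lambda_mu=10, lambda_sigma=10))

    def test_fit_invariant_to_observation_order(self):
        t, y = shash_training_data(n=200, seed=3)
        m1 = fit_reference_model(t, y, "Logistic", FIXED)
        perm = np.random.default_rng(1).permutation(len(t))
        m2 = fit_reference_model(t[perm], y[perm], "Logistic", FIXED)
        assert np.allclose(m1.beta_mu, m2.beta_mu)
        assert np.allclose(m1.beta_sigma, m2.beta_sigma)

    def test_fit_deterministic(self):
        t, y = shash_training_data(n=200, seed=3)
        m1 = fit_reference_model(t, y, "SHASH", FIXED)
        m2 = fit_reference_model(t, y, "SHASH", FIXED)
        assert m1.to_json() == m2.to_json()

    def test_json_round_trip(self):
        t, y = shash_training_data(n=200, seed=3)
        model = fit_reference_model(t, y, "SHASH", FIXED)
        back = ReferenceModel.from_json(model.to_json())
        grid = [0.2, 1.0, 1.8]
        assert np.allclose(back.quantile(0.5, grid), model.quantile(0.5, grid))
        assert back.diagnostics == model.diagnostics


@pytest.fixture(scope="module")
def model():
    t, y = shash_training_data()
    return fit_reference_model(t, y, "SHASH")


@pytest.fixture(scope="module")
def scenario():
    dataset, truth = simulate_dataset(
        make_example_scenario("transplant_consult", n_patients=40)
    )
    cohort = evaluate_cohort(dataset, example_definition("transplant_success"))
    patient = Cohort("Patient of Interest", cohort.members.iloc[[0]].reset_index(drop=True))
    comparator = Cohort("Transplant Success", cohort.members.iloc[1:].reset_index(drop=True))
    return dataset, patient, comparator


class TestCentiles:
    def test_curves_do_not_cross(self, model):
        curves = predict_centiles(model, np.linspace(0, 2, 40), (0.25, 0.5, 0.75))
        assert (curves["c0.25"] < curves["c0.5"]).all()
        assert (curves["c0.5"] < curves["c0.75"]).all()

    def test_symmetric_family_median_equals_location(self):
        t = np.linspace(0, 5, 120)
        y = np.sin(t) + np.random.default_rng(2).normal(0, 0.1, 120)
        m = fit_reference_model(t, y, "Logistic", FIXED)
        grid = np.linspace(0, 5, 30)
        assert np.allclose(m.quantile(0.5, grid), m.params_at(grid)["mu"], atol=1e-10)

    def test_empirical_calibration_of_75th_centile(self, model):
        t, y = shash_training_data()
        c75 = model.quantile(0.75, t)
        coverage = float(np.mean(y < c75))
        assert abs(coverage - 0.75) <= 0.04

    def test_extrapolation_flagged(self, model):
        curves = predict_centiles(model, [-1.0, 1.0, 5.0], (0.5,))
        assert list(curves["extrapolated"]) == [True, False, True]

    def test_invalid_centile_rejected(self, model):
        with pytest.raises(ValueError):
            predict_centiles(model, [1.0], (1.2,))


class TestZScore:
    def test_median_value_scores_zero(self, model):
        med = float(model.quantile(0.5, [1.0])[0])
        zs = zscore(model, 1.0, med)
        assert zs.z == pytest.approx(0.0, abs=1e-8)
        assert zs.centile == pytest.approx(0.5, abs=1e-9)

    def test_75th_centile_value_scores_0674(self, model):
        v = float(model.quantile(0.75, [1.0])[0])
        zs = zscore(model, 1.0, v)
        assert zs.centile == pytest.approx(0.75, abs=1e-9)
        assert zs.z == pytest.approx(0.6744897502, abs=1e-6)

    def test_patient_on_90th_centile_scores_near_90(self):
        """Trajectory generated at the 90th centile of the generating law,
        scored against a model fitted to 1000 reference draws."""
        rng = np.random.default_rng(11)
        t = rng.uniform(0.0, 2.0, 1000)
        y = np.array([sample_shash(50 + 10 * ti, 5.0, 0.5, 1.0, 1, rng)[0] for ti in t])
        model = fit_reference_model(t, y, "SHASH")
        from clintel.shash import ShashParams, shash_quantile

        times = np.linspace(0.1, 1.9, 25)
        values = [shash_quantile(0.9, ShashParams(50 + 10 * ti, 5.0, 0.5, 1.0))
                  for ti in times]
        centiles = [zscore(model, ti, v).centile for ti, v in zip(times, values)]
        assert 0.85 <= float(np.median(centiles)) <= 0.95


class TestConsult:
    def test_end_to_end_consult_smoke(self, scenario):
        dataset, patient, comparator = scenario
        report = consult(dataset, patient, comparator, "CREAT", smooth=FIXED)
        assert len(report.patient_scores) > 0
        assert np.isfinite(report.patient_scores["z"]).all()
        assert report.reference.family == "SHASH"
        assert report.patient_model is None or report.patient_model.family == "Logistic"
        parsed = json.loads(report.to_json())
        assert parsed["observation_code"] == "CREAT"

    def test_window_excludes_out_of_range_observations(self, scenario):
        dataset, patient, comparator = scenario
        report = consult(dataset, patient, comparator, "CREAT",
                         smooth=FIXED, window=(7.0, 730.0))
        assert (report.patient_scores["time"] >= 7.0).all()
        assert (report.patient_scores["time"] <= 730.0).all()

    def test_patient_without_observations_is_informative_error(self, scenario):
        dataset, patient, comparator = scenario
        with pytest.raises(ValueError, match="no CREAT observations"):
            consult(dataset, patient, comparator, "CREAT",
                    smooth=FIXED, window=(10000.0, 10001.0))

    def test_multi_member_patient_cohort_rejected(self, scenario):
        dataset, patient, comparator = scenario
        with pytest.raises(ValueError, match="exactly 1"):
            consult(dataset, comparator, comparator, "CREAT", smooth=FIXED)
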