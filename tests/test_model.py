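"""Unit and property tests for the turnover model and MAP estimation."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from biliforecast import (
    BilirubinMeasurement,
    Covariates,
    HorizonError,
    PopulationModel,
    estimate_eta_map,
    fit_population_two_stage,
    individual_parameters,
    predict_bilirubin,
    trajectory,
)
from biliforecast.model import map_objective


def tsb(pna, value):
    return BilirubinMeasurement(pna=pna, value=value, method="TSB")


class TestIndividualParameters:
    def test_identity_at_prior_mode_and_reference_covariates(self, pop, ref_cov):
        params = individual_parameters(pop, ref_cov, (0.0, 0.0))
        assert params["k_in0"] == pytest.approx(pop.k_in0)
        assert params["t50"] == pytest.approx(pop.t50)
        assert params["k_out_max"] == pytest.approx(pop.k_out_max)
        assert params["lambda_prod"] == pop.lambda_prod
        assert params["b0"] == pop.b0

    def test_log_scale_eta_doubles_its_parameter_only(self, pop, ref_cov):
        base = individual_parameters(pop, ref_cov, (0.0, 0.0))
        bumped = individual_parameters(pop, ref_cov, (math.log(2), 0.0))
        assert bumped["k_in0"] == pytest.approx(2 * base["k_in0"])
        assert bumped["t50"] == pytest.approx(base["t50"])
        bumped = individual_parameters(pop, ref_cov, (0.0, math.log(2)))
        assert bumped["t50"] == pytest.approx(2 * base["t50"])
        assert bumped["k_in0"] == pytest.approx(base["k_in0"])

    def test_hemolysis_raises_production(self, pop):
        kw = dict(gestational_age=38.7, birth_weight=3500.0)
        healthy = individual_parameters(pop, Covariates(hemolytic=False, **kw), (0, 0))
        hemo = individual_parameters(pop, Covariates(hemolytic=True, **kw), (0, 0))
        assert hemo["k_in0"] > healthy["k_in0"]
        assert hemo["t50"] == pytest.approx(healthy["t50"])

    def test_lower_ga_slows_elimination_maturation(self, pop):
        term = individual_parameters(
            pop, Covariates(gestational_age=40.0, birth_weight=3500.0), (0, 0))
        preterm = individual_parameters(
            pop, Covariates(gestational_age=34.5, birth_weight=3500.0), (0, 0))
        assert preterm["t50"] > term["t50"]

    def test_all_outputs_strictly_positive(self, pop):
        cov = Covariates(gestational_age=34.0, birth_weight=1500.0,
                         delivery_mode="cesarean", hemolytic=True)
        params = individual_parameters(pop, cov, (-3.0, 3.0))
        assert all(v > 0 for v in params.values())

    def test_eta_dimension_mismatch_rejected(self, pop, ref_cov):
        with pytest.raises(ValueError):
            individual_parameters(pop, ref_cov, (0.0,))


class TestTrajectory:
    def test_constant_elimination_closed_form(self, ref_cov):
        # lambda_prod → 0 and t50 → 0 make the ODE autonomous with
        # B(t) = kin/kout + (B0 − kin/kout)·exp(−kout·t).
        pop = PopulationModel(lambda_prod=1e-12, t50=1e-9, k_in0=4.0, k_out_max=0.03)
        t = np.linspace(0.0, 120.0, 25)
        # fine grid: the maturation step function at t≈0 costs half a cell
        num = trajectory(pop, ref_cov, (0.0, 0.0), t, dt=0.005)
        ss = pop.k_in0 / pop.k_out_max
        exact = ss + (pop.b0 - ss) * np.exp(-pop.k_out_max * t)
        np.testing.assert_allclose(num, exact, rtol=1e-4)

    def test_default_trajectory_peaks_in_clinical_window(self, pop, ref_cov):
        t = np.linspace(0.0, 168.0, 1681)
        B = trajectory(pop, ref_cov, (0.0, 0.0), t)
        i = int(np.argmax(B))
        assert 0 < i < len(t) - 1, "peak must be interior"
        assert 48.0 <= t[i] <= 120.0
        assert B[i] > B[0] and B[i] > B[-1]

    def test_vanishing_production_gives_decreasing_course(self, ref_cov):
        pop = PopulationModel(k_in0=1e-9)
        B = trajectory(pop, ref_cov, (0.0, 0.0), np.linspace(1.0, 168.0, 100))
        assert np.all(np.diff(B) < 0)

    def test_grid_refinement_consistency(self, pop, ref_cov):
        t = np.linspace(0.0, 168.0, 57)
        coarse = trajectory(pop, ref_cov, (0.1, -0.1), t, dt=0.2)
        fine = trajectory(pop, ref_cov, (0.1, -0.1), t, dt=0.02)
        np.testing.assert_allclose(coarse, fine, rtol=2e-4, atol=1e-3)

    def test_matches_adaptive_ode_solver(self, pop, ref_cov):
        """Independent oracle: scipy's adaptive integrator on the same ODE."""
        eta = (0.15, -0.2)
        params = individual_parameters(pop, ref_cov, eta)

        def rhs(t, y):
            frac = t ** params["gamma"] / (params["t50"] ** params["gamma"] + t ** params["gamma"]) if t > 0 else 0.0
            return params["k_in0"] * math.exp(-params["lambda_prod"] * t) - params["k_out_max"] * frac * y[0]

        t = np.linspace(0.0, 168.0, 30)
        sol = solve_ivp(rhs, (0.0, 168.0), [params["b0"]], t_eval=t,
                        rtol=1e-10, atol=1e-10, method="LSODA")
        mine = trajectory(pop, ref_cov, eta, t)
        np.testing.assert_allclose(mine, sol.y[0], rtol=5e-4, atol=5e-3)

    def test_input_validation(self, pop, ref_cov):
        with pytest.raises(ValueError):
            trajectory(pop, ref_cov, (0, 0), [-1.0, 5.0])
        with pytest.raises(ValueError):
            trajectory(pop, ref_cov, (0, 0), [10.0, 5.0])
        assert trajectory(pop, ref_cov, (0, 0), []).size == 0

    def test_deterministic(self, pop, ref_cov):
        t = [10.0, 50.0, 90.0]
        a = trajectory(pop, ref_cov, (0.05, 0.05), t)
        b = trajectory(pop, ref_cov, (0.05, 0.05), t)
        np.testing.assert_array_equal(a, b)


class TestEstimateEtaMap:
    def test_empty_measurements_return_prior_mode(self, pop, ref_cov):
        est = estimate_eta_map(pop, ref_cov, [])
        assert est.eta == (0.0, 0.0)
        assert est.objective_value == 0.0
        assert est.n_measurements_used == 0

    def test_matches_dense_grid_search(self, pop, ref_cov):
        """Brute-force oracle: the optimiser must do at least as well as a
        dense grid over η, and land at (about) the same place."""
        ms = [tsb(30.0, 170.0), tsb(50.0, 230.0)]
        est = estimate_eta_map(pop, ref_cov, ms)
        grid = np.linspace(-1.0, 1.0, 81)
        vals = np.array([[map_objective(pop, ref_cov, ms, (e1, e2)) for e2 in grid]
                         for e1 in grid])
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        assert est.objective_value <= vals[i, j] + 1e-6
        assert abs(est.eta[0] - grid[i]) <= 2 * (grid[1] - grid[0])
        assert abs(est.eta[1] - grid[j]) <= 2 * (grid[1] - grid[0])

    def test_recovers_known_eta_at_low_noise(self, pop, ref_cov):
        true_eta = (0.25, -0.2)
        times = [20.0, 60.0, 110.0]
        truth = trajectory(pop, ref_cov, true_eta, times)
        low_noise = replace(pop, sigma_tsb=0.5, sigma_tcb=0.6)
        ms = [tsb(t, v) for t, v in zip(times, truth)]
        est = estimate_eta_map(low_noise, ref_cov, ms)
        assert est.eta[0] == pytest.approx(true_eta[0], abs=0.02)
        assert est.eta[1] == pytest.approx(true_eta[1], abs=0.02)

    def test_never_worse_than_prior_mode(self, pop, ref_cov):
        rng = np.random.default_rng(7)
        for _ in range(10):
            ms = [tsb(float(t), float(v)) for t, v in
                  zip(np.sort(rng.uniform(10, 110, 3)), rng.uniform(60, 320, 3))]
            est = estimate_eta_map(pop, ref_cov, ms)
            assert est.objective_value <= map_objective(pop, ref_cov, ms, (0, 0)) + 1e-12

    def test_infinite_noise_shrinks_to_prior_mode(self, pop, ref_cov):
        huge = replace(pop, sigma_tsb=1e7, sigma_tcb=1e7)
        ms = [tsb(30.0, 300.0), tsb(60.0, 60.0)]
        est = estimate_eta_map(huge, ref_cov, ms)
        assert abs(est.eta[0]) < 1e-3 and abs(est.eta[1]) < 1e-3

    def test_rejects_nonfinite_values(self, pop, ref_cov):
        bad = tsb(30.0, 100.0)
        object.__setattr__(bad, "value", float("nan"))
        with pytest.raises(ValueError):
            estimate_eta_map(pop, ref_cov, [bad])


class TestPredictBilirubin:
    def test_prior_mode_prediction_without_measurements(self, pop, ref_cov):
        expected = trajectory(pop, ref_cov, (0.0, 0.0), [80.0])[0]
        assert predict_bilirubin(pop, ref_cov, [], 80.0) == pytest.approx(expected)

    def test_interpolates_data_in_small_noise_limit(self, pop, ref_cov):
        true_eta = (0.15, -0.1)
        times = [20.0, 45.0, 70.0, 95.0]
        truth = trajectory(pop, ref_cov, true_eta, times + [110.0])
        tiny = replace(pop, sigma_tsb=0.2, sigma_tcb=0.3)
        ms = [tsb(t, v) for t, v in zip(times, truth[:-1])]
        pred = predict_bilirubin(tiny, ref_cov, ms, 110.0, horizon_limit=60.0)
        assert pred == pytest.approx(truth[-1], rel=0.01)

    def test_tsb_only_horizon_is_60h(self, pop, ref_cov):
        ms = [tsb(30.0, 160.0)]
        predict_bilirubin(pop, ref_cov, ms, 90.0)  # 60 h ahead: allowed
        with pytest.raises(HorizonError):
            predict_bilirubin(pop, ref_cov, ms, 91.0)  # 61 h ahead

    def test_tcb_input_caps_horizon_at_48h(self, pop, ref_cov):
        ms = [BilirubinMeasurement(pna=30.0, value=160.0, method="TcB")]
        predict_bilirubin(pop, ref_cov, ms, 78.0)
        with pytest.raises(HorizonError):
            predict_bilirubin(pop, ref_cov, ms, 79.0)

    def test_target_before_last_measurement_rejected(self, pop, ref_cov):
        with pytest.raises(ValueError):
            predict_bilirubin(pop, ref_cov, [tsb(50.0, 180.0)], 50.0)

    def test_bitwise_reproducible(self, pop, ref_cov):
        ms = [tsb(28.0, 150.0), tsb(47.0, 190.0)]
        a = predict_bilirubin(pop, ref_cov, ms, 90.0)
        b = predict_bilirubin(pop, ref_cov, ms, 90.0)
        assert a == b


class TestTwoStageFit:
    def test_single_patient_rejected(self, pop, ref_cov):
        ms = [tsb(t, 150.0) for t in (20.0, 40.0, 60.0, 80.0)]
        with pytest.raises(ValueError):
            fit_population_two_stage([ms], [ref_cov])

    def test_too_few_measurements_rejected(self, pop, ref_cov):
        cohorts = [[tsb(20.0, 120.0)]] * 25
        with pytest.raises(ValueError):
            fit_population_two_stage(cohorts, [ref_cov] * 25)

    def test_noise_free_zero_variability_cohort_gives_null_omega(self, pop, ref_cov):
        times = [15.0, 35.0, 55.0, 80.0, 105.0]
        truth = trajectory(pop, ref_cov, (0.0, 0.0), times)
        ms = [tsb(t, v) for t, v in zip(times, truth)]
        fitted = fit_population_two_stage([list(ms)] * 20, [ref_cov] * 20, template=pop)
        om = np.asarray(fitted.omega)
        assert np.abs(om).max() < 1e-4
        assert fitted.k_in0 == pytest.approx(pop.k_in0, rel=1e-3)
        assert fitted.t50 == pytest.approx(pop.t50, rel=1e-3)


class TestPopulationModelContracts:
    def test_flat_roundtrip(self, pop, tmp_path):
        for name in ("model.json", "model.yaml"):
            path = tmp_path / name
            pop.save(path)
            again = PopulationModel.load(path)
            assert again == pop

    def test_dict_roundtrip(self, pop):
        assert PopulationModel.from_dict(pop.to_dict()) == pop

    def test_rejects_nonpositive_fixed_effects(self):
        with pytest.raises(ValueError):
            PopulationModel(k_in0=0.0)
        with pytest.raises(ValueError):
            PopulationModel(t50=-5.0)

    def test_rejects_noise_ordering_violation(self):
        # TcB is the noisier method by definition
        with pytest.raises(ValueError):
            PopulationModel(sigma_tsb=20.0, sigma_tcb=10.0)

    def test_rejects_indefinite_omega(self):
        with pytest.raises(ValueError):
            PopulationModel(omega=((0.04, 0.2), (0.2, 0.04)))
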