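"""The combined body-mass x temperature speed model."""

import numpy as np
import pytest

from thermoallo import (AlloTPCParams, NoiseModel, StudyDesign,
                        eval_allo_tpc, fit_allo_tpc, fit_multistart,
                        generate_speed_dataset, params_from_fit,
                        predict_grid, residuals)
from thermoallo.tpc_models import (BOLTZMANN_EV, KELVIN_OFFSET, T_REF_C,
                                   eval_model)


class TestEval:
    def test_mass_doubling_ratio_is_power_of_exponent(self, carabid_truth):
        for T in (10.0, 20.0, 30.0):
            ratio = eval_allo_tpc(carabid_truth, 20.0, T) / \
                eval_allo_tpc(carabid_truth, 10.0, T)
            assert ratio == pytest.approx(2 ** carabid_truth.b, rel=1e-12)

    def test_tenfold_mass_ratio(self, carabid_truth):
        ratio = eval_allo_tpc(carabid_truth, 100.0, 20.0) / \
            eval_allo_tpc(carabid_truth, 10.0, 20.0)
        assert ratio == pytest.approx(10 ** 0.12, rel=1e-12)

    def test_closed_form_at_optimum(self, carabid_truth):
        p = carabid_truth
        got = eval_allo_tpc(p, 50.0, p.t_opt)
        boltz = np.exp(-p.e / BOLTZMANN_EV
                       * (1 / (p.t_opt + KELVIN_OFFSET)
                          - 1 / (T_REF_C + KELVIN_OFFSET)))
        expected = p.a0 * 50.0 ** p.b * boltz * (p.e_h - p.e) / p.e_h
        assert got == pytest.approx(expected, rel=1e-12)

    def test_intercept_is_speed_at_reference_temperature(self, carabid_truth):
        """For a 1 mg animal at 15 C the model returns ~a0 (the
        deactivation denominator is ~1.001 there)."""
        v = eval_allo_tpc(carabid_truth, 1.0, 15.0)
        assert v == pytest.approx(carabid_truth.a0, rel=2e-3)
        assert v < carabid_truth.a0  # denominator slightly above one

    def test_log_linear_in_log_mass_at_fixed_temperature(self, carabid_truth):
        M = np.geomspace(10.0, 303.0, 10)
        v = eval_allo_tpc(carabid_truth, M, 22.0)
        slope = np.polyfit(np.log(M), np.log(v), 1)[0]
        assert slope == pytest.approx(carabid_truth.b, abs=1e-12)

    def test_nonpositive_mass_rejected(self, carabid_truth):
        with pytest.raises(ValueError, match="mass"):
            eval_allo_tpc(carabid_truth, -5.0, 20.0)

    def test_invalid_energy_ordering_rejected(self):
        with pytest.raises(ValueError, match="E_h > E"):
            AlloTPCParams(a0=0.03, b=0.12, e=3.11, e_h=0.37, t_opt=26.33)

    def test_peak_over_temperature_at_t_opt(self, rng):
        grid = np.arange(0.0, 60.0, 0.001)
        for _ in range(5):
            p = AlloTPCParams(a0=0.03, b=0.12,
                              e=rng.uniform(0.2, 1.0),
                              e_h=rng.uniform(2.0, 6.0),
                              t_opt=rng.uniform(18.0, 32.0))
            v = eval_allo_tpc(p, 105.0, grid)
            assert abs(grid[np.argmax(v)] - p.t_opt) <= 0.0015


class TestFit:
    def test_noiseless_recovery(self, noiseless_records, carabid_truth):
        fit = fit_allo_tpc(noiseless_records, n_starts=25, seed=0)
        np.testing.assert_allclose(fit.estimates,
                                   carabid_truth.as_array(), rtol=1e-6)

    def test_single_temperature_unidentifiable(self, carabid_truth):
        data = generate_speed_dataset(
            StudyDesign(n_individuals=30, temperature_levels=(20.0,),
                        seed=0), carabid_truth, NoiseModel(sigma=0.1))
        with pytest.raises(ValueError, match="temperatures identical"):
            fit_allo_tpc(data)

    def test_single_mass_unidentifiable(self, noiseless_records):
        data = noiseless_records.copy()
        data["mass_mg"] = 100.0
        with pytest.raises(ValueError, match="masses identical"):
            fit_allo_tpc(data)

    def test_mass_free_reduction_agrees_with_pure_tpc_fit(self):
        """Fixing b = 0 collapses the model onto the Sharpe-Schoolfield
        TPC; on noiseless data both routes land on the same optimum."""
        import pandas as pd
        T = np.resize(np.linspace(8.0, 32.0, 14), 42)
        truth = np.array([0.05, 0.37, 3.11, 26.33])
        v = eval_model("pawar", truth, T)
        records = pd.DataFrame({"mass_mg": 1.0, "temperature_C": T,
                                "speed_m_s": v})
        allo = fit_allo_tpc(records, n_starts=25, seed=0, fix_b=0.0)
        pure = fit_multistart("pawar", T, v, n_starts=25, seed=0)
        np.testing.assert_allclose(allo.estimates, pure.estimates,
                                   rtol=1e-8, atol=1e-12)

    def test_missing_speeds_dropped(self, noiseless_records):
        data = noiseless_records.copy()
        data.loc[data.index[:5], "speed_m_s"] = np.nan
        fit = fit_allo_tpc(data, n_starts=15, seed=0)
        assert fit.n_obs == len(data) - 5

    def test_recovery_under_study_noise(self, carabid_truth):
        """Median estimates across replicates at generous sample size stay
        near the generating values (a scaled-down calibration check)."""
        from thermoallo import validation
        df = validation.parameter_recovery(
            range(200, 230), truth=carabid_truth, n_individuals=400,
            n_starts=15)
        med = df[["a0", "b", "e", "e_h", "t_opt"]].median()
        truth = carabid_truth
        assert abs(med["a0"] - truth.a0) / truth.a0 < 0.10
        assert abs(med["b"] - truth.b) / truth.b < 0.10
        assert abs(med["e"] - truth.e) / truth.e < 0.10
        assert abs(med["e_h"] - truth.e_h) / truth.e_h < 0.25
        assert abs(med["t_opt"] - truth.t_opt) / truth.t_opt < 0.10


class TestPredictGrid:
    def test_cells_equal_pointwise_evaluation(self, carabid_truth):
        grid = predict_grid(carabid_truth, [10.0, 105.0, 303.0],
                            np.linspace(8, 32, 20))
        for i, m in enumerate(grid.masses):
            for j, t in enumerate(grid.temperatures):
                assert grid.speeds[i, j] == \
                    pytest.approx(eval_allo_tpc(carabid_truth, m, t))

    def test_row_argmax_at_temperature_nearest_optimum(self, carabid_truth):
        temps = np.linspace(8, 32, 97)
        grid = predict_grid(carabid_truth, [10.0, 303.0], temps)
        nearest = np.argmin(np.abs(temps - carabid_truth.t_opt))
        assert np.all(np.argmax(grid.speeds, axis=1) == nearest)

    def test_speeds_increase_with_mass_for_positive_exponent(
            self, carabid_truth):
        grid = predict_grid(carabid_truth, np.geomspace(10, 303, 8),
                            [12.0, 22.0, 30.0])
        assert np.all(np.diff(grid.speeds, axis=0) > 0)

    def test_extrapolation_warns(self, carabid_truth):
        with pytest.warns(UserWarning, match="temperature range"):
            predict_grid(carabid_truth, [100.0], [40.0])
        with pytest.warns(UserWarning, match="mass range"):
            predict_grid(carabid_truth, [1.0], [20.0])

    def test_long_format_round_trip(self, carabid_truth):
        grid = predict_grid(carabid_truth, [10.0, 100.0], [15.0, 25.0])
        frame = grid.to_frame()
        assert len(frame) == 4
        assert set(frame.columns) == {"mass_mg", "temperature_C",
                                      "speed_m_s"}


class TestResiduals:
    def test_noiseless_residuals_vanish(self, noiseless_records):
        fit = fit_allo_tpc(noiseless_records, n_starts=25, seed=0)
        res = residuals(fit, noiseless_records)
        assert len(res) == len(noiseless_records)
        assert np.abs(res["residual"]).max() < 1e-9

    def test_grouping_columns_carried_through(self, noisy_records):
        fit = fit_allo_tpc(noisy_records, n_starts=15, seed=0)
        res = residuals(fit, noisy_records)
        assert {"species", "habitat_group", "residual"} <= set(res.columns)

    def test_mean_residual_near_zero_for_unbiased_fit(self, noisy_records):
        fit = fit_allo_tpc(noisy_records, n_starts=15, seed=0)
        res = residuals(fit, noisy_records)["residual"]
        se_mean = res.std(ddof=1) / np.sqrt(len(res))
        assert abs(res.mean()) < 2 * se_mean

    def test_params_round_trip(self, noiseless_records, carabid_truth):
        fit = fit_allo_tpc(noiseless_records, n_starts=25, seed=0)
        p = params_from_fit(fit)
        assert p.t_opt == pytest.approx(carabid_truth.t_opt, rel=1e-6)
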