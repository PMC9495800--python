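"""Calibration: metrics, fitting machinery and the laboratory table."""

import numpy as np
import pytest

from parafuzz.calibration import (
    CalibrationPoint,
    FitTemplate,
    FreeParameter,
    default_calibration_table,
    default_template,
    fit,
    load_calibration_csv,
    metrics_dict,
    r_squared,
    rmse,
    save_calibration_csv,
)
from parafuzz.fuzzy import InferenceConfig, predict_r0_many


class TestLabTable:
    def test_six_printed_pairs(self):
        table = default_calibration_table()
        assert len(table) == 6
        pairs = {(p.temperature, p.r0_observed) for p in table}
        assert (20.0, 15.0) in pairs
        assert (35.0, 0.06) in pairs
        assert pairs == {(10.0, 0.13), (15.0, 1.55), (20.0, 15.0),
                         (25.0, 14.0), (30.0, 2.18), (35.0, 0.06)}

    def test_negative_r0_rejected(self):
        with pytest.raises(ValueError):
            CalibrationPoint(20.0, -1.0)

    def test_csv_roundtrip(self, tmp_path):
        path = tmp_path / "table.csv"
        save_calibration_csv(default_calibration_table(), path)
        assert load_calibration_csv(path) == default_calibration_table()

    def test_csv_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("temp,value\n20,15\n")
        with pytest.raises(ValueError):
            load_calibration_csv(path)


class TestMetrics:
    def test_rmse_examples(self):
        assert rmse([1, 2, 3], [1, 2, 3]) == 0.0
        assert rmse([3, -4], [0, 0]) == pytest.approx(np.sqrt(12.5))
        obs = np.array([1.0, 5.0, 9.0])
        assert rmse(obs + 0.7, obs) == pytest.approx(0.7)
        with pytest.raises(ValueError):
            rmse([1, 2], [1, 2, 3])

    def test_r_squared_examples(self):
        obs = [1.0, 2.0, 4.0]
        assert r_squared(obs, obs) == pytest.approx(1.0)
        mean_pred = [np.mean(obs)] * 3
        assert r_squared(mean_pred, obs) == pytest.approx(0.0)
        # hand computation: pred=(1,3,4), obs=(1,2,4): SS_res=1,
        # mean(obs)=7/3, SS_tot=(16+1+25)/9=14/3 -> R^2 = 1 - 3/14
        assert r_squared([1, 3, 4], [1, 2, 4]) == pytest.approx(1 - 3 / 14)
        with pytest.raises(ValueError):
            r_squared([1, 2], [3, 3])


class TestFitMachinery:
    def test_template_validates_names_and_bounds(self):
        base = default_template().base
        with pytest.raises(Exception):
            FitTemplate(base, (FreeParameter("temperature", "nope", "a", (0, 1)),))
        with pytest.raises(Exception):
            FitTemplate(base, (FreeParameter("temperature", "optimal", "e", (0, 1)),))
        with pytest.raises(Exception):
            FitTemplate(base, (FreeParameter("temperature", "optimal", "a", (5, 5)),))

    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            fit([CalibrationPoint(20, 15)], seed=0)

    def test_single_free_parameter_matches_grid_search(self):
        """1-D fit agrees with a brute-force grid oracle over the bound."""
        template = FitTemplate(
            default_template().base,
            (FreeParameter("temperature", "optimal", "a", (11.0, 19.0)),),
        )
        cfg = InferenceConfig()
        points = [CalibrationPoint(16.0, 6.0), CalibrationPoint(18.0, 11.0)]
        temps = np.array([p.temperature for p in points])
        obs = np.array([p.r0_observed for p in points])

        def objective(v):
            rb = template.build(np.array([v]))
            pred, _ = predict_r0_many(rb, cfg, temps)
            return float(np.sqrt(np.mean((pred - obs) ** 2)))

        grid = np.linspace(11.0, 19.0, 8001)
        grid_best = min(objective(v) for v in grid)
        res = fit(points, template=template, cfg=cfg, seed=3, maxiter=60,
                  popsize=8)
        assert res.rmse <= grid_best + 1e-6

    def test_deterministic_for_fixed_seed(self):
        template = FitTemplate(
            default_template().base,
            (FreeParameter("temperature", "optimal", "a", (11.0, 19.0)),
             FreeParameter("r0", "optimal_r0", "b", (10.0, 15.0))),
        )
        points = default_calibration_table()
        a = fit(points, template=template, seed=11, maxiter=40, popsize=8)
        b = fit(points, template=template, seed=11, maxiter=40, popsize=8)
        np.testing.assert_array_equal(a.theta, b.theta)
        assert a.rmse == b.rmse
        assert a.history == b.history

    def test_history_is_monotone_nonincreasing(self, calib):
        h = np.asarray(calib.history)
        assert h.size >= 2
        assert np.all(np.diff(h) <= 1e-12)

    def test_quick_parameter_recovery(self):
        """Data generated by a known system is refit essentially exactly."""
        truth_theta = np.array([17.0, 13.0])
        template = FitTemplate(
            default_template().base,
            (FreeParameter("temperature", "optimal", "a", (11.0, 19.0)),
             FreeParameter("r0", "optimal_r0", "b", (10.0, 15.0))),
        )
        cfg = InferenceConfig()
        truth = template.build(truth_theta)
        temps = np.linspace(10.5, 34.5, 25)
        obs, _ = predict_r0_many(truth, cfg, temps)
        points = [CalibrationPoint(float(t), float(r))
                  for t, r in zip(temps, obs)]
        res = fit(points, template=template, cfg=cfg, seed=5, maxiter=80,
                  popsize=10)
        assert res.rmse < 1e-6
        np.testing.assert_allclose(res.theta, truth_theta, atol=1e-3)

    def test_metrics_dict_shape(self, calib):
        d = metrics_dict(calib)
        assert d["n_points"] == 6
        assert d["rmse"] >= 0.0
        assert len(d["residuals"]) == 6
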