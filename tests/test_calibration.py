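"""Piecewise-linear sensor calibration: fitting, hysteresis averaging, errors."""

import json

import numpy as np
import pytest

from rehabband import (
    CalibrationCurve,
    CalibrationSweep,
    PiecewiseCurve,
    calibration_error,
    fit_hysteresis_pair,
    fit_piecewise,
    generate_calibration_sweep,
    predict_pressure,
)
from rehabband.calibration import LOADING, UNLOADING, read_sweeps_csv, write_sweeps_csv
from rehabband.errors import DegenerateInputError, InputError

# a 4-segment generating curve whose interior breakpoints sit away from data quantiles
KNOT_X = np.array([200.0, 700.0, 1500.0, 3200.0, 3800.0])
KNOT_Y = np.array([10.0, 40.0, 250.0, 430.0, 520.0])


def gen_curve(x):
    return np.interp(x, KNOT_X, KNOT_Y)


def test_single_line_fit_has_uniform_slope():
    ad = np.linspace(100, 1000, 300)
    sweep = CalibrationSweep(ad=ad, force=2 * ad, direction=LOADING)
    curve = fit_piecewise(sweep, n_segments=9, seed=0)
    assert curve.n_segments == 9
    np.testing.assert_allclose(curve.slopes, 2.0, atol=1e-8)
    np.testing.assert_allclose(curve.intercepts, 0.0, atol=1e-6)


def test_recovers_noise_free_piecewise_generator():
    up, _ = generate_calibration_sweep(gen_curve, gen_curve, n_points=300, seed=3)
    curve = fit_piecewise(up, n_segments=4, seed=0)
    np.testing.assert_allclose(curve.predict(up.ad), up.force, atol=1e-6)


def test_too_few_points_rejected():
    sweep = CalibrationSweep(ad=np.linspace(0, 100, 10), force=np.linspace(0, 50, 10), direction=LOADING)
    with pytest.raises(InputError):
        fit_piecewise(sweep, n_segments=9)


def test_zero_ad_range_rejected():
    sweep = CalibrationSweep(ad=np.full(30, 500.0), force=np.linspace(0, 50, 30), direction=LOADING)
    with pytest.raises(DegenerateInputError):
        fit_piecewise(sweep, n_segments=2)


def test_breakpoint_continuity():
    rng = np.random.default_rng(7)
    ad = np.linspace(100, 4000, 240)
    sweep = CalibrationSweep(ad=ad, force=np.abs(0.1 * ad + rng.normal(0, 8, ad.size)), direction=LOADING)
    curve = fit_piecewise(sweep, n_segments=5, seed=1)
    # value just left vs just right of every interior breakpoint
    for b in curve.breakpoints[1:-1]:
        left = curve.predict(b - 1e-7)
        right = curve.predict(b + 1e-7)
        assert abs(left - right) < 1e-5


def test_monotone_generator_gives_monotone_fit():
    up, _ = generate_calibration_sweep(gen_curve, gen_curve, n_points=260, seed=5)
    curve = fit_piecewise(up, n_segments=4, seed=0)
    grid = np.linspace(up.ad.min(), up.ad.max(), 500)
    assert np.all(np.diff(curve.predict(grid)) >= -1e-9)


class TestHysteresisPair:
    def test_no_hysteresis_gives_identical_members(self):
        up, down = generate_calibration_sweep(gen_curve, gen_curve, n_points=260, seed=2)
        pair = fit_hysteresis_pair(up, down, n_segments=4, seed=0)
        grid = np.linspace(300, 3700, 200)
        np.testing.assert_allclose(pair.up.predict(grid), pair.down.predict(grid), atol=1e-5)

    def test_constant_offset_loop_averages_to_midline(self):
        up_fn = gen_curve
        down_fn = lambda x: gen_curve(x) + 40.0
        up, down = generate_calibration_sweep(up_fn, down_fn, n_points=260, seed=2)
        pair = fit_hysteresis_pair(up, down, n_segments=4, seed=0)
        grid = np.linspace(300, 3700, 200)
        np.testing.assert_allclose(pair.down.predict(grid) - pair.up.predict(grid), 40.0, atol=1e-4)
        np.testing.assert_allclose(predict_pressure(pair, grid), up_fn(grid) + 20.0, atol=1e-4)

    def test_direction_mismatch_rejected(self):
        up, down = generate_calibration_sweep(gen_curve, gen_curve, n_points=260, seed=2)
        with pytest.raises(InputError):
            fit_hysteresis_pair(down, up)  # swapped roles


class TestPredictPressure:
    @staticmethod
    def _line_curve(slope, intercept):
        bx = np.array([0.0, 1000.0])
        return PiecewiseCurve(breakpoints=bx, knot_values=slope * bx + intercept, ssr=0.0)

    def test_equal_members_reproduce_member(self):
        pair = CalibrationCurve(up=self._line_curve(0.5, 10), down=self._line_curve(0.5, 10))
        assert predict_pressure(pair, 400.0) == pytest.approx(0.5 * 400 + 10)

    def test_arithmetic_mean_of_members(self):
        pair = CalibrationCurve(up=self._line_curve(0.0, 300), down=self._line_curve(0.0, 340))
        assert predict_pressure(pair, 123.0) == pytest.approx(320.0)

    def test_extrapolation_extends_terminal_segments(self):
        curve = self._line_curve(2.0, 0.0)
        assert curve.predict(-100.0) == pytest.approx(-200.0)
        assert curve.predict(2000.0) == pytest.approx(4000.0)


class TestCalibrationError:
    def test_signed_error_and_percent(self):
        rep = calibration_error(310.0, 300.0)
        assert rep.f_error == pytest.approx(10.0)
        assert rep.percent_error == pytest.approx(10 / 300)
        assert rep.percent_defined

    def test_zero_error(self):
        assert calibration_error(250.0, 250.0).f_error == 0.0

    def test_dead_zone_percent_undefined(self):
        rep = calibration_error(280.0, 0.0)
        assert rep.f_error == 280.0
        assert not rep.percent_defined
        assert np.isnan(rep.percent_error)

    def test_negative_true_force_rejected(self):
        with pytest.raises(InputError):
            calibration_error(10.0, -1.0)


def test_curve_json_roundtrip(tmp_path):
    up, down = generate_calibration_sweep(gen_curve, lambda x: gen_curve(x) + 25, n_points=260, seed=2)
    pair = fit_hysteresis_pair(up, down, n_segments=4, seed=0)
    path = tmp_path / "curve.json"
    pair.save(path)
    loaded = CalibrationCurve.load(path)
    grid = np.linspace(200, 3800, 100)
    np.testing.assert_array_equal(predict_pressure(loaded, grid), predict_pressure(pair, grid))
    # file carries the documented fields
    payload = json.loads(path.read_text())
    assert {"breakpoints", "slopes", "intercepts", "n_segments", "seed"} <= set(payload["up"])


def test_sweep_csv_roundtrip(tmp_path):
    up, down = generate_calibration_sweep(gen_curve, gen_curve, n_points=60, seed=2)
    path = tmp_path / "sweeps.csv"
    write_sweeps_csv(path, [up, down])
    sweeps = read_sweeps_csv(path)
    np.testing.assert_allclose(sweeps[LOADING].ad, up.ad, rtol=1e-12)
    np.testing.assert_allclose(sweeps[UNLOADING].force, down.force, rtol=1e-12)
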