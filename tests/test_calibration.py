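"""Calibration-model application and static-bias estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from footgait import CalibrationParams, ImuRecording, apply_calibration, estimate_static_bias
from footgait.calibration import estimate_accelerometer_calibration, invert_calibration, StaticPoseSet
from footgait.datatypes import GRAVITY, StateError, UnitsState


def _raw(acc, gyr, rate=104.0):
    n = len(acc)
    return ImuRecording(
        time=np.arange(n) / rate, acc=np.asarray(acc, float),
        gyr=np.asarray(gyr, float), rate_hz=rate,
    )


def _random_params(rng):
    return CalibrationParams(
        acc_bias=rng.normal(size=3),
        acc_misalignment=np.eye(3) + rng.normal(scale=0.05, size=(3, 3)),
        acc_scaling=np.diag(rng.uniform(0.5, 2.0, 3)) + rng.normal(scale=0.01, size=(3, 3)),
        gyr_bias=rng.normal(size=3),
        gyr_misalignment=np.eye(3) + rng.normal(scale=0.05, size=(3, 3)),
        gyr_scaling=np.diag(rng.uniform(0.5, 2.0, 3)) + rng.normal(scale=0.01, size=(3, 3)),
        clock_error=rng.uniform(0.99, 1.01),
    )


def test_bias_cancellation_gives_zero():
    params = CalibrationParams(
        acc_bias=[1.0, -2.0, 3.0], gyr_bias=[0.5, 0.5, -0.5],
        acc_scaling=np.diag([2.0, 3.0, 4.0]),
    )
    rec = _raw(np.tile(params.acc_bias, (4, 1)), np.tile(params.gyr_bias, (4, 1)))
    cal = apply_calibration(rec, params)
    np.testing.assert_allclose(cal.acc, 0.0, atol=1e-15)
    np.testing.assert_allclose(cal.gyr, 0.0, atol=1e-15)


def test_identity_params_change_only_units_state():
    rng = np.random.default_rng(1)
    rec = _raw(rng.normal(size=(5, 3)), rng.normal(size=(5, 3)))
    cal = apply_calibration(rec, CalibrationParams.identity())
    assert cal.units_state is UnitsState.CALIBRATED
    np.testing.assert_array_equal(cal.acc, rec.acc)
    np.testing.assert_array_equal(cal.gyr, rec.gyr)
    np.testing.assert_array_equal(cal.time, rec.time)


def test_matches_per_sample_matrix_oracle():
    # independent oracle: explicit per-sample loop of S @ M @ (x - b)
    rng = np.random.default_rng(2)
    params = _random_params(rng)
    rec = _raw(rng.normal(size=(100, 3)), rng.normal(size=(100, 3)))
    cal = apply_calibration(rec, params)
    for i in range(len(rec)):
        exp_acc = params.acc_scaling @ params.acc_misalignment @ (rec.acc[i] - params.acc_bias)
        exp_gyr = params.gyr_scaling @ params.gyr_misalignment @ (rec.gyr[i] - params.gyr_bias)
        np.testing.assert_allclose(cal.acc[i], exp_acc, rtol=0, atol=1e-12)
        np.testing.assert_allclose(cal.gyr[i], exp_gyr, rtol=0, atol=1e-12)
    np.testing.assert_allclose(cal.time, rec.time * params.clock_error)


def test_double_calibration_rejected():
    rec = _raw(np.zeros((3, 3)), np.zeros((3, 3)))
    cal = apply_calibration(rec, CalibrationParams.identity())
    with pytest.raises(StateError):
        apply_calibration(cal, CalibrationParams.identity())


def test_invert_calibration_is_exact_inverse():
    rng = np.random.default_rng(3)
    params = _random_params(rng)
    rec = _raw(rng.normal(size=(50, 3)), rng.normal(size=(50, 3)))
    back = invert_calibration(apply_calibration(rec, params), params)
    np.testing.assert_allclose(back.acc, rec.acc, atol=1e-10)
    np.testing.assert_allclose(back.gyr, rec.gyr, atol=1e-10)
    np.testing.assert_allclose(back.time, rec.time, atol=1e-12)


@settings(deadline=None, max_examples=25)
@given(
    w=st.floats(0.0, 1.0),
    seed=st.integers(0, 10_000),
)
def test_affine_identity_on_convex_combinations(w, seed):
    """Calibrating a convex combination equals combining calibrated outputs."""
    rng = np.random.default_rng(seed)
    params = _random_params(rng)
    a, b = rng.normal(size=(2, 3)), rng.normal(size=(2, 3))
    mix = w * a + (1 - w) * b

    def calib(x):
        return apply_calibration(_raw(x, np.zeros_like(x)), params).acc

    lhs = calib(mix)
    rhs = w * calib(a) + (1 - w) * calib(b)  # bias term is convex-combined too
    np.testing.assert_allclose(lhs, rhs, atol=1e-10)


class TestStaticBias:
    def test_recovers_injected_gyro_offset(self):
        rng = np.random.default_rng(4)
        n = 104 * 30
        offset = np.array([0.01, -0.02, 0.005])
        sigma = 0.005
        rec = ImuRecording(
            time=np.arange(n) / 104.0,
            acc=np.tile([0, 0, GRAVITY], (n, 1)) + rng.normal(0, 0.05, (n, 3)),
            gyr=offset + rng.normal(0, sigma, (n, 3)),
            rate_hz=104.0,
            units_state=UnitsState.CALIBRATED,
        )
        bias, acc_mean = estimate_static_bias(rec, window=30.0)
        np.testing.assert_allclose(bias, offset, atol=3 * sigma / np.sqrt(n))
        assert np.linalg.norm(acc_mean) == pytest.approx(GRAVITY, abs=0.01)

    def test_zero_signals_give_zero_bias(self):
        rec = ImuRecording(
            time=np.arange(100) / 104.0, acc=np.zeros((100, 3)),
            gyr=np.zeros((100, 3)), rate_hz=104.0, units_state=UnitsState.CALIBRATED,
        )
        bias, _ = estimate_static_bias(rec, window=0.5)
        np.testing.assert_array_equal(bias, 0.0)

    def test_motion_in_window_shortens_with_warning(self):
        n = 104 * 4
        gyr = np.zeros((n, 3))
        gyr[n // 2:, 0] = 2.0  # walking starts mid-window
        rec = ImuRecording(
            time=np.arange(n) / 104.0, acc=np.tile([0, 0, GRAVITY], (n, 1)),
            gyr=gyr, rate_hz=104.0, units_state=UnitsState.CALIBRATED,
        )
        with pytest.warns(UserWarning, match="shortening"):
            bias, _ = estimate_static_bias(rec, window=4.0)
        np.testing.assert_allclose(bias, 0.0, atol=1e-12)


def test_accelerometer_scale_fit_from_poses():
    # synthetic poses: diag-scale + bias corrupted gravity vectors
    rng = np.random.default_rng(5)
    true_scale = np.array([1.02, 0.98, 1.05])
    true_bias = np.array([0.3, -0.2, 0.1])
    dirs = rng.normal(size=(15, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    measured = GRAVITY * dirs / true_scale + true_bias
    poses = StaticPoseSet(
        segments=[(i, i + 4.0) for i in range(15)],
        acc_means=measured, gyr_means=np.zeros((15, 3)),
    )
    scale, bias = estimate_accelerometer_calibration(poses)
    np.testing.assert_allclose(scale, true_scale, rtol=1e-6)
    np.testing.assert_allclose(bias, true_bias, atol=1e-5)
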