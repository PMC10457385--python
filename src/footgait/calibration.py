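"""Application (and reduced estimation) of the sensor calibration model.

The calibration model per sensor is

    calibrated = Scaling @ Misalignment @ (raw - bias)

applied per sample, with the time axis rescaled by the clock factor
(t_true = t_nominal * clock_error). The scaling matrix carries the unit
conversion to SI (m/s^2 for the accelerometer, rad/s for the gyroscope).

Full multi-position parameter estimation is a separate, involved procedure
(static captures in ~20 orientations inside a polyhedral jig); only a reduced
form is provided here: gyroscope bias from a static window and a diagonal
accelerometer scale/bias fit from gravity-norm residuals over static poses.
It is flagged experimental.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
import numpy as np
from scipy.optimize import least_squares

from .datatypes import GRAVITY, CalibrationParams, ImuRecording, StateError, UnitsState


@dataclass
class StaticPoseSet:
    """Mean sensor readings over intervals flagged static.

    ``segments`` are (start, end) times in seconds; ``acc_means`` /
    ``gyr_means`` are the per-segment mean 3-vectors. The intended capture
    protocol is one long initial static period followed by short holds in
    many distinct orientations.
    """

    segments: list[tuple[float, float]]
    acc_means: np.ndarray  # (k, 3)
    gyr_means: np.ndarray  # (k, 3)


def apply_calibration(raw: ImuRecording, params: CalibrationParams) -> ImuRecording:
    """Convert a raw recording to SI units using calibration parameters.

    Returns a new recording with ``units_state='calibrated'``, acceleration in
    m/s^2, angular rate in rad/s, and the time axis multiplied by the clock
    factor.
    """
    if raw.units_state is not UnitsState.RAW:
        raise StateError("recording is already calibrated")
    acc_mat = params.acc_scaling @ params.acc_misalignment
    gyr_mat = params.gyr_scaling @ params.gyr_misalignment
    acc = (raw.acc - params.acc_bias) @ acc_mat.T
    gyr = (raw.gyr - params.gyr_bias) @ gyr_mat.T
    return replace(
        raw,
        time=raw.time * params.clock_error,
        acc=acc,
        gyr=gyr,
        units_state=UnitsState.CALIBRATED,
    )


def invert_calibration(cal: ImuRecording, params: CalibrationParams) -> ImuRecording:
    """Map a calibrated recording back to raw counts (exact algebraic inverse)."""
    if cal.units_state is not UnitsState.CALIBRATED:
        raise StateError("recording is not calibrated")
    acc_inv = np.linalg.inv(params.acc_scaling @ params.acc_misalignment)
    gyr_inv = np.linalg.inv(params.gyr_scaling @ params.gyr_misalignment)
    acc = cal.acc @ acc_inv.T + params.acc_bias
    gyr = cal.gyr @ gyr_inv.T + params.gyr_bias
    return replace(
        cal,
        time=cal.time / params.clock_error,
        acc=acc,
        gyr=gyr,
        units_state=UnitsState.RAW,
    )


def estimate_static_bias(
    recording: ImuRecording,
    window: float = 30.0,
    still_threshold: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate gyro bias and mean gravity direction from an initial standstill.

    Parameters
    ----------
    recording : calibrated recording beginning with a standstill.
    window : length of the initial window, seconds (the acquisition protocol
        prescribes a ~30 s initial standstill).
    still_threshold : rad/s; if the bias-free angular-rate magnitude exceeds
        this inside the window, the window is shortened to the last quiet
        sample and a warning is issued.

    Returns
    -------
    (gyr_bias, acc_mean) : mean angular rate (the gyroscope bias, rad/s) and
        mean specific force (the gravity direction in the sensor frame, m/s^2)
        over the window.
    """
    t0 = recording.time[0]
    mask = recording.time - t0 <= window
    n = int(mask.sum())
    if n == 0:
        raise ValueError("recording shorter than the requested static window")
    gyr = recording.gyr[:n]
    # center on the start of the window so later motion cannot mask itself
    center = np.median(gyr[: max(10, n // 10)], axis=0)
    mag = np.linalg.norm(gyr - center, axis=1)
    moving = np.flatnonzero(mag > still_threshold)
    if moving.size:
        n_new = int(moving[0])
        if n_new < max(2, n // 10):
            raise ValueError("no usable still interval at recording start")
        warnings.warn(
            f"motion detected {recording.time[moving[0]] - t0:.2f}s into the "
            f"static window; shortening window to {n_new} samples",
            stacklevel=2,
        )
        n = n_new
    return recording.gyr[:n].mean(axis=0), recording.acc[:n].mean(axis=0)


def estimate_accelerometer_calibration(
    poses: StaticPoseSet, g: float = GRAVITY
) -> tuple[np.ndarray, np.ndarray]:
    """Experimental: diagonal scale + bias fit from static-pose gravity norms.

    Solves ``min sum_k (|| diag(s) (a_k - b) || - g)^2`` over the pose means
    a_k. Needs poses spanning enough orientations (>= 9 recommended) to be
    well conditioned.

    Returns (scale_diagonal, bias). Misalignment is not estimated.
    """
    a = np.asarray(poses.acc_means, dtype=float)
    if a.shape[0] < 6:
        raise ValueError("need at least 6 static poses to fit scale and bias")

    def resid(x: np.ndarray) -> np.ndarray:
        s, b = x[:3], x[3:]
        return np.linalg.norm((a - b) * s, axis=1) - g

    norm0 = np.linalg.norm(a, axis=1).mean()
    x0 = np.concatenate([np.full(3, g / norm0), np.zeros(3)])
    sol = least_squares(resid, x0)
    return sol.x[:3], sol.x[3:]
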