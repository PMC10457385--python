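"""Sensor-to-global orientation via a Mahony complementary filter.

The filter integrates the gyroscope with a quaternion exponential update and
corrects drift toward the accelerometer's gravity direction with proportional
and integral feedback. Because the accelerometer observes gravity only when
the foot is quasi-static, the correction is gated on the specific-force norm:
feedback is applied only while ``| ||a|| - g | < acc_gate`` (during stance and
standstill), and the filter runs on the gyroscope alone during swing.

Pitch is the sagittal-plane inclination of the sensor: the elevation of the
sensor's forward (Y) axis above the horizontal plane of the global frame,
positive toe-up. With the device on the instep, heel-strike occurs near the
pitch maximum and toe-off near the pitch minimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.spatial.transform import Rotation

from .datatypes import GRAVITY, ImuRecording, StateError, UnitsState


class MahonyGains(NamedTuple):
    """Proportional / integral feedback gains of the complementary filter."""

    kp: float = 0.5
    ki: float = 0.01


@dataclass
class OrientationSeries:
    """Per-sample sensor-to-global rotation and derived pitch angle.

    Attributes
    ----------
    R : (n, 3, 3) rotation matrices, sensor -> global.
    pitch : (n,) pitch in degrees, in [-90, 90], positive toe-up.
    quat : (n, 4) unit quaternions in scalar-last (x, y, z, w) order.
    """

    R: np.ndarray
    pitch: np.ndarray
    quat: np.ndarray

    def __len__(self) -> int:
        return int(self.pitch.shape[0])


def pitch_from_rotation(R: np.ndarray) -> np.ndarray:
    """Pitch (degrees) from rotation matrices: elevation of the forward axis.

    The global Z-component of the rotated sensor Y axis is ``R[..., 2, 1]``;
    its arcsine is the sagittal inclination.
    """
    return np.degrees(np.arcsin(np.clip(np.asarray(R)[..., 2, 1], -1.0, 1.0)))


def alignment_from_gravity(acc_mean: np.ndarray) -> np.ndarray:
    """Initial sensor-to-global rotation from a static accelerometer mean.

    Returns the minimal (yaw-free) rotation taking the measured gravity
    direction to the global vertical. Yaw is unobservable without a
    magnetometer and is set to zero.
    """
    v = np.asarray(acc_mean, dtype=float)
    nv = np.linalg.norm(v)
    if nv == 0:
        raise ValueError("zero accelerometer mean; cannot align to gravity")
    v = v / nv
    e3 = np.array([0.0, 0.0, 1.0])
    axis = np.cross(v, e3)
    s = np.linalg.norm(axis)
    c = float(v @ e3)
    if s < 1e-12:
        return np.eye(3) if c > 0 else Rotation.from_rotvec([np.pi, 0, 0]).as_matrix()
    angle = np.arctan2(s, c)
    return Rotation.from_rotvec(axis / s * angle).as_matrix()


def _quat_mult(q: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Hamilton product, scalar-first (w, x, y, z)."""
    w0, x0, y0, z0 = q
    w1, x1, y1, z1 = r
    return np.array(
        [
            w0 * w1 - x0 * x1 - y0 * y1 - z0 * z1,
            w0 * x1 + x0 * w1 + y0 * z1 - z0 * y1,
            w0 * y1 - x0 * z1 + y0 * w1 + z0 * x1,
            w0 * z1 + x0 * y1 - y0 * x1 + z0 * w1,
        ]
    )


def mahony_filter(
    rec: ImuRecording,
    gains: MahonyGains = MahonyGains(),
    R0: np.ndarray | None = None,
    acc_gate: float = 0.5,
    g: float = GRAVITY,
) -> OrientationSeries:
    """Run the Mahony complementary filter over a calibrated recording.

    Parameters
    ----------
    rec : calibrated recording (rad/s, m/s^2).
    gains : proportional/integral gains. ``kp = ki = 0`` integrates the
        gyroscope only.
    R0 : initial sensor-to-global rotation. Default: gravity alignment from
        the first accelerometer sample (use a standstill mean for a clean
        start, see :func:`alignment_from_gravity`).
    acc_gate : m/s^2; accelerometer feedback is applied only when the
        specific-force norm is within this distance of g. Set to ``inf`` to
        disable gating.
    """
    if rec.units_state is not UnitsState.CALIBRATED:
        raise StateError("mahony_filter requires a calibrated recording")
    bad = ~(np.isfinite(rec.acc).all(axis=1) & np.isfinite(rec.gyr).all(axis=1))
    if bad.any():
        raise ValueError(f"NaN/inf sample at index {int(np.flatnonzero(bad)[0])}")

    n = len(rec)
    if R0 is None:
        R0 = alignment_from_gravity(rec.acc[0])
    # scalar-first quaternion of R0 (sensor -> global)
    q_xyzw = Rotation.from_matrix(R0).as_quat()
    q = np.array([q_xyzw[3], q_xyzw[0], q_xyzw[1], q_xyzw[2]])

    quats = np.empty((n, 4))
    quats[0] = q
    integral = np.zeros(3)
    kp, ki = gains

    for i in range(1, n):
        dt = rec.time[i] - rec.time[i - 1]
        acc = rec.acc[i - 1]
        na = np.linalg.norm(acc)
        if na > 0 and abs(na - g) < acc_gate and (kp > 0 or ki > 0):
            # gravity direction error: measured up-vector vs estimated one
            w, x, y, z = q
            v = np.array(  # R^T e3
                [2 * (x * z - w * y), 2 * (y * z + w * x), w * w - x * x - y * y + z * z]
            )
            err = np.cross(acc / na, v)
            integral += ki * err * dt
        else:
            err = np.zeros(3)
        # trapezoidal gyro midpoint: exact for constant rate, O(dt^2) otherwise
        omega = 0.5 * (rec.gyr[i - 1] + rec.gyr[i]) + kp * err + integral
        theta = np.linalg.norm(omega) * dt
        if theta > 0:
            half = 0.5 * theta
            dq = np.empty(4)
            dq[0] = np.cos(half)
            dq[1:] = omega / np.linalg.norm(omega) * np.sin(half)
            q = _quat_mult(q, dq)
            q /= np.linalg.norm(q)
        quats[i] = q

    quat_xyzw = np.column_stack([quats[:, 1], quats[:, 2], quats[:, 3], quats[:, 0]])
    R = Rotation.from_quat(quat_xyzw).as_matrix()
    return OrientationSeries(R=R, pitch=pitch_from_rotation(R), quat=quat_xyzw)


def remove_gravity(
    rec: ImuRecording, orient: OrientationSeries, g: float = GRAVITY
) -> np.ndarray:
    """Rotate specific force to the global frame and subtract gravity.

    Returns the (n, 3) gravity-free linear acceleration in m/s^2:
    ``a_free = R @ a_sensor - (0, 0, g)``.
    """
    if len(rec) != len(orient):
        raise ValueError(
            f"recording length {len(rec)} != orientation length {len(orient)}"
        )
    a_global = np.einsum("nij,nj->ni", orient.R, rec.acc)
    a_global[:, 2] -= g
    return a_global
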