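"""Shared in-memory containers for IMU recordings and calibration parameters."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

#: Standard gravity, m/s^2.
GRAVITY = 9.81


class Device(str, Enum):
    """Recording hardware family.

    CSIC devices sample at 104 Hz (±2000°/s, ±16 g); Gaitup devices at 128 Hz
    (±1000°/s, ±8 g). Synthetic recordings default to CSIC conventions.
    """

    CSIC = "CSIC"
    GAITUP = "Gaitup"


class UnitsState(str, Enum):
    """Whether channel values are raw counts (a.u.) or SI (m/s^2, rad/s)."""

    RAW = "raw"
    CALIBRATED = "calibrated"


class StateError(RuntimeError):
    """Operation applied to a recording in the wrong units state."""


@dataclass
class ImuRecording:
    """Time-stamped tri-axial accelerometer + gyroscope recording.

    Axes follow the sensor convention of the foot-mounted device: X lateral,
    Y frontal (direction of progression), Z vertical when the foot is flat.
    Acceleration includes gravity (specific force).

    Attributes
    ----------
    time : (n,) float array, seconds since recording start, strictly increasing.
    acc : (n, 3) float array; a.u. when raw, m/s^2 when calibrated.
    gyr : (n, 3) float array; a.u. when raw, rad/s when calibrated.
    rate_hz : nominal sampling rate (104 CSIC / 128 Gaitup; arbitrary for
        synthetic recordings).
    device : hardware family.
    units_state : raw or calibrated.
    """

    time: np.ndarray
    acc: np.ndarray
    gyr: np.ndarray
    rate_hz: float
    device: Device = Device.CSIC
    units_state: UnitsState = UnitsState.RAW

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.acc = np.atleast_2d(np.asarray(self.acc, dtype=float))
        self.gyr = np.atleast_2d(np.asarray(self.gyr, dtype=float))
        n = self.time.shape[0]
        if self.acc.shape != (n, 3) or self.gyr.shape != (n, 3):
            raise ValueError(
                f"acc/gyr must be (n, 3) with n={n}; got {self.acc.shape} and {self.gyr.shape}"
            )
        if n > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    def __len__(self) -> int:
        return int(self.time.shape[0])

    @property
    def dt(self) -> float:
        """Mean sampling interval in seconds."""
        if len(self) < 2:
            return 1.0 / self.rate_hz
        return float((self.time[-1] - self.time[0]) / (len(self) - 1))

    def gyr_magnitude(self) -> np.ndarray:
        """Euclidean norm of the angular-rate vector per sample."""
        return np.linalg.norm(self.gyr, axis=1)

    def copy(self) -> "ImuRecording":
        return replace(
            self, time=self.time.copy(), acc=self.acc.copy(), gyr=self.gyr.copy()
        )


@dataclass
class CalibrationParams:
    """Per-sensor calibration model.

    The calibrated signal is ``Scaling @ Misalignment @ (raw - bias)`` applied
    per sample, and the time axis is rescaled by ``clock_error``
    (t_true = t_nominal * clock_error). Scaling carries the unit conversion
    (a.u. -> m/s^2 for the accelerometer, a.u. -> rad/s for the gyroscope);
    misalignment is dimensionless.
    """

    acc_bias: np.ndarray = field(default_factory=lambda: np.zeros(3))
    acc_misalignment: np.ndarray = field(default_factory=lambda: np.eye(3))
    acc_scaling: np.ndarray = field(default_factory=lambda: np.eye(3))
    gyr_bias: np.ndarray = field(default_factory=lambda: np.zeros(3))
    gyr_misalignment: np.ndarray = field(default_factory=lambda: np.eye(3))
    gyr_scaling: np.ndarray = field(default_factory=lambda: np.eye(3))
    clock_error: float = 1.0

    def __post_init__(self) -> None:
        for name in ("acc_bias", "gyr_bias"):
            v = np.asarray(getattr(self, name), dtype=float).reshape(3)
            setattr(self, name, v)
        for name in ("acc_misalignment", "acc_scaling", "gyr_misalignment", "gyr_scaling"):
            m = np.asarray(getattr(self, name), dtype=float).reshape(3, 3)
            setattr(self, name, m)
        self.clock_error = float(self.clock_error)
        if self.clock_error <= 0:
            raise ValueError("clock_error must be positive")
        for name in ("acc_scaling", "gyr_scaling"):
            if abs(np.linalg.det(getattr(self, name))) < 1e-12:
                raise ValueError(f"{name} is singular")

    @classmethod
    def identity(cls) -> "CalibrationParams":
        """Neutral parameters: zero bias, identity matrices, unit clock."""
        return cls()
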