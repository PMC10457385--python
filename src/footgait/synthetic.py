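"""Synthetic foot-mounted-IMU walking bouts with full ground truth.

The simulator builds a continuous, piecewise-analytic foot trajectory for a
straight-line walking bout and derives noise-free sensor streams from it, so
every stage of the processing chain can be validated against known truth:

* an initial standstill (default 30 s, matching the acquisition protocol),
* ``n_strides`` gait cycles, each a *moving window* (the foot advances one
  stride length with a single clearance hump while the pitch swings from a
  toe-down minimum at toe-off to a toe-up maximum at heel-strike) followed by
  a *foot-flat dwell* with the foot exactly stationary,
* a final standstill.

Kinematic profiles are compact-support polynomials: a minimum-jerk horizontal
advance, a single-hump quartic vertical profile and two overlapping pitch
bumps whose peaks define the toe-off and heel-strike instants exactly. The
rotation is pitch-only (sagittal plane), so the gyroscope sees the pitch rate
on its lateral axis and the accelerometer the tilted specific force
``R^T (a_free + g)``. White noise and constant biases are added on top;
everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .calibration import invert_calibration
from .datatypes import GRAVITY, CalibrationParams, Device, ImuRecording, UnitsState
from .io import write_calibration_params, write_raw_recording
from .segmentation import StrideEvents

# normalised positions of the gait events inside a moving window
_U_TO = 0.30  # peak of the toe-off pitch bump
_U_HS = 0.725  # peak of the heel-strike pitch bump
_TO_SUPPORT = (0.0, 0.60)
_HS_SUPPORT = (0.45, 1.0)


@dataclass
class GaitSimParams:
    """Simulator configuration.

    Defaults describe a slow, regular elderly gait recorded by a 104 Hz
    foot-mounted IMU: ~1 m strides at ~1.1 s per cycle (cadence ~55
    strides/min), 35% of the cycle spent foot-flat, 15 cm swing clearance,
    pitch swinging between -35 deg (toe-off) and +20 deg (heel-strike), and
    a 30 s initial standstill as prescribed by the recording protocol.
    """

    n_strides: int = 20
    stride_length_m: float = 1.0
    stride_length_sd: float = 0.05
    stride_time_s: float = 1.1
    stride_time_sd: float = 0.05
    foot_flat_fraction: float = 0.35
    clearance_m: float = 0.15
    pitch_hs_deg: float = 20.0  # toe-up maximum at heel-strike
    pitch_to_deg: float = 35.0  # magnitude of the toe-down minimum at toe-off
    initial_still_s: float = 30.0
    final_still_s: float = 10.0
    rate_hz: float = 104.0
    noise_acc: float = 0.05  # m/s^2, white
    noise_gyr: float = 0.005  # rad/s, white
    acc_bias: tuple[float, float, float] = (0.02, -0.03, 0.05)  # m/s^2
    gyr_bias: tuple[float, float, float] = (0.002, -0.001, 0.0015)  # rad/s
    seed: int = 0

    def validate(self) -> None:
        if self.n_strides < 0:
            raise ValueError("n_strides must be >= 0")
        if not 0 < self.foot_flat_fraction < 1:
            raise ValueError("foot_flat_fraction must be in (0, 1)")
        for name in ("stride_length_m", "stride_time_s", "rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "stride_length_sd", "stride_time_sd", "clearance_m",
            "initial_still_s", "final_still_s", "noise_acc", "noise_gyr",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def noise_free(self) -> "GaitSimParams":
        """Copy with all noise, bias and stride-to-stride variation removed."""
        import dataclasses

        return dataclasses.replace(
            self,
            stride_length_sd=0.0,
            stride_time_sd=0.0,
            noise_acc=0.0,
            noise_gyr=0.0,
            acc_bias=(0.0, 0.0, 0.0),
            gyr_bias=(0.0, 0.0, 0.0),
        )


@dataclass
class GroundTruth:
    """Everything the simulator knows about the generated bout."""

    time: np.ndarray
    pitch_deg: np.ndarray  # (n,)
    r: np.ndarray  # (n, 3) true foot position, m
    v: np.ndarray  # (n, 3) true foot velocity, m/s
    a_free: np.ndarray  # (n, 3) true gravity-free acceleration, m/s^2
    events: list[StrideEvents]  # complete strides, HS -> HS
    stride_times: np.ndarray  # per complete stride, s
    stride_lengths: np.ndarray  # m
    clearances: np.ndarray  # m
    toe_off_angles: np.ndarray  # deg
    heel_strike_angles: np.ndarray  # deg
    still_intervals: list[tuple[float, float]] = field(default_factory=list)


def _bump(u: np.ndarray, a: float, b: float) -> tuple[np.ndarray, np.ndarray]:
    """Compact-support bump on [a, b], peak 1 at the midpoint; value and du."""
    w = b - a
    qmax = (w / 2.0) ** 2
    inside = (u > a) & (u < b)
    q = np.where(inside, (u - a) * (b - u), 0.0)
    val = (q / qmax) ** 2
    dq = np.where(inside, a + b - 2.0 * u, 0.0)
    dval = 2.0 * q * dq / qmax**2
    return val, dval


def _minjerk(u: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Minimum-jerk 0->1 profile with value, first and second derivatives."""
    s = 10 * u**3 - 15 * u**4 + 6 * u**5
    ds = 30 * u**2 - 60 * u**3 + 30 * u**4
    dds = 60 * u - 180 * u**2 + 120 * u**3
    return s, ds, dds


def _hump(u: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Quartic single-hump 0->0 profile (peak 1 at u=0.5) and derivatives."""
    h = 256 * u**4 * (1 - u) ** 4
    dh = 1024 * u**3 * (1 - u) ** 3 * (1 - 2 * u)
    ddh = 1024 * u**2 * (1 - u) ** 2 * (3 * (1 - 2 * u) ** 2 - 2 * u * (1 - u))
    return h, dh, ddh


def simulate_walk(params: GaitSimParams) -> tuple[ImuRecording, GroundTruth]:
    """Generate one walking bout and its ground truth.

    Returns a calibrated-units recording (m/s^2, rad/s) with the configured
    noise and biases applied, and the noise-free :class:`GroundTruth`.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n_str = params.n_strides

    # per-stride draws (clamped away from zero)
    T = np.maximum(
        rng.normal(params.stride_time_s, params.stride_time_sd, n_str),
        0.2 * params.stride_time_s,
    )
    L = np.maximum(
        rng.normal(params.stride_length_m, params.stride_length_sd, n_str),
        0.2 * params.stride_length_m,
    )
    f = params.foot_flat_fraction
    m_dur = (1.0 - f) * T  # moving-window durations
    d_dur = f * T  # dwell durations

    # segment timeline: (kind, t0, dur, stride index)
    segments: list[tuple[str, float, float, int]] = []
    t = 0.0
    segments.append(("still", t, params.initial_still_s, -1))
    t += params.initial_still_s
    move_start = np.empty(n_str)
    for k in range(n_str):
        move_start[k] = t
        segments.append(("move", t, m_dur[k], k))
        t += m_dur[k]
        if k < n_str - 1:
            segments.append(("dwell", t, d_dur[k], k))
            t += d_dur[k]
    segments.append(("still", t, params.final_still_s, -1))
    total = t + params.final_still_s

    dt = 1.0 / params.rate_hz
    time = np.arange(0.0, total, dt)
    n = time.size

    pitch = np.zeros(n)  # rad
    pitch_rate = np.zeros(n)  # rad/s
    y = np.zeros(n)
    vy = np.zeros(n)
    ay = np.zeros(n)
    z = np.zeros(n)
    vz = np.zeros(n)
    az = np.zeros(n)

    a_to = np.radians(params.pitch_to_deg)
    a_hs = np.radians(params.pitch_hs_deg)
    y0 = 0.0
    for kind, t0, dur, k in segments:
        if kind != "move":
            if kind in ("dwell", "still"):
                mask = (time >= t0) & (time < t0 + dur)
                y[mask] = y0
            continue
        mask = (time >= t0) & (time < t0 + dur)
        u = (time[mask] - t0) / dur
        s, ds, dds = _minjerk(u)
        y[mask] = y0 + L[k] * s
        vy[mask] = L[k] / dur * ds
        ay[mask] = L[k] / dur**2 * dds
        h, dh, ddh = _hump(u)
        z[mask] = params.clearance_m * h
        vz[mask] = params.clearance_m / dur * dh
        az[mask] = params.clearance_m / dur**2 * ddh
        b1, db1 = _bump(u, *_TO_SUPPORT)
        b2, db2 = _bump(u, *_HS_SUPPORT)
        pitch[mask] = -a_to * b1 + a_hs * b2
        pitch_rate[mask] = (-a_to * db1 + a_hs * db2) / dur
        y0 = y0 + L[k]

    r = np.column_stack([np.zeros(n), y, z])
    v = np.column_stack([np.zeros(n), vy, vz])
    a_free = np.column_stack([np.zeros(n), ay, az])

    # specific force in the sensor frame: R^T (a_free + g e3), pitch-only R
    c, s_ = np.cos(pitch), np.sin(pitch)
    az_tot = az + GRAVITY
    acc_true = np.column_stack(
        [np.zeros(n), c * ay + s_ * az_tot, -s_ * ay + c * az_tot]
    )
    gyr_true = np.column_stack([pitch_rate, np.zeros(n), np.zeros(n)])

    acc = acc_true + np.asarray(params.acc_bias)
    gyr = gyr_true + np.asarray(params.gyr_bias)
    if params.noise_acc > 0:
        acc = acc + rng.normal(0.0, params.noise_acc, (n, 3))
    if params.noise_gyr > 0:
        gyr = gyr + rng.normal(0.0, params.noise_gyr, (n, 3))

    rec = ImuRecording(
        time=time,
        acc=acc,
        gyr=gyr,
        rate_hz=params.rate_hz,
        device=Device.CSIC,
        units_state=UnitsState.CALIBRATED,
    )

    # ground-truth events: one complete stride per consecutive HS pair
    def nearest(ts: float) -> int:
        return int(np.clip(round(ts / dt), 0, n - 1))

    events: list[StrideEvents] = []
    st_t, st_l, st_c, st_toa, st_hsa = [], [], [], [], []
    for j in range(n_str - 1):
        t_hs = move_start[j] + _U_HS * m_dur[j]
        t_ts = move_start[j] + m_dur[j]
        t_ho = t_ts + d_dur[j]
        t_to = move_start[j + 1] + _U_TO * m_dur[j + 1]
        t_hs_next = move_start[j + 1] + _U_HS * m_dur[j + 1]
        ev = StrideEvents(
            t_hs=t_hs, t_ts=t_ts, t_ho=t_ho, t_to=t_to, t_hs_next=t_hs_next,
            i_hs=nearest(t_hs), i_ts=nearest(t_ts), i_ho=nearest(t_ho),
            i_to=nearest(t_to), i_hs_next=nearest(t_hs_next),
        )
        events.append(ev)
        st_t.append(t_hs_next - t_hs)
        # horizontal advance between the two heel strikes (x is constant)
        s_hs, _, _ = _minjerk(np.array([_U_HS]))
        st_l.append(L[j] * (1.0 - s_hs[0]) + L[j + 1] * s_hs[0])
        st_c.append(params.clearance_m)  # hump peak lies inside the swing
        st_toa.append(-params.pitch_to_deg)
        st_hsa.append(params.pitch_hs_deg)

    truth = GroundTruth(
        time=time,
        pitch_deg=np.degrees(pitch),
        r=r,
        v=v,
        a_free=a_free,
        events=events,
        stride_times=np.array(st_t),
        stride_lengths=np.array(st_l),
        clearances=np.array(st_c),
        toe_off_angles=np.array(st_toa),
        heel_strike_angles=np.array(st_hsa),
        still_intervals=[
            (0.0, params.initial_still_s),
            (total - params.final_still_s, total),
        ],
    )
    return rec, truth


def default_fixture_calibration(seed: int = 0) -> CalibrationParams:
    """Plausible non-trivial calibration parameters for raw fixtures.

    Scale factors emulate a 16-bit IMU at ±16 g / ±2000 deg/s full range with
    small axis misalignments and biases; deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    acc_lsb = 16 * GRAVITY / 32768.0
    gyr_lsb = np.radians(2000.0) / 32768.0
    small = lambda: rng.uniform(-0.02, 0.02, (3, 3)) * (1 - np.eye(3))
    return CalibrationParams(
        acc_bias=rng.uniform(-50, 50, 3),
        acc_misalignment=np.eye(3) + small(),
        acc_scaling=np.diag(acc_lsb * rng.uniform(0.98, 1.02, 3)),
        gyr_bias=rng.uniform(-20, 20, 3),
        gyr_misalignment=np.eye(3) + small(),
        gyr_scaling=np.diag(gyr_lsb * rng.uniform(0.98, 1.02, 3)),
        clock_error=float(rng.uniform(0.999, 1.001)),
    )


def write_fixture_set(
    params_list: Sequence[GaitSimParams], directory: str | Path
) -> list[dict[str, Path]]:
    """Write raw-TXT recordings + calibration files + truth sidecars.

    Files follow the database naming scheme: ``V{NNN}_{IDIMU}.TXT`` for the
    raw recording, ``C{IDIMU}.TXT`` for the calibration parameters and
    ``V{NNN}_truth.json`` for the ground-truth sidecar. Raw counts are
    obtained by applying the exact inverse of the calibration model to the
    simulated SI signals.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for i, params in enumerate(params_list, start=1):
        idimu = f"{0x45C9 + i:04X}"
        rec, truth = simulate_walk(params)
        cal = default_fixture_calibration(seed=params.seed + 1000)
        raw = invert_calibration(rec, cal)
        raw_path = directory / f"V{i:03d}_{idimu}.TXT"
        cal_path = directory / f"C{idimu}.TXT"
        truth_path = directory / f"V{i:03d}_truth.json"
        write_raw_recording(raw, raw_path)
        write_calibration_params(cal, cal_path)
        truth_path.write_text(
            json.dumps(
                {
                    "stride_times": truth.stride_times.tolist(),
                    "stride_lengths": truth.stride_lengths.tolist(),
                    "clearances": truth.clearances.tolist(),
                    "toe_off_angles": truth.toe_off_angles.tolist(),
                    "heel_strike_angles": truth.heel_strike_angles.tolist(),
                    "event_times": [
                        [ev.t_hs, ev.t_ts, ev.t_ho, ev.t_to, ev.t_hs_next]
                        for ev in truth.events
                    ],
                    "still_intervals": truth.still_intervals,
                },
                indent=1,
            )
        )
        written.append({"raw": raw_path, "calibration": cal_path, "truth": truth_path})
    return written
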