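"""End-to-end orchestration: calibrate -> orient -> segment -> integrate -> metrics.

:func:`analyze` runs the complete processing chain on one recording and
returns everything the register needs (per-stride metrics, the aggregated
summary) together with the intermediate products (zones, events, orientation,
trajectory) for diagnostics. All stages are deterministic given the inputs
and the configuration; configuration defaults equal the canonical thresholds
of the method (0.2 / 1.41 / 0.5 rad/s zone thresholds, 1.4x / 0.36x median
stride filter).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import yaml

from . import io as fio
from .calibration import apply_calibration, estimate_static_bias
from .datatypes import CalibrationParams, ImuRecording, UnitsState
from .metrics import GaitSummary, StrideMetrics, compute_stride, filter_strides, summarize
from .orientation import MahonyGains, OrientationSeries, alignment_from_gravity, mahony_filter, remove_gravity
from .segmentation import (
    GaitEvents,
    MinDurations,
    NoStridesError,
    ZoneSeries,
    ZoneThresholds,
    detect_events,
    detect_zones,
)
from .strapdown import Trajectory, compute_trajectory


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Tunable parameters of the analysis chain (defaults = canonical values)."""

    still_threshold: float = 0.2  # rad/s
    movement_threshold: float = 1.41  # rad/s
    footflat_threshold: float = 0.5  # rad/s
    min_still_s: float = 1.0
    min_footflat_s: float = 0.05
    smooth_window_s: float = 0.05
    mahony_kp: float = 0.5
    mahony_ki: float = 0.01
    acc_gate: float = 0.5  # m/s^2 window around g for accelerometer feedback
    static_window_s: float = 30.0  # initial standstill used for bias/alignment
    filter_upper: float = 1.4  # x median stride length
    filter_lower: float = 0.36
    anchor_policy: str = "midpoint"
    rezero_vertical: bool = True

    @property
    def zone_thresholds(self) -> ZoneThresholds:
        return ZoneThresholds(
            self.still_threshold, self.movement_threshold, self.footflat_threshold
        )

    @property
    def min_durations(self) -> MinDurations:
        return MinDurations(self.min_still_s, self.min_footflat_s)

    @property
    def mahony_gains(self) -> MahonyGains:
        return MahonyGains(self.mahony_kp, self.mahony_ki)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class AnalysisResult:
    """Products of one full pipeline run."""

    recording: ImuRecording  # calibrated, gyro-bias-corrected
    orientation: OrientationSeries
    zones: ZoneSeries
    events: GaitEvents
    trajectory: Trajectory
    strides: list[StrideMetrics]  # kept after the median filter
    removed: list[StrideMetrics]
    summary: GaitSummary

    @property
    def still_time(self) -> float:
        t = self.recording.time
        return float(
            sum(t[b - 1] - t[a] for a, b in self.zones.still_intervals)
        )


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except NoStridesError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise PipelineError(f"stage {name!r}: {exc}") from exc

        return wrapped

    return deco


def analyze(
    recording: ImuRecording,
    calibration: CalibrationParams | None = None,
    config: PipelineConfig | None = None,
) -> AnalysisResult:
    """Run the full gait-analysis chain on one recording.

    Parameters
    ----------
    recording : raw (supply ``calibration``) or already calibrated recording.
    calibration : parameters applied when the recording is raw.
    config : pipeline configuration; defaults used when omitted.

    Raises
    ------
    NoStridesError : when no complete stride can be detected.
    PipelineError : when any other stage fails; the message names the stage.
    """
    cfg = config or PipelineConfig()

    if recording.units_state is UnitsState.RAW:
        if calibration is None:
            raise PipelineError("stage 'calibrate': raw recording but no parameters")
        rec = _stage("calibrate")(apply_calibration)(recording, calibration)
    else:
        rec = recording.copy()

    # initial standstill: gyro bias + gravity alignment
    gyr_bias, acc_mean = _stage("static_bias")(estimate_static_bias)(
        rec, window=cfg.static_window_s, still_threshold=cfg.still_threshold
    )
    rec.gyr = rec.gyr - gyr_bias
    R0 = alignment_from_gravity(acc_mean)

    orient = _stage("orientation")(mahony_filter)(
        rec, gains=cfg.mahony_gains, R0=R0, acc_gate=cfg.acc_gate
    )

    zones = _stage("segmentation")(detect_zones)(
        rec.gyr_magnitude(),
        rec.rate_hz,
        thresholds=cfg.zone_thresholds,
        min_durations=cfg.min_durations,
        smooth_window_s=cfg.smooth_window_s,
    )
    events = detect_events(orient.pitch, zones, rec.time)
    if len(events) == 0:
        raise NoStridesError("no strides detected")

    a_free = _stage("gravity_removal")(remove_gravity)(rec, orient)
    trajectory = _stage("strapdown")(compute_trajectory)(
        a_free, rec.time, zones,
        anchor_policy=cfg.anchor_policy, rezero_z=cfg.rezero_vertical,
    )

    all_strides = [
        _stage("metrics")(compute_stride)(ev, n, orient.pitch, trajectory)
        for n, ev in enumerate(events)
    ]
    kept, removed = _stage("filter")(filter_strides)(
        all_strides, upper=cfg.filter_upper, lower=cfg.filter_lower
    )
    # renumber kept strides 0..N-1 for the metrics file
    kept = [replace(s, n=i) for i, s in enumerate(kept)]

    t = rec.time
    still_time = sum(t[min(b, len(t)) - 1] - t[a] for a, b in zones.still_intervals)
    summary = _stage("summarize")(summarize)(
        kept, still_time=float(still_time), duration=float(t[-1] - t[0])
    )
    return AnalysisResult(
        recording=rec,
        orientation=orient,
        zones=zones,
        events=events,
        trajectory=trajectory,
        strides=kept,
        removed=removed,
        summary=summary,
    )


def analyze_files(
    raw_path: str | Path,
    calib_path: str | Path | None = None,
    config: PipelineConfig | None = None,
    metrics_out: str | Path | None = None,
    rate_hz: float = 104.0,
) -> AnalysisResult:
    """File-level wrapper: read raw TXT (+ calibration TXT), run, write metrics."""
    rec = fio.read_raw_recording(raw_path, rate_hz=rate_hz)
    cal = fio.read_calibration_params(calib_path) if calib_path else None
    result = analyze(rec, calibration=cal, config=config)
    if metrics_out is not None:
        fio.write_stride_metrics(result.strides, metrics_out)
    return result


def plot_diagnostics(result: AnalysisResult, path: str | Path) -> None:
    """Three-panel diagnostic figure: signals + events, 2D path, histogram."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = result.recording.time
    fig, axes = plt.subplots(1, 3, figsize=(15, 4))

    ax = axes[0]
    ax.plot(t, result.recording.gyr_magnitude(), lw=0.6, label="|gyr| [rad/s]")
    ax.plot(t, np.radians(result.orientation.pitch), lw=0.6, label="pitch [rad]")
    for ev in result.events:
        ax.axvline(ev.t_hs, color="tab:green", lw=0.4, alpha=0.5)
        ax.axvline(ev.t_to, color="tab:red", lw=0.4, alpha=0.5)
    for a, b in result.zones.still_intervals:
        ax.axvspan(t[a], t[b - 1], color="gold", alpha=0.2)
    ax.set_xlabel("time [s]")
    ax.legend(loc="upper right", fontsize=7)
    ax.set_title("angular rate, pitch, events")

    ax = axes[1]
    ax.plot(result.trajectory.r[:, 0], result.trajectory.r[:, 1], lw=0.8)
    ax.set_xlabel("x [m]")
    ax.set_ylabel("y [m]")
    ax.set_aspect("equal", adjustable="datalim")
    ax.set_title("2D path")

    ax = axes[2]
    ax.hist([s.stride_length for s in result.strides], bins=20, color="tab:blue")
    ax.set_xlabel("stride length [m]")
    ax.set_ylabel("strides")
    ax.set_title("stride-length histogram")

    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
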