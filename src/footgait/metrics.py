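"""Per-stride spatio-temporal gait metrics, outlier filtering, aggregation.

A stride runs heel-strike to heel-strike and decomposes into four phases:

    Load      HS -> TS     (heel down, forefoot lowering)
    Foot Flat TS -> HO     (foot fully on the ground)
    Push      HO -> TO     (heel rises, push-off)
    Swing     TO -> next HS

expressed as percentages of the stride time, which sum to 100 by
construction. Spatial metrics come from the ZUPT-corrected foot trajectory:
stride length is the horizontal-plane distance between the stride endpoints,
the 2D/3D path lengths are cumulative sample-to-sample displacements, and
clearance is the maximum vertical excursion during swing (vertical position
is re-anchored to ground level at each stance).

Outlier strides (turns, stumbles, missed events) are removed by the median
rule: keep a stride iff 0.36 * median <= length <= 1.4 * median, bounds
inclusive, with the median taken over all detected strides before removal.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Mapping, Sequence

import numpy as np

from .segmentation import StrideEvents
from .strapdown import Trajectory

#: (attribute name, metrics-CSV column label) in file order.
FIELD_LABELS = (
    ("n", "Num. Steps"),
    ("stride_time", "Stride time"),
    ("swing_pct", "Swing"),
    ("load_pct", "Load"),
    ("foot_flat_pct", "Foot Flat"),
    ("push_pct", "Push"),
    ("toe_off_angle", "Toe Off angle"),
    ("heel_strike_angle", "Heel Strike angle"),
    ("cadence", "Cadence"),
    ("speed", "Speed"),
    ("stride_length", "Stride Length"),
    ("path3d", "3D Length Path"),
    ("path2d", "2D Length Path"),
    ("clearance", "Clearance"),
)

_LABEL_TO_FIELD = {label: name for name, label in FIELD_LABELS}


@dataclass
class StrideMetrics:
    """The 14 canonical metrics of one stride."""

    n: int  # stride index, 0-based
    stride_time: float  # s
    swing_pct: float  # % of gait cycle
    load_pct: float
    foot_flat_pct: float
    push_pct: float
    toe_off_angle: float  # deg, pitch at TO
    heel_strike_angle: float  # deg, pitch at HS
    cadence: float  # strides/min
    speed: float  # m/s
    stride_length: float  # m
    path3d: float  # m
    path2d: float  # m
    clearance: float  # m

    def as_row(self) -> dict:
        return {label: getattr(self, name) for name, label in FIELD_LABELS}

    @classmethod
    def from_row(cls, row: Mapping) -> "StrideMetrics":
        kwargs = {_LABEL_TO_FIELD[k]: row[k] for k in _LABEL_TO_FIELD if k in row}
        kwargs["n"] = int(kwargs["n"])
        return cls(**kwargs)


@dataclass
class GaitSummary:
    """Register-level aggregation of the kept strides of one walking test."""

    total_distance: float  # m, sum of stride lengths
    walking_time: float  # s, recording duration minus still intervals
    n_strides: int
    avg: dict[str, float]  # per-metric mean (keys: StrideMetrics field names)
    std: dict[str, float]  # per-metric sample std (n-1 denominator)


def compute_stride(
    events: StrideEvents,
    n: int,
    pitch: np.ndarray,
    trajectory: Trajectory,
) -> StrideMetrics:
    """Evaluate all 14 metrics for one stride.

    ``pitch`` is the per-sample pitch (degrees) aligned with
    ``trajectory.time``; ``events`` carries both times and sample indices.
    """
    events.validate(n)
    st = events.t_hs_next - events.t_hs
    load = (events.t_ts - events.t_hs) / st * 100.0
    foot_flat = (events.t_ho - events.t_ts) / st * 100.0
    push = (events.t_to - events.t_ho) / st * 100.0
    swing = (events.t_hs_next - events.t_to) / st * 100.0

    r = trajectory.r[events.i_hs : events.i_hs_next + 1]
    d_xy = float(np.hypot(*(r[-1, :2] - r[0, :2])))
    steps = np.diff(r, axis=0)
    path3d = float(np.linalg.norm(steps, axis=1).sum())
    path2d = float(np.linalg.norm(steps[:, :2], axis=1).sum())
    z_swing = trajectory.r[events.i_to : events.i_hs_next + 1, 2]
    clearance = float(max(z_swing.max(), 0.0))

    return StrideMetrics(
        n=n,
        stride_time=st,
        swing_pct=swing,
        load_pct=load,
        foot_flat_pct=foot_flat,
        push_pct=push,
        toe_off_angle=float(pitch[events.i_to]),
        heel_strike_angle=float(pitch[events.i_hs]),
        cadence=60.0 / st,
        speed=d_xy / st,
        stride_length=d_xy,
        path3d=path3d,
        path2d=path2d,
        clearance=clearance,
    )


def filter_strides(
    strides: Sequence[StrideMetrics],
    upper: float = 1.4,
    lower: float = 0.36,
) -> tuple[list[StrideMetrics], list[StrideMetrics]]:
    """Median-rule outlier removal on stride length.

    Keeps a stride iff ``lower * median <= length <= upper * median`` (bounds
    inclusive), the median being computed over all input strides before any
    removal. Returns ``(kept, removed)``.
    """
    if len(strides) == 0:
        raise ValueError("cannot filter an empty stride list")
    med = float(np.median([s.stride_length for s in strides]))
    kept, removed = [], []
    for s in strides:
        if lower * med <= s.stride_length <= upper * med:
            kept.append(s)
        else:
            removed.append(s)
    return kept, removed


def summarize(
    kept: Sequence[StrideMetrics],
    still_time: float,
    duration: float,
) -> GaitSummary:
    """Aggregate kept strides to the register's gait summary.

    ``still_time`` is the total duration of still intervals and ``duration``
    the full recording span; walking time is their difference.
    """
    if len(kept) == 0:
        raise ValueError("cannot summarize an empty stride list")
    numeric = [f.name for f in fields(StrideMetrics) if f.name != "n"]
    avg, std = {}, {}
    for name in numeric:
        vals = np.array([getattr(s, name) for s in kept], dtype=float)
        avg[name] = float(vals.mean())
        std[name] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return GaitSummary(
        total_distance=float(sum(s.stride_length for s in kept)),
        walking_time=float(duration - still_time),
        n_strides=len(kept),
        avg=avg,
        std=std,
    )
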