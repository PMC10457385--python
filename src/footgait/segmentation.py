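"""Gyro-threshold zone classification and pitch-extrema gait-event detection.

Zones are classified from the smoothed angular-rate magnitude:

* still      — magnitude < 0.2 rad/s sustained, outside walking bouts
* movement   — magnitude > 1.41 rad/s opens a walking bout
* foot-flat  — magnitude < 0.5 rad/s inside a walking bout

Within a bout, each pair of consecutive foot-flat intervals brackets one
swing window; toe-off is the pitch minimum early in the window and
heel-strike the pitch maximum late in the window (positive pitch = toe-up).
Toe-strike and heel-off are the boundaries of the following foot-flat
interval. Strides are assembled heel-strike to heel-strike; the partial first
and last cycles of each bout are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np


class ZoneThresholds(NamedTuple):
    """Angular-rate magnitude thresholds (rad/s) for zone classification."""

    still: float = 0.2
    movement: float = 1.41
    footflat: float = 0.5


class MinDurations(NamedTuple):
    """Debounce durations in seconds for zone intervals."""

    still: float = 1.0
    footflat: float = 0.05


class NoStridesError(RuntimeError):
    """Raised when a recording contains no detectable complete stride."""


@dataclass
class ZoneSeries:
    """Per-sample zone labels plus interval lists (sample-index pairs).

    ``labels`` holds one of ``{"still", "movement", "foot_flat",
    "transition"}`` per sample. Interval end indices are exclusive.
    """

    labels: np.ndarray
    still_intervals: list[tuple[int, int]]
    foot_flat_intervals: list[tuple[int, int]]
    bouts: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class StrideEvents:
    """Event times (s) and sample indices for one stride (HS -> next HS)."""

    t_hs: float
    t_ts: float
    t_ho: float
    t_to: float
    t_hs_next: float
    i_hs: int
    i_ts: int
    i_ho: int
    i_to: int
    i_hs_next: int

    def validate(self, n: int | None = None) -> None:
        seq = (self.t_hs, self.t_ts, self.t_ho, self.t_to, self.t_hs_next)
        if not all(a < b for a, b in zip(seq, seq[1:])):
            label = f"stride {n}" if n is not None else "stride"
            raise ValueError(f"{label}: event ordering violated: {seq}")


@dataclass
class GaitEvents:
    """All complete strides of a recording."""

    strides: list[StrideEvents]

    def __len__(self) -> int:
        return len(self.strides)

    def __iter__(self):
        return iter(self.strides)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, end-exclusive) index pairs of True runs."""
    if mask.size == 0:
        return []
    padded = np.diff(np.concatenate([[0], mask.astype(np.int8), [0]]))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def smooth_magnitude(gyr_mag: np.ndarray, rate_hz: float, window_s: float = 0.05) -> np.ndarray:
    """Moving-average smoothing of the angular-rate magnitude."""
    w = max(1, int(round(window_s * rate_hz)))
    if w == 1:
        return np.asarray(gyr_mag, dtype=float)
    kernel = np.ones(w) / w
    # edge-padded convolution keeps length and avoids edge droop
    padded = np.pad(np.asarray(gyr_mag, dtype=float), (w // 2, w - 1 - w // 2), mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def detect_zones(
    gyr_mag: np.ndarray,
    rate_hz: float,
    thresholds: ZoneThresholds = ZoneThresholds(),
    min_durations: MinDurations = MinDurations(),
    smooth_window_s: float = 0.05,
) -> ZoneSeries:
    """Classify still / movement / foot-flat zones from gyro magnitude.

    Still intervals are sustained quiet runs (>= ``min_durations.still``)
    outside walking bouts; segments between still intervals qualify as walking
    bouts when the magnitude exceeds the movement threshold somewhere inside;
    foot-flat intervals are quiet dwells (>= ``min_durations.footflat``)
    within a bout.
    """
    mag = np.asarray(gyr_mag, dtype=float)
    if mag.size == 0:
        raise ValueError("empty magnitude series")
    if mag.min() < 0:
        raise ValueError("magnitude must be nonnegative")
    mag = smooth_magnitude(mag, rate_hz, smooth_window_s)
    n = mag.size
    min_still = max(1, int(round(min_durations.still * rate_hz)))
    min_ff = max(1, int(round(min_durations.footflat * rate_hz)))

    still = [
        (a, b) for a, b in _runs(mag < thresholds.still) if b - a >= min_still
    ]

    # candidate bouts: complement of still intervals containing real movement
    edges = [0] + [i for ab in still for i in ab] + [n]
    bouts = []
    for a, b in zip(edges[::2], edges[1::2]):
        if b > a and np.any(mag[a:b] > thresholds.movement):
            bouts.append((a, b))

    foot_flat: list[tuple[int, int]] = []
    for a, b in bouts:
        for fa, fb in _runs(mag[a:b] < thresholds.footflat):
            if fb - fa >= min_ff:
                foot_flat.append((a + fa, a + fb))

    labels = np.full(n, "transition", dtype=object)
    for a, b in bouts:
        labels[a:b] = "movement"
    for a, b in foot_flat:
        labels[a:b] = "foot_flat"
    for a, b in still:
        labels[a:b] = "still"
    return ZoneSeries(
        labels=labels,
        still_intervals=still,
        foot_flat_intervals=foot_flat,
        bouts=bouts,
    )


def detect_events(
    pitch: np.ndarray,
    zones: ZoneSeries,
    time: np.ndarray,
) -> GaitEvents:
    """Detect per-stride HS/TS/HO/TO events from pitch extrema and foot-flats.

    For each swing window between consecutive foot-flat intervals of a bout,
    toe-off is the pitch minimum and heel-strike the subsequent pitch maximum.
    Windows whose pitch is monotone (no interior extrema, TO not before HS)
    yield no stride. Strides are chained HS -> HS, so a bout with k usable
    windows yields k - 1 strides.
    """
    pitch = np.asarray(pitch, dtype=float)
    time = np.asarray(time, dtype=float)
    strides: list[StrideEvents] = []

    usable = [
        (a, b)
        for a, b in zones.bouts
        if sum(1 for iv in zones.foot_flat_intervals if a <= iv[0] and iv[1] <= b) >= 2
    ]
    if not usable:
        raise NoStridesError(
            "no strides detected: no walking bout with >= 2 foot-flat intervals"
        )

    for a, b in zones.bouts:
        ffs = [iv for iv in zones.foot_flat_intervals if a <= iv[0] and iv[1] <= b]
        if len(ffs) < 2:
            continue
        # one (TO, HS) candidate per swing window between consecutive dwells
        window_events: list[tuple[int, int] | None] = []
        for (_, ho), (ts_next, _) in zip(ffs, ffs[1:]):
            w = slice(ho, ts_next + 1)
            seg = pitch[w]
            if seg.size < 3:
                window_events.append(None)
                continue
            i_to = ho + int(np.argmin(seg))
            i_hs = i_to + int(np.argmax(pitch[i_to : ts_next + 1]))
            if i_hs <= i_to or i_to == ho or i_hs >= ts_next:
                window_events.append(None)  # monotone / degenerate window
            else:
                window_events.append((i_to, i_hs))

        for j in range(len(window_events) - 1):
            if window_events[j] is None or window_events[j + 1] is None:
                continue
            _, i_hs = window_events[j]
            i_ts, i_ho = ffs[j + 1]
            i_to, i_hs_next = window_events[j + 1]
            ev = StrideEvents(
                t_hs=time[i_hs],
                t_ts=time[i_ts],
                t_ho=time[i_ho - 1],
                t_to=time[i_to],
                t_hs_next=time[i_hs_next],
                i_hs=i_hs,
                i_ts=i_ts,
                i_ho=i_ho - 1,
                i_to=i_to,
                i_hs_next=i_hs_next,
            )
            try:
                ev.validate(len(strides))
            except ValueError:
                continue
            strides.append(ev)

    return GaitEvents(strides=strides)
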