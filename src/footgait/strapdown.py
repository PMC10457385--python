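"""Strapdown integration with zero-velocity-update (ZUPT) drift correction.

Gravity-free global acceleration is integrated (trapezoidal rule) to
velocity; velocity drift is removed by subtracting, between each pair of
consecutive zero-velocity anchors, the straight line through the raw velocity
at those anchors — so the corrected velocity is exactly zero at every anchor
and any drift affine in time is removed exactly. The corrected velocity is
integrated again to position. The vertical position can be re-anchored the
same way so that foot clearance is measured from ground level per stride.

Anchors are placed at the midpoints of foot-flat dwells (where the foot is
most reliably stationary) and at the endpoints of still intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .segmentation import ZoneSeries


@dataclass
class Trajectory:
    """Global-frame foot velocity and position with ZUPT anchor indices."""

    time: np.ndarray
    v: np.ndarray  # (n, 3) m/s
    r: np.ndarray  # (n, 3) m
    anchors: np.ndarray  # sample indices of zero-velocity instants


def integrate_velocity(a_free: np.ndarray, time: np.ndarray) -> np.ndarray:
    """Trapezoidal integral of gravity-free acceleration; v(0) = 0."""
    a_free = np.atleast_2d(np.asarray(a_free, dtype=float))
    return cumulative_trapezoid(a_free, np.asarray(time, dtype=float), axis=0, initial=0.0)


def integrate_position(v: np.ndarray, time: np.ndarray) -> np.ndarray:
    """Trapezoidal integral of velocity; r(0) = 0."""
    return integrate_velocity(v, time)


def anchor_indices(zones: ZoneSeries, policy: str = "midpoint") -> np.ndarray:
    """Zero-velocity anchor sample indices from zone intervals.

    ``policy='midpoint'`` uses the midpoint of each foot-flat dwell;
    ``policy='endpoints'`` uses both dwell boundaries. Still-interval
    endpoints are always included (velocity is zero throughout a standstill).
    """
    idx: list[int] = []
    for a, b in zones.still_intervals:
        idx += [a, b - 1]
    for a, b in zones.foot_flat_intervals:
        if policy == "midpoint":
            idx.append((a + b - 1) // 2)
        elif policy == "endpoints":
            idx += [a, b - 1]
        else:
            raise ValueError(f"unknown anchor policy {policy!r}")
    return np.unique(np.asarray(idx, dtype=int))


def zupt_correct(v_raw: np.ndarray, anchors: np.ndarray, time: np.ndarray) -> np.ndarray:
    """Remove velocity drift by piecewise-linear interpolation between anchors.

    Between consecutive anchors the line through the raw velocity values at
    the anchors is subtracted (per axis); before the first and after the last
    anchor the anchor value is subtracted as a constant. The result is exactly
    zero at every anchor.
    """
    anchors = np.asarray(anchors, dtype=int)
    if anchors.size < 2:
        raise ValueError("cannot correct drift: need at least 2 anchors")
    v_raw = np.atleast_2d(np.asarray(v_raw, dtype=float))
    time = np.asarray(time, dtype=float)
    t_anchor = time[anchors]
    drift = np.empty_like(v_raw)
    for axis in range(v_raw.shape[1]):
        drift[:, axis] = np.interp(time, t_anchor, v_raw[anchors, axis])
    corrected = v_raw - drift
    corrected[anchors] = 0.0  # exact by construction; enforce bit-exactly
    return corrected


def rezero_vertical(r: np.ndarray, anchors: np.ndarray, time: np.ndarray) -> np.ndarray:
    """Re-anchor the vertical position to zero at every anchor.

    Subtracts the piecewise-linear interpolation of the vertical coordinate
    through its anchor values, so clearance is measured from the local ground
    level of each stride rather than from an altitude-drifting baseline.
    """
    anchors = np.asarray(anchors, dtype=int)
    if anchors.size < 2:
        raise ValueError("cannot re-anchor: need at least 2 anchors")
    r = np.array(r, dtype=float, copy=True)
    time = np.asarray(time, dtype=float)
    r[:, 2] -= np.interp(time, time[anchors], r[anchors, 2])
    return r


def compute_trajectory(
    a_free: np.ndarray,
    time: np.ndarray,
    zones: ZoneSeries,
    anchor_policy: str = "midpoint",
    rezero_z: bool = True,
) -> Trajectory:
    """Full strapdown chain: integrate, ZUPT-correct, integrate again."""
    anchors = anchor_indices(zones, anchor_policy)
    v_raw = integrate_velocity(a_free, time)
    v = zupt_correct(v_raw, anchors, time)
    r = integrate_position(v, time)
    if rezero_z:
        r = rezero_vertical(r, anchors, time)
    return Trajectory(time=np.asarray(time, dtype=float), v=v, r=r, anchors=anchors)
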