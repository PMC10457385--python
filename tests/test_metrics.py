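"""Per-stride metric formulas, the median stride filter, and aggregation."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from footgait import compute_stride, filter_strides, summarize
from footgait.segmentation import StrideEvents
from footgait.strapdown import Trajectory


def _events(rate=100.0, t_hs=0.0, t_ts=0.1, t_ho=0.5, t_to=0.7, t_next=1.0):
    return StrideEvents(
        t_hs=t_hs, t_ts=t_ts, t_ho=t_ho, t_to=t_to, t_hs_next=t_next,
        i_hs=int(t_hs * rate), i_ts=int(t_ts * rate), i_ho=int(t_ho * rate),
        i_to=int(t_to * rate), i_hs_next=int(t_next * rate),
    )


def _traj(n=101, rate=100.0, r=None):
    t = np.arange(n) / rate
    if r is None:
        r = np.zeros((n, 3))
    return Trajectory(time=t, v=np.zeros((n, 3)), r=r, anchors=np.array([0, n - 1]))


def test_phase_percentages_hand_computed():
    # hand evaluation: HS=0, TS=0.1, HO=0.5, TO=0.7, nextHS=1.0
    m = compute_stride(_events(), 0, np.zeros(101), _traj())
    assert m.stride_time == pytest.approx(1.0)
    assert m.load_pct == pytest.approx(10.0)
    assert m.foot_flat_pct == pytest.approx(40.0)
    assert m.push_pct == pytest.approx(20.0)
    assert m.swing_pct == pytest.approx(30.0)
    assert m.cadence == pytest.approx(60.0)


def test_straight_line_stride_length_and_path():
    # Pythagoras oracle: endpoints (0,0) -> (1.2, 0.5) give length 1.3;
    # a straight path makes the cumulative 2D path equal the chord
    n = 101
    r = np.zeros((n, 3))
    r[:, 0] = np.linspace(0, 1.2, n)
    r[:, 1] = np.linspace(0, 0.5, n)
    m = compute_stride(_events(), 0, np.zeros(n), _traj(r=r))
    assert m.stride_length == pytest.approx(1.3)
    assert m.path2d == pytest.approx(1.3)
    assert m.path3d == pytest.approx(1.3)
    assert m.speed == pytest.approx(1.3 / 1.0)


def test_stationary_trajectory_all_zero():
    m = compute_stride(_events(), 0, np.zeros(101), _traj())
    assert m.stride_length == 0.0
    assert m.path3d == 0.0
    assert m.clearance == 0.0


def test_angles_read_from_pitch_at_events():
    pitch = np.zeros(101)
    pitch[70] = -33.0  # TO sample
    pitch[0] = 21.0  # HS sample
    m = compute_stride(_events(), 0, pitch, _traj())
    assert m.toe_off_angle == -33.0
    assert m.heel_strike_angle == 21.0


def test_clearance_is_max_vertical_during_swing():
    n = 101
    r = np.zeros((n, 3))
    r[80, 2] = 0.18  # inside swing (TO at 70, next HS at 100)
    r[30, 2] = 0.50  # during stance: must not count
    m = compute_stride(_events(), 0, np.zeros(n), _traj(r=r))
    assert m.clearance == pytest.approx(0.18)


def test_violated_ordering_names_stride():
    ev = _events(t_ts=0.6, t_ho=0.5)
    with pytest.raises(ValueError, match="stride 3"):
        compute_stride(ev, 3, np.zeros(101), _traj())


def _metric(length, n=0):
    return dataclasses.replace(
        compute_stride(_events(), n, np.zeros(101), _traj()), stride_length=length
    )


class TestFilter:
    def test_toy_set_removes_exactly_the_outliers(self):
        strides = [_metric(1.0, i) for i in range(9)] + [_metric(0.2, 9), _metric(2.0, 10)]
        kept, removed = filter_strides(strides)
        assert len(kept) == 9
        assert sorted(s.stride_length for s in removed) == [0.2, 2.0]

    def test_all_equal_all_kept(self):
        kept, removed = filter_strides([_metric(0.8, i) for i in range(5)])
        assert len(kept) == 5 and removed == []

    def test_boundaries_inclusive(self):
        strides = [_metric(1.0, i) for i in range(9)]
        strides += [_metric(1.4, 9), _metric(0.36, 10)]  # exactly at the bounds
        kept, _ = filter_strides(strides)
        assert len(kept) == 11

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            filter_strides([])

    def test_idempotent_on_toy_set(self):
        strides = [_metric(1.0, i) for i in range(9)] + [_metric(0.2, 9), _metric(2.0, 10)]
        kept, _ = filter_strides(strides)
        kept2, removed2 = filter_strides(kept)
        assert removed2 == [] and kept2 == kept

    def test_idempotent_on_pipeline_output(self, noisy_result):
        kept2, removed2 = filter_strides(noisy_result.strides)
        assert removed2 == [] and kept2 == noisy_result.strides

    @settings(deadline=None, max_examples=50)
    @given(lengths=st.lists(st.floats(0.9, 1.2), min_size=1, max_size=30))
    def test_idempotent_for_regular_gait(self, lengths):
        """For stride lengths within a normal gait spread the filter is a
        no-op, hence trivially idempotent (all within 0.36x-1.4x any median)."""
        strides = [_metric(l, i) for i, l in enumerate(lengths)]
        kept, removed = filter_strides(strides)
        assert removed == []
        kept2, removed2 = filter_strides(kept)
        assert removed2 == [] and kept2 == kept


class TestSummarize:
    def test_single_stride_std_zero(self):
        s = _metric(1.0)
        summary = summarize([s], still_time=10.0, duration=60.0)
        assert summary.n_strides == 1
        assert summary.std["stride_length"] == 0.0
        assert summary.avg["stride_length"] == 1.0
        assert summary.walking_time == 50.0

    def test_two_strides_arithmetic(self):
        summary = summarize(
            [_metric(1.0, 0), _metric(1.2, 1)], still_time=0.0, duration=3.0
        )
        assert summary.total_distance == pytest.approx(2.2)
        assert summary.avg["stride_length"] == pytest.approx(1.1)
        assert summary.std["stride_length"] == pytest.approx(np.std([1.0, 1.2], ddof=1))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([], still_time=0.0, duration=1.0)


def test_identities_hold_for_every_pipeline_stride(noisy_result):
    for s in noisy_result.strides:
        assert s.swing_pct + s.load_pct + s.foot_flat_pct + s.push_pct == pytest.approx(
            100.0, abs=1e-6
        )
        assert s.cadence * s.stride_time == pytest.approx(60.0, abs=1e-9)
        assert s.speed * s.stride_time == pytest.approx(s.stride_length, abs=1e-9)
        assert s.path3d >= s.path2d >= s.stride_length - 1e-9
        assert s.clearance >= 0


def test_total_distance_close_to_ground_truth(clean_sim, clean_result):
    _, truth = clean_sim
    est = clean_result.summary.total_distance
    # compare against the true lengths of the detected strides
    true_per_stride = truth.stride_lengths.mean()
    expected = true_per_stride * clean_result.summary.n_strides
    assert abs(est - expected) / expected < 0.05
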