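"""Clinical instrument scoring: cut-offs, boundaries, monotonicity."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from footgait.clinical import (
    ClinicalRecord,
    Missing,
    Sex,
    fes_i_total,
    fried_assess,
    fried_thresholds,
    gait_speed_4m,
    sppb_balance,
    sppb_chair,
    sppb_gait,
    sppb_total,
    validate_gds,
)


@pytest.mark.parametrize(
    "time_s,expected", [(5.0, 0.8), (4.0, 1.0), (8.0, 0.5)]
)
def test_gait_speed_4m(time_s, expected):
    assert gait_speed_4m(time_s) == pytest.approx(expected)


def test_gait_speed_missing_propagates():
    assert gait_speed_4m(Missing.INCAPABLE) is Missing.INCAPABLE
    with pytest.raises(ValueError):
        gait_speed_4m(0.0)


@pytest.mark.parametrize(
    "sex,height,bmi,expected",
    [
        (Sex.F, 150, 24, (0.41, 11.0)),
        (Sex.M, 170, 28, (0.43, 22.9)),
        (Sex.M, 164, 26.4, (0.50, 19.1)),  # boundaries are inclusive (<=)
        (Sex.M, 165, 26.5, (0.43, 22.9)),
        (Sex.F, 152, 26.4, (0.41, 11.0)),
        (Sex.F, 153, 26.5, (0.33, 12.0)),
        (Sex.M, 150, 20, (0.50, 19.1)),
        (Sex.F, 160, 30, (0.33, 12.0)),
    ],
)
def test_fried_thresholds_table(sex, height, bmi, expected):
    assert fried_thresholds(sex, height, bmi) == expected


def _record(**kw):
    base = dict(
        sex=Sex.M, height_cm=170, weight_kg=70,
        four_m_time=4.0,  # 1.0 m/s, not slow
        grip_forces=(30.0,),
        weight_loss_kg=0.0, exhaustion_days=0.0, activity_hours=10.0,
    )
    base.update(kw)
    return ClinicalRecord(**base)


class TestFried:
    def test_all_negative_is_robust(self):
        res = fried_assess(_record())
        assert res.index == 0 and res.category == "robust"

    def test_two_affirmative_is_prefrail(self):
        res = fried_assess(_record(weight_loss_kg=5.0, exhaustion_days=3.0))
        assert res.index == 2 and res.category == "prefrail"

    def test_three_affirmative_is_frail(self):
        res = fried_assess(
            _record(weight_loss_kg=5.0, exhaustion_days=2.0, activity_hours=2.0)
        )
        assert res.index == 3 and res.category == "frail"

    def test_weight_loss_cutoff_is_strictly_over_4_5(self):
        assert fried_assess(_record(weight_loss_kg=4.5)).weight_loss is False
        assert fried_assess(_record(weight_loss_kg=4.51)).weight_loss is True

    def test_exhaustion_cutoff_two_days(self):
        assert fried_assess(_record(exhaustion_days=1.0)).exhaustion is False
        assert fried_assess(_record(exhaustion_days=2.0)).exhaustion is True

    def test_activity_cutoff_by_sex(self):
        assert fried_assess(_record(activity_hours=2.9)).low_activity is True
        assert fried_assess(_record(activity_hours=3.0)).low_activity is False
        f = _record(sex=Sex.F, activity_hours=0.9)
        assert fried_assess(f).low_activity is True
        assert fried_assess(_record(sex=Sex.F, activity_hours=1.0)).low_activity is False

    def test_slowness_uses_stratified_threshold(self):
        # M, 170 cm -> threshold 0.43 m/s; 4 m in 9.4 s = 0.4255 m/s (slow)
        assert fried_assess(_record(four_m_time=9.4)).slowness is True
        assert fried_assess(_record(four_m_time=9.2)).slowness is False

    def test_weakness_uses_stratified_threshold(self):
        # M, BMI 70/1.7^2 = 24.2 -> force threshold 19.1 kg
        assert fried_assess(_record(grip_forces=(19.0,))).weakness is True
        assert fried_assess(_record(grip_forces=(19.1,))).weakness is False

    def test_grip_is_max_over_attempts_and_hands(self):
        assert fried_assess(_record(grip_forces=(15.0, 19.5, 18.0))).weakness is False

    def test_incapable_walk_counts_as_slow(self):
        res = fried_assess(_record(four_m_time=Missing.INCAPABLE))
        assert res.slowness is True

    def test_missing_grip_leaves_index_undetermined(self):
        res = fried_assess(_record(grip_forces=()))
        assert res.weakness is None
        assert res.index is None and res.category is None


class TestSppbBalance:
    @pytest.mark.parametrize(
        "side,semi,tandem,expected",
        [
            (10, 10, 11, 4),
            (10, 10, 5, 3),
            (0, 0, 0, 0),
            (10, 10, 10, 3),  # tandem exactly 10 s: 1 point (2 needs > 10)
            (10, 10, 3.99, 3),
            (10, 10, 3.98, 2),
            (9.99, 10, 11, 3),
        ],
    )
    def test_cutoffs(self, side, semi, tandem, expected):
        assert sppb_balance(side, semi, tandem) == expected


class TestSppbGait:
    @pytest.mark.parametrize(
        "time_s,expected",
        [
            (7.0, 2),
            (4.5, 4),
            (Missing.INCAPABLE, 0),
            (8.70, 2), (8.71, 1),
            (6.21, 2), (6.20, 3),
            (4.82, 3), (4.81, 4),
            (20.0, 1),
        ],
    )
    def test_cutoffs(self, time_s, expected):
        assert sppb_gait(time_s) == expected

    @settings(deadline=None, max_examples=60)
    @given(t1=st.floats(1.0, 30.0), t2=st.floats(1.0, 30.0))
    def test_faster_never_scores_lower(self, t1, t2):
        lo, hi = sorted((t1, t2))
        assert sppb_gait(lo) >= sppb_gait(hi)


class TestSppbChair:
    @pytest.mark.parametrize(
        "time_s,expected",
        [
            (12.0, 3),
            (65.0, 0),
            (10.0, 4),
            (Missing.INCAPABLE, 0),
            (60.00, 1), (60.01, 0),
            (16.70, 1), (16.69, 2),
            (13.70, 2), (13.69, 3),
            (11.20, 3), (11.19, 4),
        ],
    )
    def test_cutoffs(self, time_s, expected):
        assert sppb_chair(time_s) == expected

    @settings(deadline=None, max_examples=60)
    @given(t1=st.floats(5.0, 70.0), t2=st.floats(5.0, 70.0))
    def test_longer_never_scores_higher(self, t1, t2):
        lo, hi = sorted((t1, t2))
        assert sppb_chair(lo) >= sppb_chair(hi)


def test_sppb_total_sums_and_validates():
    assert sppb_total(4, 4, 4) == 12
    assert sppb_total(0, 0, 0) == 0
    assert sppb_total(3, 2, 1) == 6
    with pytest.raises(ValueError):
        sppb_total(5, 0, 0)


class TestFesI:
    def test_extremes_and_sum(self):
        assert fes_i_total([1] * 7) == 7
        assert fes_i_total([4] * 7) == 28
        assert fes_i_total([1, 1, 1, 1, 1, 1, 2]) == 8

    def test_item_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fes_i_total([1, 1, 1, 1, 1, 1, 5])
        with pytest.raises(ValueError):
            fes_i_total([1] * 6)


def test_gds_validation():
    assert validate_gds(1) == 1
    assert validate_gds(7) == 7
    with pytest.raises(ValueError):
        validate_gds(8)


def test_bmi_from_height_weight():
    rec = _record(weight_kg=64.0, height_cm=160.0)
    assert rec.bmi == pytest.approx(25.0)
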