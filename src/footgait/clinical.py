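"""Deterministic scoring of the clinical frailty and function instruments.

Implements the instruments recorded alongside the instrumented walking test:

* 4-m walk gait speed (also feeds the SPPB gait item and the Fried slowness
  criterion)
* Fried frailty phenotype: five binary criteria (weight loss, exhaustion,
  low activity, slowness, weakness); index 0 = robust, 1-2 = prefrail,
  >= 3 = frail. The slowness/weakness cut-offs depend on sex, height and BMI.
* SPPB: balance (0-4), gait (0-4), chair-stand (0-4), total 0-12.
* Short FES-I: seven items, each 1-4, total 7-28 (higher = more fear).
* GDS 1-7 and TUG time are recorded and validated but carry no scoring rule.

Timed items are rounded to two decimals before binning and bins are
half-open at the printed edges (e.g. a chair-stand time of exactly 13.70 s
scores 2, 13.69 s scores 3), so every rounded value falls in exactly one bin.
"Incapable" outcomes score zero on the timed SPPB items; absent measurements
propagate as missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence


class Missing(Enum):
    """Distinguishable missing states of a clinical outcome.

    INCAPABLE: the subject attempted but could not perform the test (scores
    zero where the instrument says so). ABSENT: the datum was not collected.
    Never conflated with a numeric zero.
    """

    INCAPABLE = "incapable"
    ABSENT = "-"


Maybe = float | Missing  # a measured value or a missing marker


class Sex(str, Enum):
    M = "M"
    F = "F"


@dataclass
class ClinicalRecord:
    """Raw clinical-test outcomes for one subject."""

    sex: Sex
    height_cm: float
    weight_kg: float
    four_m_time: Maybe = Missing.ABSENT  # s
    grip_forces: Sequence[float] = field(default_factory=tuple)  # kg, all attempts
    weight_loss_kg: Maybe = Missing.ABSENT  # unintentional, last year
    exhaustion_days: Maybe = Missing.ABSENT  # days/week with low energy
    activity_hours: Maybe = Missing.ABSENT  # walking hours/week
    balance_side: Maybe = Missing.ABSENT  # s held, feet side-by-side
    balance_semitandem: Maybe = Missing.ABSENT  # s
    balance_tandem: Maybe = Missing.ABSENT  # s
    chair_time: Maybe = Missing.ABSENT  # s, five sit-to-stands
    tug_time: Maybe = Missing.ABSENT  # s
    fes_items: Sequence[int] | Missing = Missing.ABSENT  # seven ints, 1-4
    gds: int | Missing = Missing.ABSENT  # 1-7

    @property
    def bmi(self) -> float:
        return self.weight_kg / (self.height_cm / 100.0) ** 2

    @property
    def grip_force(self) -> Maybe:
        """Maximum force over all attempts, either hand."""
        if not self.grip_forces:
            return Missing.ABSENT
        return float(max(self.grip_forces))


@dataclass
class FrailtyResult:
    """Outcome of the Fried phenotype assessment."""

    weight_loss: bool | None
    exhaustion: bool | None
    low_activity: bool | None
    slowness: bool | None
    weakness: bool | None
    index: int | None  # 0-5, None if any criterion unresolved
    category: str | None  # robust / prefrail / frail


def _is_missing(x) -> bool:
    return isinstance(x, Missing)


def gait_speed_4m(time_s: Maybe) -> Maybe:
    """Gait speed (m/s) from the 4-m walk time; missing markers propagate."""
    if _is_missing(time_s):
        return time_s
    if time_s <= 0:
        raise ValueError("4-m walk time must be positive")
    return 4.0 / time_s


def fried_thresholds(sex: Sex, height_cm: float, bmi: float) -> tuple[float, float]:
    """Sex/height/BMI-stratified cut-offs for slowness and weakness.

    Returns ``(speed_threshold m/s, force_threshold kg)``; a measurement
    strictly below its threshold makes the criterion affirmative. Height and
    BMI boundaries are inclusive on the low side.
    """
    sex = Sex(sex)
    if sex is Sex.M:
        speed = 0.50 if height_cm <= 164 else 0.43
        force = 19.1 if bmi <= 26.4 else 22.9
    else:
        speed = 0.41 if height_cm <= 152 else 0.33
        force = 11.0 if bmi <= 26.4 else 12.0
    return speed, force


def fried_assess(record: ClinicalRecord) -> FrailtyResult:
    """Score the five Fried criteria and derive the frailty category.

    Criteria: unintentional weight loss > 4.5 kg; exhaustion on >= 2
    days/week; low activity (< 3 h/week walking for men, < 1 h/week for
    women); slowness (4-m speed below the stratified cut-off); weakness
    (grip force below the stratified cut-off). An incapable 4-m walk counts
    as slow. Unresolvable criteria leave the index undetermined (None).
    """
    speed_thr, force_thr = fried_thresholds(record.sex, record.height_cm, record.bmi)

    def crit(value: Maybe, predicate) -> bool | None:
        return None if _is_missing(value) else bool(predicate(value))

    weight_loss = crit(record.weight_loss_kg, lambda v: v > 4.5)
    exhaustion = crit(record.exhaustion_days, lambda v: v >= 2)
    activity_cut = 3.0 if Sex(record.sex) is Sex.M else 1.0
    low_activity = crit(record.activity_hours, lambda v: v < activity_cut)

    if record.four_m_time is Missing.INCAPABLE:
        slowness: bool | None = True
    else:
        speed = gait_speed_4m(record.four_m_time)
        slowness = None if _is_missing(speed) else bool(speed < speed_thr)
    weakness = crit(record.grip_force, lambda v: v < force_thr)

    criteria = (weight_loss, exhaustion, low_activity, slowness, weakness)
    if any(c is None for c in criteria):
        index, category = None, None
    else:
        index = int(sum(criteria))
        category = "robust" if index == 0 else ("prefrail" if index <= 2 else "frail")
    return FrailtyResult(weight_loss, exhaustion, low_activity, slowness,
                         weakness, index, category)


def _round2(t: float) -> float:
    return round(float(t), 2)


def sppb_balance(side_s: Maybe, semitandem_s: Maybe, tandem_s: Maybe) -> int:
    """Balance item: side-by-side (1 pt at >=10 s), semi-tandem (1 pt at
    >=10 s), tandem (2 pts above 10 s, 1 pt at >=3.99 s)."""
    score = 0
    if not _is_missing(side_s) and side_s >= 10:
        score += 1
    if not _is_missing(semitandem_s) and semitandem_s >= 10:
        score += 1
    if not _is_missing(tandem_s):
        if tandem_s > 10:
            score += 2
        elif tandem_s >= 3.99:
            score += 1
    return score


def sppb_gait(time_s: Maybe) -> int:
    """Gait item from the 4-m walk time (0 if incapable; faster = higher)."""
    if _is_missing(time_s):
        return 0
    t = _round2(time_s)
    if t > 8.70:
        return 1
    if t >= 6.21:
        return 2
    if t >= 4.82:
        return 3
    return 4


def sppb_chair(time_s: Maybe) -> int:
    """Chair-stand item from the five-repetition time (0 if incapable or
    over 60 s; faster = higher)."""
    if _is_missing(time_s):
        return 0
    t = _round2(time_s)
    if t > 60.00:
        return 0
    if t >= 16.70:
        return 1
    if t >= 13.70:
        return 2
    if t >= 11.20:
        return 3
    return 4


def sppb_total(balance: int, gait: int, chair: int) -> int:
    """SPPB total, 0-12 (lower = higher frailty risk)."""
    for name, v in (("balance", balance), ("gait", gait), ("chair", chair)):
        if not 0 <= v <= 4:
            raise ValueError(f"SPPB {name} sub-score {v} outside 0-4")
    return balance + gait + chair


def sppb_assess(record: ClinicalRecord) -> tuple[int, int, int, int]:
    """(balance, gait, chair, total) for a clinical record."""
    b = sppb_balance(record.balance_side, record.balance_semitandem, record.balance_tandem)
    g = sppb_gait(record.four_m_time)
    c = sppb_chair(record.chair_time)
    return b, g, c, sppb_total(b, g, c)


def fes_i_total(items: Sequence[int]) -> int:
    """Short FES-I total: sum of seven 1-4 items, range 7-28."""
    items = list(items)
    if len(items) != 7:
        raise ValueError(f"Short FES-I has 7 items, got {len(items)}")
    for i, v in enumerate(items):
        if not 1 <= int(v) <= 4 or int(v) != v:
            raise ValueError(f"FES-I item {i} value {v!r} outside 1-4")
    return int(sum(items))


def validate_gds(gds: int) -> int:
    """Validate the Global Deterioration Scale stage (1-7); no scoring rule."""
    if not 1 <= int(gds) <= 7:
        raise ValueError(f"GDS stage {gds} outside 1-7")
    return int(gds)
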