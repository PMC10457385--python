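"""Score the clinical frailty/function instruments for two subjects.

Builds two clinical records — a robust community-dwelling woman and a frail
man who cannot complete the timed tests — and prints the Fried phenotype,
SPPB sub-scores and Short FES-I totals the clinic would report.
"""

from footgait.clinical import (
    ClinicalRecord,
    Missing,
    Sex,
    fes_i_total,
    fried_assess,
    fried_thresholds,
    gait_speed_4m,
    sppb_assess,
)

robust = ClinicalRecord(
    sex=Sex.F, height_cm=158, weight_kg=61,
    four_m_time=4.4, grip_forces=(16.0, 17.5),
    weight_loss_kg=0.0, exhaustion_days=0.0, activity_hours=6.0,
    balance_side=10, balance_semitandem=10, balance_tandem=12,
    chair_time=10.8, tug_time=9.5,
)
frail = ClinicalRecord(
    sex=Sex.M, height_cm=168, weight_kg=58,
    four_m_time=Missing.INCAPABLE, grip_forces=(14.0,),
    weight_loss_kg=6.0, exhaustion_days=4.0, activity_hours=0.5,
    balance_side=10, balance_semitandem=4, balance_tandem=0,
    chair_time=Missing.INCAPABLE, tug_time=28.0,
)

for name, rec in (("robust subject", robust), ("frail subject", frail)):
    fried = fried_assess(rec)
    b, g, c, total = sppb_assess(rec)
    speed = gait_speed_4m(rec.four_m_time)
    speed_txt = "incapable" if isinstance(speed, Missing) else f"{speed:.2f} m/s"
    thr_speed, thr_force = fried_thresholds(rec.sex, rec.height_cm, rec.bmi)
    print(f"{name}: BMI {rec.bmi:.1f}, 4-m speed {speed_txt} "
          f"(slow if < {thr_speed}), grip {rec.grip_force} kg (weak if < {thr_force})")
    print(f"  Fried criteria (loss/exhaustion/activity/slow/weak): "
          f"{[fried.weight_loss, fried.exhaustion, fried.low_activity, fried.slowness, fried.weakness]}")
    print(f"  Fried index {fried.index} -> {fried.category}")
    print(f"  SPPB balance {b} + gait {g} + chair {c} = {total}/12")

fes = fes_i_total([1, 2, 1, 1, 2, 1, 1])
print(f"\nShort FES-I example (7 items, 1-4 each): total {fes}/28 "
      "(7 = no fear of falling, 28 = maximal fear)")
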