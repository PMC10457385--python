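"""Simulate a walking bout and run the full gait-analysis pipeline.

Generates a 20-stride foot-mounted-IMU recording with the default elderly
gait conditions (plus sensor noise and bias), runs calibration-free analysis
(the simulator emits SI units) and prints the recovered spatio-temporal
parameters next to the simulator's ground truth.
"""

import warnings

from footgait import GaitSimParams, PipelineConfig, analyze
from footgait.synthetic import simulate_walk

params = GaitSimParams(n_strides=20, initial_still_s=10.0, seed=3)
recording, truth = simulate_walk(params)
print(f"simulated {len(recording)} samples at {recording.rate_hz:g} Hz "
      f"({recording.time[-1]:.1f} s), {params.n_strides} strides")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # the 10 s standstill is shorter than 30 s
    result = analyze(recording, config=PipelineConfig(static_window_s=10.0))

s = result.summary
print(f"\ndetected {s.n_strides} complete strides "
      f"({len(result.removed)} removed by the median filter)")
print(f"{'':>24}  estimated   truth")
print(f"{'mean stride time [s]':>24}  {s.avg['stride_time']:.3f}      {truth.stride_times.mean():.3f}")
print(f"{'mean stride length [m]':>24}  {s.avg['stride_length']:.3f}      {truth.stride_lengths.mean():.3f}")
print(f"{'mean clearance [m]':>24}  {s.avg['clearance']:.3f}      {truth.clearances.mean():.3f}")
print(f"{'toe-off angle [deg]':>24}  {s.avg['toe_off_angle']:.1f}      {truth.toe_off_angles.mean():.1f}")
print(f"{'heel-strike angle [deg]':>24}  {s.avg['heel_strike_angle']:.1f}       {truth.heel_strike_angles.mean():.1f}")
print(f"{'cadence [strides/min]':>24}  {s.avg['cadence']:.1f}")
print(f"\ntotal distance {s.total_distance:.1f} m, walking time {s.walking_time:.1f} s")
print("phase split [% of cycle]: "
      f"load {s.avg['load_pct']:.1f}, foot-flat {s.avg['foot_flat_pct']:.1f}, "
      f"push {s.avg['push_pct']:.1f}, swing {s.avg['swing_pct']:.1f}")
# The estimates come from integrating the IMU signals alone (Mahony pitch,
# ZUPT-corrected double integration); the truth column is the simulator's
# known kinematics, so the difference is the end-to-end estimation error.
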