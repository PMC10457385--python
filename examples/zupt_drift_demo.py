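"""Show how zero-velocity updates remove integration drift.

Simulates a noise-free bout, injects a constant accelerometer bias (a tilt
error of ~0.3 deg worth of gravity leakage), and compares the stride lengths
from plain double integration against ZUPT-corrected integration.
"""

import dataclasses
import warnings

import numpy as np

from footgait import GaitSimParams, PipelineConfig, analyze
from footgait.orientation import mahony_filter, remove_gravity, alignment_from_gravity
from footgait.strapdown import integrate_position, integrate_velocity
from footgait.synthetic import simulate_walk

params = dataclasses.replace(
    GaitSimParams(n_strides=20, initial_still_s=10.0, seed=5).noise_free(),
    acc_bias=(0.05, 0.05, 0.05),  # m/s^2, a realistic residual bias
)
rec, truth = simulate_walk(params)

# uncorrected: orient, remove gravity, integrate twice, no ZUPT
orient = mahony_filter(rec, R0=alignment_from_gravity(rec.acc[:500].mean(axis=0)))
a_free = remove_gravity(rec, orient)
v_raw = integrate_velocity(a_free, rec.time)
r_raw = integrate_position(v_raw, rec.time)
final_speed = np.linalg.norm(v_raw[-1])
print(f"without ZUPT: velocity at the final standstill = {final_speed:.2f} m/s "
      "(should be 0; bias integrates into unbounded drift)")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    result = analyze(rec, config=PipelineConfig(static_window_s=10.0))
v_anchor = np.abs(result.trajectory.v[result.trajectory.anchors]).max()
err = abs(result.summary.avg["stride_length"] - truth.stride_lengths.mean())
print(f"with ZUPT: velocity at every stance anchor = {v_anchor:.1e} m/s (exact 0)")
print(f"mean stride length {result.summary.avg['stride_length']:.3f} m "
      f"vs truth {truth.stride_lengths.mean():.3f} m "
      f"({100 * err / truth.stride_lengths.mean():.2f}% error despite the bias)")
# Linear interpolation between stance anchors removes any velocity drift that
# is affine in time — a constant acceleration error is cancelled exactly.
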