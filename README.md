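# footgait

Gait analysis from a single foot-mounted inertial measurement unit (IMU),
for research on frailty and fall risk in older adults.

A tri-axial accelerometer + gyroscope strapped to the instep observes every
stride a person takes during a walking test. `footgait` turns those raw
signals into the spatio-temporal gait parameters clinicians and researchers
use as digital biomarkers — stride time and length, gait speed, cadence,
phase percentages (load, foot-flat, push, swing), foot pitch angles at
heel-strike and toe-off, and swing clearance — and scores the clinical
instruments usually collected alongside such tests (4-m gait speed, the
Fried frailty phenotype, SPPB, Short FES-I, GDS, TUG).

## The method

For each recording the pipeline runs:

1. **Calibration** — per sensor, `x_cal = S · M · (x_raw − b)` with bias
   vector `b`, misalignment matrix `M` and scaling matrix `S` (which carries
   the unit conversion to m/s² and rad/s); the time axis is rescaled by a
   clock factor.
2. **Orientation** — a Mahony complementary filter estimates the
   sensor-to-global rotation `R_t` per sample: gyroscope integration by
   quaternion exponential updates, with proportional/integral feedback toward
   the accelerometer's gravity direction, gated on `| ‖a‖ − g | < 0.5 m/s²`
   so feedback acts only when the foot is quasi-static. The sagittal *pitch*
   (elevation of the forward axis, positive toe-up) drives event detection.
3. **Gait segmentation** — thresholds on the smoothed angular-rate magnitude
   classify *still* (< 0.2 rad/s, sustained), *movement* (> 1.41 rad/s opens
   a walking bout) and *foot-flat* (< 0.5 rad/s inside a bout) zones.
   Between consecutive foot-flat dwells, toe-off (TO) is the pitch minimum
   and heel-strike (HS) the pitch maximum; toe-strike (TS) and heel-off (HO)
   are the dwell boundaries. Strides run HS → HS.
4. **ZUPT strapdown integration** — gravity is removed in the global frame
   (`a_free = R a_S − g`), integrated to velocity, and drift is cancelled by
   zero-velocity updates: between consecutive stance anchors the straight
   line through the raw velocity at the anchors is subtracted, so velocity
   is exactly zero at every anchor and any drift affine in time vanishes.
   A second integration gives the foot trajectory.
5. **Stride metrics** — the 14 per-stride quantities, with outlier strides
   removed by the median rule (keep iff `0.36·median ≤ length ≤ 1.4·median`),
   aggregated into a subject-level register row (totals, averages, standard
   deviations).

A synthetic gait simulator (`footgait.synthetic`) generates piecewise-analytic
foot trajectories with full ground truth — event times, per-stride lengths,
clearances, pitch angles — so the whole chain is validated end to end
without any real recordings.

## Worked example

`python examples/simulate_and_analyze.py` simulates a 20-stride bout at the
default study conditions (104 Hz, ~1 m strides at ~1.1 s, σ_acc = 0.05 m/s²,
σ_gyr = 0.005 rad/s plus constant biases) and analyzes it:

```
simulated 4315 samples at 104 Hz (41.5 s), 20 strides

detected 17 complete strides (0 removed by the median filter)
                          estimated   truth
    mean stride time [s]  1.089      1.091
  mean stride length [m]  1.007      1.003
      mean clearance [m]  0.150      0.150
     toe-off angle [deg]  -35.0      -35.0
 heel-strike angle [deg]  20.0       20.0
   cadence [strides/min]  55.2

total distance 17.1 m, walking time 21.5 s
phase split [% of cycle]: load 17.8, foot-flat 34.3, push 20.1, swing 27.8
```

The *estimated* column comes purely from the simulated sensor streams
(Mahony pitch + ZUPT-corrected double integration); *truth* is the
simulator's known kinematics, so the differences are the end-to-end
estimation errors (all below 1% here). The first/last cycles of a bout lack
complete event sets and are discarded, hence 17 of 20 strides.

Other examples: `clinical_scoring.py` (Fried/SPPB/FES-I for a robust and a
frail subject), `zupt_drift_demo.py` (drift cancellation under sensor bias),
`file_dialects.py` (every file format round-tripped).

There is also a thin CLI:

```sh
footgait simulate out_dir --n-strides 20         # synthetic fixtures
footgait calibrate raw.TXT cal.TXT --params C45C9.TXT
footgait analyze V001_45C9.TXT --params C45C9.TXT --metrics-out V001_metrics.csv
footgait score records.csv register.csv
footgait aggregate V*_metrics.csv --out register.csv
```

## Layout

- `src/footgait/` — library: `datatypes`, `io`, `register`, `calibration`,
  `orientation`, `segmentation`, `strapdown`, `metrics`, `clinical`,
  `synthetic`, `pipeline`, `cli`
- `examples/` — narrative scripts, one per capability
- `docs/methods.md` — models, conventions, parameter choices, limitations
- `tests/` — unit, property and end-to-end acceptance tests
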