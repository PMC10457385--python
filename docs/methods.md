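# Methods

This note records the models, conventions and numerical choices behind
`footgait`, in enough detail that a maintainer can judge what the results
mean and where the method's assumptions end.

## Frames and conventions

* **Sensor frame (S):** X lateral, Y frontal (direction of progression),
  Z vertical when the foot is flat — the mounting convention for a device on
  the instep. **Global frame (G):** Z up, gravity `g = 9.81 m/s²` along −Z.
* **Pitch** is the elevation of the sensor's forward (Y) axis above the
  global horizontal plane, `pitch = asin(R[2,1])` in degrees, range
  [−90°, 90°]. Sign: positive = toe-up (dorsiflexion). Consequently the
  heel-strike of a stride sits near a pitch *maximum* (heel down, toe up)
  and toe-off near a pitch *minimum* (push-off, toe down). Both assignments
  are verified against the simulator's ground truth.
* Yaw is unobservable without a magnetometer and is fixed to zero at
  initialisation. All reported metrics (pitch, per-stride displacement
  norms, path lengths, clearance) are invariant to global yaw.

## Calibration model

`calibrated = Scaling · Misalignment · (raw − bias)` per sample and sensor,
with the time axis rescaled as `t_true = t_nominal × clock_error`. The order
(bias-subtract → misalign → scale) follows the parameter naming of the file
dialect; any consistent convention reproduces calibrated outputs given
matching parameter files. The scaling matrix carries the unit conversion
(a.u. → m/s² or rad/s). The exact algebraic inverse
(`invert_calibration`) is used to produce raw-count fixtures from simulated
SI signals.

Full multi-position parameter *estimation* (static captures in ~20
orientations inside a polyhedral jig, with separate accelerometer, clock and
gyroscope stages) is out of scope; a reduced, experimental form is provided:
gyroscope bias as the mean over an initial standstill, and a diagonal
accelerometer scale + bias fit minimising gravity-norm residuals over static
poses (needs ≥ 6, recommended ≥ 9 poses; solved with `scipy.optimize.least_squares`).

## Orientation: Mahony complementary filter

Per step `i` (Δt from the clock-corrected timestamps):

1. error `e = â × v`, where `â` is the normalised accelerometer sample and
   `v = Rᵀ e₃` the estimated gravity direction in the sensor frame;
2. integral feedback `∫ Ki·e dt`; corrected rate
   `ω = ½(gyr[i−1] + gyr[i]) + Kp·e + ∫Ki·e`;
3. quaternion exponential update `q ← q ⊗ exp(½ ω Δt)`, normalised.

The trapezoidal gyro midpoint makes constant-rate integration exact and the
update O(Δt²) otherwise; `R[i]` is the orientation *at* `time[i]` (the state
before the first update is stored at index 0), which matters when projecting
gravity during fast swings (~5 rad/s at 104 Hz ≈ 0.05 rad per sample).

Defaults `Kp = 0.5`, `Ki = 0.01` (configurable). **Gating:** accelerometer
feedback is applied only while `| ‖a‖ − g | < 0.5 m/s²`. The accelerometer
observes gravity only when the foot is quasi-static; during swing the
specific force is dominated by foot acceleration and feedback would drag the
estimate toward a wrong vertical. With gating, stance and standstill keep
the filter aligned while swing runs on the gyroscope alone. Set
`acc_gate=inf` to disable.

Initial orientation: gravity alignment from the accelerometer mean of the
initial standstill (the recording protocol prescribes ~30 s), as the minimal
(yaw-free) rotation taking the measured gravity direction to vertical. The
same standstill provides the gyroscope bias estimate that is subtracted
before filtering; if motion is detected inside the requested window the
window is shortened with a warning.

Convergence note: from a deliberately wrong initial orientation, integral
windup during the transient gives a small overshoot that decays on the slow
time scale Ki/Kp; a 20° error still settles within 0.5° over a 30 s
standstill. The pipeline avoids the transient entirely by initialising from
the standstill mean.

## Gait segmentation

Angular-rate magnitude is smoothed by a 0.05 s moving average (suppresses
single-sample threshold crossings), then:

* **still**: runs below 0.2 rad/s lasting ≥ 1 s (debounce chosen so a
  foot-flat dwell of ordinary length, ~0.3–0.5 s, can never be mistaken for
  a standstill);
* **walking bout**: a segment between still intervals containing at least
  one sample above 1.41 rad/s;
* **foot-flat**: runs below 0.5 rad/s inside a bout lasting ≥ 0.05 s.

Events: for each window between consecutive foot-flat dwells of a bout,
toe-off is the pitch minimum and heel-strike the subsequent pitch maximum;
windows with monotone pitch (no interior extrema) yield no stride.
Toe-strike / heel-off are the boundaries of the following dwell. Strides are
chained heel-strike to heel-strike, so a bout with k usable windows yields
k − 1 strides and the partial first and last cycles are discarded by
construction. The event ordering HS < TS < HO < TO < next-HS is validated
per stride; violations name the stride index.

## Strapdown integration and ZUPT

Gravity-free global acceleration `a_free = R a_S − (0,0,g)` is integrated by
the trapezoidal rule (v(0)=0). Zero-velocity anchors are placed at the
midpoint of each foot-flat dwell — the instant the foot is most reliably
stationary — and at both endpoints of every still interval (`endpoints`
policy for dwells available). Drift correction subtracts, between each pair
of consecutive anchors, the straight line through the raw velocity at those
anchors; before the first and after the last anchor the anchor value is
subtracted as a constant. Two exactness properties follow algebraically and
are enforced bit-exactly: corrected velocity is 0 at every anchor, and any
drift affine in time vanishes identically between anchors — in particular a
constant acceleration error (e.g. a small residual tilt leaking gravity)
produces a linear velocity error and is cancelled *exactly*.

Velocity is corrected per axis (not per magnitude). A second trapezoidal
integration gives position; the vertical coordinate is then re-anchored to
zero at every anchor the same way, so clearance is measured from the local
ground level of each stride rather than from an altitude-drifting baseline
(disable with `rezero_vertical=False`).

## Stride metrics

For a stride with events HS, TS, HO, TO, next-HS and `ST = t_HSnext − t_HS`:
load = (TS−HS)/ST, foot-flat = (HO−TS)/ST, push = (TO−HO)/ST,
swing = (HSnext−TO)/ST, each ×100 — summing to 100 by construction.
Cadence = 60/ST; stride length = horizontal-plane distance between the
stride's endpoint positions; speed = length/ST; 2D/3D path lengths =
cumulative sample-to-sample displacements (so path3d ≥ path2d ≥ length);
clearance = maximum vertical excursion during swing (TO → next HS), from
the re-anchored vertical; angles = pitch at TO and HS. Stride boundaries are
HS-to-HS, consistent with the phase decomposition.

**Median filter:** keep a stride iff `0.36·median ≤ length ≤ 1.4·median`,
bounds inclusive, median over all detected strides before removal. For the
unimodal length distributions of straight-line gait the filter is a no-op on
its own output (idempotent); adversarial bimodal sets can defeat
idempotence, which is why the bounds convention is documented rather than
assumed. Aggregation uses the sample standard deviation (n−1 denominator; 0
for a single stride); walking time is the recording span minus still
intervals; "number of steps" in the metrics-file dialect counts strides of
the instrumented foot.

## Clinical scoring

Timed SPPB items are rounded to two decimals before binning and bins are
half-open at the printed edges, so every rounded value falls in exactly one
bin: gait (4-m time) — incapable → 0, > 8.70 s → 1, ≥ 6.21 → 2, ≥ 4.82 → 3
(4.82 s itself scores 3), else 4; chair — incapable or > 60.00 s → 0,
≥ 16.70 → 1, ≥ 13.70 → 2, ≥ 11.20 → 3, else 4 (so 11.19 s scores 4).
Balance: +1 for side-by-side ≥ 10 s, +1 for semi-tandem ≥ 10 s, tandem +2
above 10 s or +1 at ≥ 3.99 s. Fried criteria: weight loss > 4.5 kg;
exhaustion ≥ 2 days/week; low activity < 3 h/week (men) or < 1 h/week
(women); slowness and weakness below sex/height/BMI-stratified cut-offs
(height ≤ 164/152 cm and BMI ≤ 26.4 kg/m² boundaries inclusive); an
incapable 4-m walk counts as slow; grip is the maximum over all attempts and
hands. Index 0 = robust, 1–2 = prefrail, ≥ 3 = frail; any unresolved
criterion leaves the index undetermined rather than defaulting to 0. GDS
(1–7) and TUG are validated and recorded without a scoring rule.

Missing data carry two distinct sentinels end to end: `incapable` (attempted,
could not perform — scores 0 where the instrument says so) and `-` (not
collected) — never conflated with numeric zero.

## Synthetic gait simulator

Each bout is: initial standstill (default 30 s, matching the recording
protocol) → n gait cycles → final standstill (10 s). A cycle is a *moving
window* of duration (1−f)·T followed by a *foot-flat dwell* of f·T
(f = 0.35 default). Within the moving window (normalised u ∈ [0,1]):

* horizontal advance: minimum-jerk profile `10u³ − 15u⁴ + 6u⁵` scaled to the
  stride length (zero velocity *and* acceleration at both ends);
* vertical: quartic hump `256u⁴(1−u)⁴` scaled to the clearance (peak at
  u = 0.5, zero height/velocity/acceleration at the ends);
* pitch: two compact-support bumps, a toe-down bump on [0, 0.6] (peak −35°
  at u = 0.3 — the true toe-off) and a toe-up bump on [0.45, 1] (peak +20°
  at u = 0.725 — the true heel-strike). The supports overlap so the
  angular-rate magnitude does not dip below the foot-flat threshold
  mid-swing; the peaks fall outside each other's support, so the true event
  times are exactly the bump peaks.

The rotation is pitch-only, so the exact body rate is the pitch rate on the
lateral axis and the specific force is `Rᵀ(a_free + g e₃)` in closed form.
White noise (defaults σ_acc = 0.05 m/s², σ_gyr = 0.005 rad/s) and constant
biases (0.02–0.05 m/s², 0.001–0.002 rad/s per axis) are added on top;
per-stride times and lengths are drawn N(1.1 s, 0.05 s) and N(1.0 m, 0.05 m),
clamped positive. Everything is deterministic given the seed.

Defaults describe a slow, regular elderly gait (cadence ≈ 55 strides/min,
speed ≈ 0.9 m/s). What the simulator does **not** emulate: turning, stairs,
shuffling or festinating gait, double-support mechanics of the
non-instrumented foot, soft-tissue artefacts, temperature drift, or
magnetic disturbance. Passing tests therefore demonstrate the correctness of
the signal-processing chain under the stated sensor model, not clinical
validity on pathological gait.

Ground truth includes the continuous event times, per-stride times/lengths/
clearances/angles, the true pitch, trajectory, velocity and gravity-free
acceleration series; a self-consistency test checks that numerically
differentiating the true trajectory reproduces the noise-free sensor
streams to discretization accuracy.

## Problem sizes and tolerances

End-to-end validation uses 20-stride bouts (recovery: mean stride time
within one sample; stride length and clearance within 2% noise-free, 10% at
default noise) and 100 six-stride bouts for the phase-sum conservation
check; these sizes keep the full suite and the acceptance script within a
few seconds on one CPU while exercising every stage. ZUPT exactness and the
calibration-vs-oracle comparison are asserted at machine precision (≤ 1e-12);
rotation orthonormality at 1e-6. Fixture files use the 104 Hz device
conventions; the reader accepts both 104 Hz and 128 Hz dialects.

## Known limitations

* Heading drift is uncorrected (no magnetometer); long bouts map to curved
  2D paths, but per-stride displacements and path lengths are unaffected.
* The stride filter's idempotence is a property of unimodal length
  distributions, not a theorem for arbitrary input.
* The reduced calibration estimator fits no misalignment and assumes the
  poses are truly static.
* Event detection presumes a detectable foot-flat phase; toe-walking or
  continuous-roll gait would defeat the dwell-based segmentation.
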