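# Methods

This note documents the models, conventions and numerical choices behind
`strokekin`, and what the synthetic-data experiments do and do not
demonstrate.

## Frames and conventions

Three right-handed frames are used: the earth frame (ECS: x = magnetic
north, z = up, y completing the triad), one body frame per rigid segment
(BCS), and one sensor frame per node (SCS). Quaternions are scalar-first
Hamilton quaternions; `q` maps body vectors to the parent frame via
`q ⊗ [0, v] ⊗ q*`. Euler angles follow the intrinsic Z–X–Y sequence (yaw
about z, pitch about x, roll about y) — the factorization under which the
accelerometer-tilt initialization `pitch = asin(a_y/|a|)`,
`roll = atan2(−a_x, a_z)` is exact.

A static accelerometer measures specific force, the body projection of
`(0, 0, +g)` (a level sensor reads +1 g on z). The simulator, the EKF
observation model, its Jacobian and the initializer all share this
convention; a round-trip test pins it.

The geomagnetic reference defaults to `[0.30, 0, −0.45]` gauss — a
mid-northern-latitude field of ≈0.54 gauss with a ≈56° downward dip. Only
its direction matters to the filter; the east component is zero by
construction because the wearer faces magnetic north at calibration.

## Magnetometer calibration

Hard-iron offset and soft-iron distortion are estimated by algebraic
least squares on the 9-parameter general quadric (unit-norm constraint,
smallest singular vector). The soft-iron correction is the symmetric
square root of the recovered quadratic form, rescaled so the mean corrected
field magnitude equals the mean raw magnitude — the calibration reshapes,
it does not invent field strength. Degenerate clouds (coplanar directions,
indefinite quadric) are rejected with a diagnostic. Under random
symmetric-positive-definite distortions with eigenvalues in [0.8, 1.25] and
offsets up to 0.5 gauss, the corrected magnitudes have a coefficient of
variation below 1%.

Only the magnetometer is ellipsoid-calibrated; gyroscope bias is estimated
online by the filter, and accelerometer scale errors are out of scope.

## Orientation EKF

* **State**: quaternion + gyro bias (7 states). The quaternion is
  propagated one first-order step per sample,
  `q ← normalize(q + T/2 · q ⊗ [0, ω − b])`, with `Φ = I + F·T` and
  `F = ∂ẋ/∂x` derived analytically from the kinematic equation.
* **Process noise**: quaternion block `(T/2)² σω² Ξ(q)Ξ(q)ᵀ` with
  `Ξ(q)` the rate-injection matrix; bias block `σωb² T I₃` (random walk).
  Defaults σω = 0.04 °/s (the gyroscope's resolution floor),
  σωb = 0.002 °/s/√s — both configuration-exposed, as no canonical values
  exist for this hardware class.
* **Observations**: stacked `[mag; accel]` body projections of the two
  reference vectors, with `R = diag(σ_mag² I₃, σ_accel² I₃)`
  (σ_mag = 0.005 gauss, σ_accel = 0.02 g). The measurement Jacobian is
  analytic (homogeneous quadratic form in q, so finite differences match it
  to machine precision); bias columns are zero.
* **Hygiene**: the quaternion is renormalized and P re-symmetrized every
  cycle; these invariants are asserted over 10⁴-step randomized runs.
* **Timing**: the gyroscope sample at index i−1 is treated as the mean
  rate over [t_{i−1}, t_i]; the update at index i uses the concurrent
  accelerometer/magnetometer sample. Misaligning these by one sample
  produces a rate-proportional lag (≈1° at peak stroke rates), which is why
  the ordering is fixed in `run_fusion` and covered by the zero-noise
  identity test.
* **Initialization**: the first second of each recording (the wearer
  standing still, arms down, facing north) is averaged into the
  tilt/compass attitude; the same window defines the constant mounting
  quaternion `sbq`, so arbitrary fixed sensor mounting cancels exactly in
  `beq = seq ⊗ sbq*`.

The accelerometer model contains gravity only. During vigorous strokes the
real instrument also senses limb acceleration; the filter treats that as
observation noise. The simulator likewise omits translational acceleration
by default, so the reported accuracy bounds the orientation pipeline, not
the disturbance rejection of a sprinting athlete — the main caveat when
transferring numbers to field data.

## Body model and joint angles

Seventeen segments (pelvis root, waist, chest, neck, head, and per side
upper arm, forearm, hand, thigh, calf, foot) form a tree; lengths are
standard anthropometric fractions of standing height (upper arm 0.186·H,
forearm 0.146·H, thigh 0.245·H, calf 0.246·H, trunk 0.288·H split evenly
between waist and chest, head+neck 0.182·H, hand 0.108·H, foot 0.152·H),
each overridable per segment. Six sensor nodes (pelvis, chest, both upper
arms, both forearms) suffice for upper-limb analysis; a 10-node layout adds
thighs and calves. Uninstrumented segments inherit the parent's
orientation.

Angle conventions are pinned so typical values read naturally: the elbow
angle EF is the interior angle at the elbow (straight arm = 180°, stroke
range roughly 120–175°); shoulder flexion SF is measured from the
trunk-down direction (arms at the sides = 0°, stroke range roughly
20–110°). The production path computes angles vectorized from segment
direction vectors; a test proves it equal to frame-by-frame forward
kinematics.

## Stroke metrics

Cycles are delimited by prominent peaks (≥20° prominence, ≥0.5 s spacing)
of the side's shoulder-flexion channel — the channel with the largest range
of motion, hence the most robust landmark. Summaries are per-cycle
MAX/MIN/ROM/MEAN, reported mean ± SD (n−1) across cycles; curves are
time-normalized to 101 points. Symmetry is the Pearson correlation between
a channel's mean curve over left-stroke cycles and its contralateral
mirror over right-stroke cycles. Phase durations come from contiguous
entry→pull→exit→recovery label runs; two propulsion ratios are reported —
propulsion/cycle (the reading under which representative published
durations give ≈62%) and propulsion/recovery — because the field uses both.

## Wavelet scattering

The transform is 1-D: dyadic Morlet wavelets ψ_j centered at ξ·2⁻ʲ
(ξ = 3π/4, bandwidth ratio 0.4, J = 3 scales) plus a Gaussian low-pass with
unit DC gain, all normalized so the Littlewood–Paley sum stays ≤ 1 — which
makes the transform nonexpansive and keeps per-order energies bounded by
the signal energy. Orders are capped at 2 and only frequency-decreasing
paths (j₂ > j₁) are kept, since increasing paths carry negligible energy.
Windows of 20 samples are reflection-padded to 32 for the FFT-based
convolutions; per path the full-resolution coefficient is averaged over
time, giving 7 features per channel and 28 per window. On smooth
joint-angle windows, orders 0–2 retain over 99% of the window energy —
order 0 alone dominates because a 50 ms window of a ~1 Hz movement is
nearly constant.

Windows are cut at the acquisition rate (400 Hz, 50 ms per window). A
decimation factor is configuration-exposed; decimating to 100 Hz makes
windows span 200 ms, longer than the entry/exit sub-phases, so nearly every
window straddles a phase boundary and accuracy drops measurably.

## Classification

Labels are the majority phase within a window (ties break toward the
earlier phase in cycle order). Phases are pooled across sides; windows
labeled by the right-side track present their channels mirrored
(ipsilateral first) so the pooled four-class problem stays well posed. The
split is stratified 80/20 and seeded. Models use fixed, configuration-
exposed defaults: RBF SVM (C = 10), logistic regression, CART decision
tree, KNN (k = 5), random forest (100 trees), each behind a standardizer
fitted on the training split only. Metrics: accuracy, macro
precision/recall/F1, one-vs-rest macro ROC-AUC and PRC-AUC (SVM scores via
softmaxed decision margins), plus the confusion matrix.

## Synthetic data generator

The generator defines the study conditions; its defaults are fixed:

* **Phase durations** (mean ± SD, ms): left entry 124 ± 13, pull 396 ± 28,
  exit 116 ± 15, recovery 388 ± 22; right entry 144 ± 15, pull 299 ± 23,
  exit 95 ± 16, recovery 371 ± 28 — a representative sprint-kayak subject,
  propulsion ≈ 62% of the cycle.
* **Joint extremes** (deg): EFl 145.2–167.0, SFl 25.8–99.9,
  EFr 138.0–174.9, SFr 21.5–110.0 (each channel parameterized on the side
  where that arm draws).
* **Sensor noise** (white, per sample at 400 Hz): gyro 0.04 °/s,
  accel 0.02 g, mag 0.005 gauss — consumer-MEMS resolution scale, matching
  the filter's R. Optional constant gyro bias and hard/soft-iron terms.
* **Mounting**: each node gets a random fixed misalignment (default up to
  5°) to exercise the alignment logic.

Within each phase the angles are cosine-eased between template keypoints
scaled to the configured extremes, so every cycle hits MIN and MAX exactly
and the curve is C¹ at phase boundaries. The elbow is most extended at the
catch and folds through the pull; shoulder flexion bottoms at the end of
the pull and peaks late in the recovery swing. Per-cycle durations jitter
normally (truncated at 25% of the mean). The left and right tracks run
independently with the right offset by one propulsion period, so strokes
alternate; an asymmetry parameter α monotonically distorts the right-side
curve shapes (α = 0 with equal side parameters gives perfectly mirrored
curves, correlation 1). Recordings begin with a 1.5 s static N-pose hold —
the initialization the real protocol requires — and an eased 0.5 s
transition; those samples carry no phase label.

IMU synthesis inverts the fusion model: body rates from the quaternion log
map of consecutive orientations, accelerometer as the body projection of
gravity, magnetometer as the body-projected reference field, plus the
configured bias/distortion/noise. Randomness is split into independent
sub-streams (jitter, mounting, per-node noise) from one seed, so the
ground-truth script is invariant across noise seeds when jitter is zero.

**What passing tests show**: the pipeline's algebra and estimation are
correct (zero-noise identity to millidegrees; r ≥ 0.995 under nominal
noise), and the feature/classifier stage separates phases whose angle
trajectories follow the scripted family. **What they do not show**:
robustness to limb translational acceleration, magnetic disturbance,
soft-tissue artifact, or stroke styles outside the template family —
real-water performance must be validated against an external reference.

## Problem sizes

Default experiment scales, chosen to keep every validation run at desk
scale: the classification experiment uses 100 cycles per side (~105 s of
simulated data, ~7,300 windows); the single-joint validation 60 s at
400 Hz; the energy measurement ≥500 windows. The full test suite runs in
under two minutes on one CPU; the acceptance script in about one.
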