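# Methods

This note documents what `mocapval` computes, the conventions and
defaults it ships with, what the synthetic data do and do not emulate,
and the places where a design had to be chosen among several defensible
options.

## Coordinate and data conventions

All positions are millimetres in a right-handed frame with x =
medio-lateral (+ right), y = vertical (+ up), z = anterior–posterior.
Subjects face the sensor and stand at ~2.5 m (z = 2500 mm); walking
toward the sensor decreases z. Frame indices are 0-based; timestamps are
seconds and strictly increasing. A recording stores one `(n_frames,
n_landmarks, 3)` array plus a boolean missing mask; missing samples hold
NaN. The on-disk format is a flat delimited table
(`time,<lm>_x,<lm>_y,<lm>_z,...`) with blanks for missing cells — chosen
so fixtures are diffable and any spreadsheet can open them.

The 21-landmark common vocabulary (head … foot_r) is the intersection of
what a depth-camera body-tracking SDK and a marker-based reference can
both provide after mapping. The shipped 32-joint → 21 mapping (pelvis →
spine base, spine chest → spine shoulder, …) is a documented default and
editable: the anatomical correspondence used by any particular lab is
site-specific, and mean-of-several-sources rules (e.g. paired pelvis
markers averaged to a spine-base point) are supported for reference
marker sets.

## Preprocessing

Order: gap interpolation → low-pass → resample (reference only) → trim.

- **Gaps.** Missing runs strictly shorter than 56 ms (10 frames of
  marker flicker at 178 Hz) are filled per axis by a B-spline (order 3,
  order reduced when fewer flanking samples exist) fitted through the
  valid samples; the gap duration is measured from the timestamps of the
  missing frames themselves. Longer runs and edge gaps are never filled
  (no extrapolation); fully missing landmarks are reported and left
  missing.
- **Filtering.** First-order 5 Hz Butterworth, applied forward–backward
  per contiguous valid segment. Zero-phase filtering is deliberate:
  transition and step detection downstream must not inherit a phase lag.
  The effective magnitude is the squared single-pass response,
  |H(f)|² = 1/(1 + (f/5)²) up to bilinear warping — 0.990 at 0.5 Hz,
  0.096 at 15 Hz for 178 Hz sampling. Segments shorter than the filter
  warm-up are returned unfiltered and flagged.
- **Resampling.** The 178 Hz reference is linearly interpolated onto a
  uniform 30 Hz grid anchored at its first timestamp. After the 5 Hz
  low-pass the signal is heavily oversampled, so linear interpolation
  has bounded, tested error (< 0.2 % of amplitude for a 1 Hz sinusoid).
  Missingness propagates to any output sample that draws on a missing
  source sample.
- **Trimming/pairing.** Recordings are cut to the intersection of their
  spans; frame pairing is by nearest timestamp within half a sensor
  period, or by interpolating the reference at the sensor timestamps
  when exact pairing is needed (registration, signal accuracy).

## Alignment

Axis normalization is a signed permutation into the canonical frame.
Tilt compensation applies the minimal (axis–angle) rotation that maps a
measured floor normal to +V; a normal with no upward component is
degenerate and rejected. Rigid registration uses the weighted Kabsch
solution (SVD with proper-rotation correction) pooled over all frames of
a calibration window — by default the whole recording and the five trunk
landmarks (spine base/mid/shoulder, hips), which carry the least
tracking noise. The temporal offset is taken from system timestamps
(declared offset); cross-correlation refinement of the spine-base AP
velocity within ±0.2 s is opt-in because near-static tasks give it
nothing to lock onto — a motion check (AP std < 15 mm) forces a flagged
fallback to the declared offset. Event detection operates on uniform
grids internally, because timestamp jitter otherwise leaks
multiplicative noise into finite-difference speed estimates and biases
speed-peak-relative thresholds.

## Clinical parameters

23 canonical parameters across four tasks; all event conventions are
isolated behind the event types so they can be swapped.

- **POCO.** The sway vector runs from the mean of both ankle landmarks
  to the spine base; pitch = atan2(AP, V), roll = atan2(ML, V).
  Range = max − min per component over the whole 40 s task. The 3D
  deflection range is the angular diameter of the (roll, pitch)
  trajectory — the largest angular separation between any two sway
  orientations — which reduces to the component range for planar sway
  (an unsigned "total inclination" range would not). Speeds are mean
  absolute first differences over elapsed time; 3D speed is the mean
  magnitude of the (pitch, roll) velocity vector.
- **SAS.** Transitions are detected from the vertical spine-shoulder
  trajectory: 2 Hz-smoothed speed peaks (rising = stand-up, falling =
  sit-down), bracketed by the 10 %-of-peak-speed crossings with
  sub-frame interpolation; candidate events must move the shoulder by
  ≥ 100 mm, which rejects noise-only excursions on the plateaus.
  Per direction, the mean duration, mean AP range of the spine shoulder
  inside the event window, and mean AP range of the hands (L/R averaged)
  are reported. The 10 % convention is a choice — "time needed to stand
  up" has no universal definition — and is documented as such.
- **SIP.** The step signal per knee is the planar (AP–V) displacement
  magnitude from a grounded baseline: vertical baseline = 10th
  percentile of the vertical coordinate; AP baseline = median AP over
  grounded frames (a plain percentile would land on the lifted extreme
  for the forward lift direction). Steps are maxima with prominence
  ≥ 25 % of the knee's amplitude and ≥ 0.3 s spacing; lift/land are the
  20 %-of-peak crossings. Cadence = events/duration × 60; step time =
  mean interval between consecutive events pooled over sides; stance
  time = same-side land→next-lift; knee amplitude = mean peak
  prominence, in cm. An AP-only variant of the step signal is available
  by flag.
- **SCSW.** Gait speed needs no cycle detection: mean AP speed of the
  spine base over the central 80 % of the walk (the first/last 10 % are
  excluded to avoid initiation/termination bias). Foot contacts are
  maxima of the ankle-ahead-of-pelvis AP excursion signed along the
  progression direction, band-limited at 3 Hz, ≥ 0.3 s apart per side.
  Step duration/length and cadence derive from consecutive contacts;
  with fewer than two contacts the cycle-based parameters are NaN and
  flagged while speed is still returned (short usable walk paths are a
  real failure mode of depth sensors). Arm swing is the sagittal
  inclination of the spine-shoulder→wrist vector; amplitude is half the
  per-cycle (stride) range averaged over cycles and arms; the symmetry
  angle is γ = |45° − atan(A_L/A_R)|/90°, unitless in [0, 0.5]. A step
  count is also computed for the walk but reported as auxiliary; the
  canonical set keeps the stepping-task count only.

## Agreement statistics

Signal accuracy is computed on frame-paired, aligned recordings per
landmark: 3D RMSE; Pearson r per axis binned poor (< .4), moderate
(.4–.7), good (.7–.9), excellent (> .9); zero-mean SNR per axis binned
good (> 10 dB), unclear (−10–10 dB), bad (< −10 dB), capped at +120 dB
when the residual vanishes.

ICC estimators are the McGraw–Wong mean-squares forms on complete cases:
ICC(A,1) (two-way, single measure, absolute agreement) for
between-system accuracy and ICC(1,1) (one-way random) for within-system
repeatability. Negative estimates are reported as-is and flagged, not
floored. SEM uses the pooled SD of all cells of the repeatability matrix
times √(1 − ICC) (with ICC floored at 0 inside the square root only);
SEM% divides by the pooled grand mean — the choice of SD and denominator
is a documented convention, not the only possible one. Bland–Altman
reports bias, bias ± 1.96 SD limits, and the indices of pairs outside
the limits.

The accuracy report uses only the first available measurement per
subject (the next repetition substitutes, flagged, if the first is
missing); the repeatability report uses all repetitions per system.

## Synthetic data

The simulators define the study conditions. Motion primitives are chosen
so that every parameter has a closed-form injected truth, at the price
of biomechanical realism:

- a rigid whole-body sway about the ankle midpoint (sinusoidal pitch and
  roll, feet fixed) for quiet stance;
- logistic vertical trunk profiles with Gaussian AP lean/reach bumps,
  phase-locked to 5 stand-up/sit-down cycles (the 10–90 % rise time maps
  to the 10 %-threshold duration in closed form: duration ≈ 1.655 ×
  rise time);
- anti-phase raised-cosine knee/ankle/foot lifts (default ~65 % duty so
  the knee genuinely rests at its baseline between lifts) for stepping
  in place;
- constant-speed progression with sinusoidal ankle and counter-swinging
  arm oscillation for the walk, clipped to a 4 m usable range ending
  1.5 m from the sensor.

A default subject stands 1765 mm tall with standard anthropometric
segment fractions; population draws perturb the task truths around
healthy-adult magnitudes (sway range ~1.3°, transition time ~1.5 s,
stepping cadence ~88 steps/min, gait speed ~1.1 m/s, arm swing ~25°) and
small within-subject repetition variability (3 % CV) so repeatability
statistics are non-degenerate.

The sensor degradation model applies, in order: a rigid misalignment
(default 6° yaw, ~300 mm translation), a clock offset (0.35 s),
resampling to 30 Hz with optional timestamp jitter (2 ms SD), additive
per-body-region Gaussian noise, a systematic offset, and random dropout
gaps. Noise SDs default to trunk 20, arms 35, knees 55, ankles/feet
80 mm — the gradient observed when depth-sensor landmarks are compared
with optical references — with per-axis multipliers (ML 1.0, V 1.3,
AP 0.7) reflecting that depth-sensor error is worst vertically. The
noise is stationary AR(1) with a 0.2 s correlation time (0 = white):
body-tracking error is temporally correlated jitter, and white noise of
this magnitude would make stationary-task parameters meaningless noise.
Unit noise is drawn independently of the SD scale, so noise sweeps at
different scales share their underlying random draws (common random
numbers) and degradation is monotone draw-by-draw. The degradation
returns the true sensor-to-reference transform for recovery testing.

What the synthetic data do **not** emulate: soft-tissue artefact,
task-dependent noise levels (real stationary-task trunk noise is far
smaller than the global per-class SDs used here, so simulated
quiet-stance parameters degrade much more under the default preset than
a real sensor's would), infrared interference between systems,
pose-estimation failure modes (left/right swaps, occlusion), and
biomechanically coupled joint kinematics. Passing recovery tests
therefore demonstrates the correctness of the pipeline's computations,
not the field accuracy of any physical sensor.

## Numerical choices and degenerate inputs

Strictly increasing timestamps are enforced at construction; rotations
must be proper to 1e-6 in the determinant. The Kabsch solver rejects
configurations whose second singular value collapses (collinear points).
ICC of an all-constant matrix is 1 by convention; zero-variance signals
make Pearson r and SNR undefined (raised, and reported as NaN in batch
reports). Filter segments shorter than the warm-up are passed through
and counted. The BA outlier rule is strict inequality outside the
limits. End-to-end runs isolate per-recording failures: a recording that
raises is excluded with a machine-readable reason and the run continues;
zero usable recordings is a hard failure.

## Problem sizes

The shipped validation study uses 30 simulated subjects × 3 repetitions
of all four tasks per noise preset (0×, 1×, 2× of the default SDs),
~1 080 recording pairs in total, which completes in a few minutes on one
CPU core. Reference recordings are 40 s at 178 Hz for the stationary
tasks and ~3.6 s walks for SCSW.

## Known limitations

- Transition-time and stance-time conventions (10 % / 20 % thresholds)
  are internally consistent but not comparable across studies using
  other event definitions.
- Under heavy noise the speed-peak-relative SAS threshold shortens
  detected transitions (the observed peak is inflated by noise); this is
  a property of peak-relative thresholds generally.
- The stepping cadence (count/duration) and mean step time satisfy
  cadence × step time ≈ 60 only up to a boundary term of one stepping
  period over the task duration.
- Cross-correlation offset refinement assumes visible AP motion of the
  spine base and falls back otherwise; it cannot rescue a wrong declared
  offset on quiet stance.
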