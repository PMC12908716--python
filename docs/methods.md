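# Methods

`fieldgaze` implements the offline quality-assessment chain of a wearable
field study in which a participant explores a real city while carrying a
mobile eye tracker (200 Hz gaze, 30 Hz scene camera at 1600 × 1200 px, a
110 Hz IMU), an RTK GNSS logger, and — for the stationary spatial tasks — a
compass-equipped pointing device. This note records the models, numerical
choices and known limitations of each stage, and what the synthetic-data
generator does and does not emulate.

## Gaze validation

Accuracy against handheld circular targets (diameter 12 cm, viewing
distance 300 cm; both overridable per session manifest) is computed per
annotated video frame in three steps:

1. `offset_px` — Euclidean distance between the frame's mean gaze point and
   the annotated target-box center;
2. `offset_cm = offset_px · target_size_cm / target_size_px`, where
   `target_size_px` is the *larger* side of the bounding box (the physical
   target is circular, so the larger side is robust to partial occlusion);
3. `θ = 2·arctan(offset_cm / (2·viewing_distance_cm))` in degrees of visual
   angle.

The per-frame gaze point is the arithmetic mean of all gaze samples whose
timestamps fall in the frame's half-open exposure interval
`[f/fps, (f+1)/fps)` — the natural reading of "averaged per frame" with
200 Hz gaze against 30 Hz video (≈ 6–7 samples per frame). Per target the
median of the frame angles is taken; the session statistic is the median of
the 10 per-target medians. Because whether published interquartile ranges
are computed across targets or across frames is ambiguous, the report emits
both. Frame windows are reduced to five evenly spaced frames (endpoints
included, round-half-up fractional indices); a window of ≤ 5 frames is used
whole. The even-count median is the midpoint of the two central values.

Start-vs-end stability uses a Wilcoxon signed-rank test on the paired
session medians (differences end − start).

## Exact small-sample tests

Both tests the pipeline relies on run at very small n, so p-values are
exact rather than asymptotic:

* **Wilcoxon signed-rank** — statistic W⁺ (sum of ranks of positive
  differences), zeros dropped, tied absolute differences given averaged
  ranks. For n ≤ 25 the exact null distribution is built by subset-sum
  convolution over the doubled ranks (algebraically identical to
  enumerating all 2ⁿ sign patterns); the two-sided p is
  `min(1, 2·min(P(W ≤ w), P(W ≥ w)))`. Above n = 25 the normal
  approximation with tie correction is used.
* **Spearman rank correlation** — ρ is the Pearson correlation of averaged
  ranks. For n ≤ 9 the two-sided p enumerates all n! permutations of one
  margin; above that, the usual t approximation. A constant margin raises
  (correlation undefined) rather than returning NaN.

Both exact paths are verified in the test suite against literal brute-force
enumeration and, where ties permit, against an independent library
implementation.

## Heading validation

The head tracker's magnetometer-referenced yaw (signed degrees, (−180, 180])
is mapped to cardinal degrees by `mod 360`. A validation reduces a window
of up to 55 samples (0.5 s at the nominal 110 Hz) to a **circular median**:
the sample angle minimizing the summed shortest-arc distances, found by
exhaustive search (exact at n = 55; a linear median would be wrong near the
0/360 wrap). Ties between minimizers resolve to their circular mean, which
reduces to the familiar midpoint convention away from the wrap. The start
window anchors at the recording onset; the end window at the
analyst-supplied timestamp where the tracker is placed back on the
reference compass — locating that event is inherently manual (it comes from
the scene video) and is accepted as manifest input. Errors are signed
shortest-arc differences IMU − compass in (−180, 180]; start-vs-end
comparison reuses the exact signed-rank machinery, excluding sessions whose
end validation is missing (truncated head-tracking recordings occur in
practice).

Magnetometer hard/soft-iron calibration and full 3-D orientation fusion are
out of scope; the yaw channel is taken as given.

## GPS cleaning

Inter-fix speed is great-circle (haversine, mean Earth radius 6 371 000 m)
distance over the time difference, in km/h. Flagging is a **greedy forward
pass**: each fix's speed is computed against the last *retained* fix.
Naive pairwise speeds would also condemn the legitimate fix after a
teleport (positions jump several meters and come back); greedy flagging
condemns only the displaced fix.

Two tiers, with strict threshold comparisons (literally "exceeding" /
"fewer than"):

| rule | strict | relaxed |
|---|---|---|
| fix quality | = 5 (uncorrected single solution) | = 5 |
| satellites | < 5 | < 4 |
| speed | > 6 km/h | > 7 km/h |

If a contiguous strict-flagged run would leave more than 30 s of missing
data — measured as the wall-clock span between the surrounding retained
fixes, i.e. the actual gap that interpolation would have to bridge — that
run alone is re-evaluated once under the relaxed rule and only
relaxed-flagged fixes stay removed; the tier used is recorded per run.
Whether speeds should be recomputed after removal is genuinely open; the
greedy convention above is the package's choice and is exposed by the
per-run bookkeeping. Camera (action-cam) tracks replace the quality /
satellite rules with per-fix precision above the session mean + 3 sd.

Removed interior fixes are linearly interpolated in latitude/longitude
against time at their original timestamps (straight chord in coordinate
space, not along roads); leading/trailing removals are dropped rather than
extrapolated. Cleaning is idempotent, and interpolation provenance is kept
in an `interpolated` column. Movement summaries report mean ± sample sd
(n − 1) of inter-fix speeds, path length and duration; calibration phases
must be cropped first (the manifest's exploration window).

## Clock alignment

The GPS logger and the eye tracker keep independent clocks that disagree by
seconds. The IMU clock is the reference (gaze and IMU share a device); the
offset δ is *added to GPS timestamps*. Anchor mode takes one
analyst-matched event per clock (the serpentine synchronization walk is
designed to be conspicuous in both streams) and returns their difference.

Correlation mode automates the same idea: the GPS course-over-ground
(per-segment initial bearings, undefined while stationary and for segments
shorter than 0.3 m) is compared against the IMU yaw heading interpolated on
its unwrapped continuous curve, at candidate lags that are multiples of the
GPS sample period within a ±15 s window; the score is the mean cosine of
the heading difference and the reported uncertainty is one grid step. The
GPS sample period bounds the achievable precision, hence the grid choice. A
motionless track raises an ill-conditioned error recommending anchor mode.
Clock *drift* (rate error) is not modeled — sessions are ~10 minutes.

## Pointing tasks

True bearings use the initial great-circle bearing
`θ = atan2(sin Δλ·cos φ₂, cos φ₁·sin φ₂ − sin φ₁·cos φ₂·cos Δλ)` on a
sphere. Participant and target coordinates come from the session manifest
(the tasks are stationary; positions were marked on a map), not from the
GPS stream. Compass readings are magnetic; the manifest's east-positive
declination is added to reference true north. Declination is a manifest
constant rather than a geomagnetic-model lookup — the study corrected for a
single location-specific value, and a model dependency would hurt
reproducibility. North trials score against 0° after the same correction.
Signed errors are shortest-arc differences; groups report mean ± sample sd
(n − 1) of absolute errors (the sd convention is a documented choice)
plus circular mean/sd of signed errors, since both signed and absolute
views are informative. Error–confidence association uses the exact Spearman
test on per-target means.

## Synthetic data

Generators are pure functions of (parameters, seed); independent substreams
derive deterministically from the scenario seed.

* **Walk** — correlated random walk on a local planar (ENU) approximation
  re-projected to WGS84; streets are not modeled, since cleaning and
  alignment depend only on kinematics. Speed is AR(1) (φ = 0.8) around
  3.35 km/h with sd 1.15 km/h, clipped symmetrically at ±2 sd
  (mean-preserving; sustained faster-than-6 km/h stretches are not walking
  for this protocol). Heading is a random walk with an 18°/√s step. Position
  integration is zero-order hold, so segment i's course over ground equals
  heading i exactly; RTK-grade observation jitter of 2 cm is added. Faults
  replace single fixes by a displaced position (random direction) and/or
  degraded quality/satellite fields, and every fix carries a truth label.
* **IMU** — 110 Hz yaw on the reference clock: a 2 s stationary hold at the
  initial heading (so the first 55 samples give the validation window a
  stable heading, as when the recording starts with the tracker aligned on
  the compass device), three 360° calibration rotations, a ±75° serpentine
  oscillation (period 5 s), the walk heading, and a stationary tail for the
  end validation; 1° yaw noise. The GPS stream's timestamps are true time
  minus `clock_offset_s`, so the aligner must recover exactly that value.
* **Gaze validation** — 10 targets on a grid in the 1600 × 1200 frame
  (placement is a parameter; the real spatial arrangement of handheld
  targets is not standardized), 5 annotated frames each, 7 gaze samples per
  frame. Per-sample noise is scaled by √7 so the per-frame *mean* gaze has
  exactly the stated sd, keeping the Rayleigh closed form
  (median offset = σ√(2 ln 2)) valid at frame level; ground truth records
  the realized per-frame mean offsets, so validation results can be checked
  to float precision. Annotation boxes are exact (manual annotation error
  is not modeled).
* **Pointing** — compass reading = true bearing − declination +
  wrapped-Gaussian noise; trial order randomized per seed; optional
  monotone confidence link `round(10·max(0, 1 − |e|/scale))`. The folded
  normal mean σ√(2/π) is the oracle for expected absolute error (von Mises
  noise would be an acceptable alternative; the wrapped Gaussian was chosen
  for its closed-form oracles).

What the generator does **not** emulate: urban multipath structure
(faults are isolated, not spatially correlated), satellite-geometry
dynamics, gaze drift or parallax between validations, compass read-out
digitization, and IMU clock drift. Passing tests therefore demonstrate the
*algorithms'* correctness and recovery behavior under the stated noise
models, not field performance on any particular hardware.

## Problem sizes and determinism

Default verification runs use: 13 × 50-frame validation scenes; 20 walks of
~400 s at 1 Hz with 16 faults each; 180 s scenarios for offset recovery at
five injected offsets; 10 000 pointing trials; exhaustive enumeration up to
2⁸ sign patterns and 8! permutations. Reports are byte-identical across
reruns on identical inputs (no wall-clock fields); all acceptance
quantities derive from the single `--seed` argument.

## Known limitations

* The bearing/haversine geometry is spherical; against ellipsoidal (WGS84)
  geodesics, initial bearings can differ by up to ~0.2° at city scale —
  irrelevant next to compass read-out error, but documented.
* The correlation aligner assumes the participant's head points roughly
  along the walking direction; large sustained head-away-from-path angles
  would bias it (the anchor mode is the fallback, as in practice).
* The relaxed-tier re-evaluation is a single pass per flagged run; a
  pathological alternation of marginal runs could in principle merge gaps
  after rescue, which is not re-examined.
* GPX input carries no fix-quality metadata, so only the speed (and, if
  present, satellite-count) rules apply to such tracks.
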