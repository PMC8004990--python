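# Methods

This note documents the models, conventions and numerical choices behind
gaze3d, and what the synthetic-data tests do and do not demonstrate.

## Coordinate frame and data model

All world coordinates follow the recording engine's convention: a
**left-handed** frame, +y up, +z forward, distances in metres. Euler
rotations are degrees applied in Z-then-X-then-Y order about the world axes.
Rotation utilities are implemented directly in this convention rather than
through a right-handed rotation library, so recordings round-trip without
axis flipping; the composition identity (to-local then to-world) is tested to
1e-9.

A recording is a pandas DataFrame with one gaze sample per row. Vector
quantities use `_x/_y/_z` column triples and poses `_pos/_rot/_scale`
triples. Absent values are empty CSV cells; booleans are written
`True`/`False` and parsed case-insensitively. The device-relative timestamp
is written with four decimals because the device clock has 100 ns
resolution, making one millisecond's fourth decimal the native quantum; all
other floats use shortest-repr so that **write → load is bit-identical** (a
tested invariant). Per-eye display projections (`gazePoint*Screen`) are
carried in the schema but not modeled: the display geometry of the headset
is not public and nothing downstream consumes them.

## Timestamp validation

The device nominally samples at 30 Hz (33.33 ms). Empirically, faulty
intervals come in two flavors: exact duplicates (Δ = 0 ms) and dropped
frames (Δ an integer multiple of 33.33 ms). `validate_timestamps` removes
duplicates (keeping the first of each run), counts and retains dropped-frame
gaps (the samples ending them carry valid data), and reports mean/SD of the
remaining *regular* deltas — gap deltas are excluded from the statistic,
which is the only way the post-cleaning mean can equal the nominal frame
time. An optional flag also removes gap-terminating samples; unlike the
default behavior that variant is not idempotent, because each removal
creates a wider join.

## Ray casting and projection

Colliders are spheres, boxes and one-sided-plane quads (hit from either
side, so AOI hits do not depend on authoring orientation) with full
position/rotation/scale poses. Rays are intersected in the collider's local
frame; because the local direction is the inverse-transformed *world unit*
direction, the local ray parameter is the metric world distance, which keeps
nonuniform scales exact. The nearest positive intersection wins; ties
resolve to the lowest collider index. AOI colliders form a separate layer
that is ray-cast independently, mirroring the recorder. The vectorized
`enrich_recording` and the scalar `enrich_sample` share the same casting
primitives; the vectorized path is what the simulator uses.

The head-mounted camera is a pinhole model (head-relative pose, resolution,
focal lengths, principal point). The shipped default intrinsics
(1920×1080, fx = fy = 1460, centered principal point) are a **placeholder**:
real device intrinsics are not published and should be supplied per use
case. Image v grows downward.

## Pre-processing

*Gap fill* linearly interpolates origin, direction (re-normalized) and gaze
point across maximal invalid runs whose bounding valid samples are at most
`max_gap_duration` ms apart (default 75 ms, roughly two dropped frames plus
margin). Validity for anchoring is `gazeHasValue`, not scene-hit status.
Filled samples are flagged in a `gapFilled` provenance column so event
detection can exclude them. Edge runs are untouched.

*Noise reduction* replaces each valid sample's gaze point and direction by
the component-wise mean or median over the valid samples in a centered
window of N samples (odd, ≥ 3). The window shrinks at the edges so length is
preserved; invalid samples pass through and never contribute. The lower
median is used for even member counts (deterministic). Directions are
re-normalized. The gaze origin (head position) is intentionally not
filtered. Whether the original analysis package filters points, directions
or both is unspecified; filtering both is the conservative choice since
either may feed event detection.

## Fixation detection

All three detectors work on gaze *points* viewed from the recorded gaze
origins — the world-centered data paradigm — rather than on directions
alone, so varying fixation depth is handled naturally.

**I-VT.** Per sample, velocity = angular distance between the gaze points of
the first and last sample inside a centered window (default 20 ms), seen
from the window's mean origin, divided by their time difference. At 30 Hz
the 20 ms window contains only the sample itself, so the immediate
neighbours are used — the documented fallback for data sparser than the
method's origin assumed. Samples ≤ 30 °/s (default) are fixation samples;
runs become events. Boundary samples of a fixation see half a saccade step
in their window, so one sample per side may be eroded relative to ground
truth; this is an estimator property, not an implementation artifact (the
exactness test uses slow 5-sample saccades, for which the boundary velocity
provably stays below threshold).

**I-DT.** A window spanning at least `window_duration` ms (default 250) is
initialized at the current sample; while its dispersion exceeds the
threshold (default 1.0°) it advances one sample; otherwise it extends right
until the threshold breaks, the window minus the breaking sample becomes a
fixation, and the next window starts at the breaking sample. Data ending
mid-extension yields a final fixation; stretches shorter than the window
yield none. Dispersion is the **maximum pairwise angular distance** among
the window's gaze points from the window's mean origin — the published
description says only "angular dispersion distance", so this is the one
place the implementation may deviate from the VR implementation it follows;
max-pairwise was chosen as the strictest of the common definitions. The
implementation is verified against a literal brute-force transcription of
the loop on 1000 random streams.

**I-AOI.** Maximal runs of valid samples sharing one AOI name (from the
real-time gaze-to-AOI mapping or supplied labels) become candidates; runs
shorter than `min_duration` (default 100 ms) are discarded.

**Post-processing.** Adjacent fixations merge when the gap is < 75 ms
(default) and the mode condition holds: centroid angle ≤ 0.5° measured from
the mean of the two events' mean origins (I-VT), combined dispersion ≤ 1.0°
(I-DT), or identical AOI (I-AOI); merging recomputes the event from the
union of samples and repeats to fixpoint. `discard_short_fixations` keeps
events with duration ≥ `min_duration` (boundary inclusive, default 60 ms).
Defaults follow the classic velocity/dispersion literature and are all
configurable.

Invalid samples are labeled `gap`, never `fixation`, and split candidate
events unless bridged by gap fill first.

## Quality metrics

Per target: accuracy (cm) is ‖mean gaze point − target‖ × 100; accuracy
(deg) is by default the mean of per-sample angles between the origin→point
and origin→target rays, with a `centroid` variant (angle of the mean point)
exposed for sensitivity analyses — the per-sample mean is inflated by
per-sample noise, while the centroid variant converges to the pure
systematic offset as n grows, which is why the parameter-recovery test uses
it. Precision is the SD (ddof = 1) of per-sample distances (cm) / angles
(deg) to the mean gaze point; RMS is available as an option since both
definitions circulate in the quality literature. `mean_distance_cm` is the
mean distance from the mean origin to the gaze points, feeding the
small-angle conversion θ = tan⁻¹(O/d) used when viewing distance varies.
Report values round half-up to two decimals. World units are metres;
centimetre outputs are a fixed ×100, with no unit autodetection.

The minimum target size S = 2(O + 2σ) follows the 2D-Gaussian 95%-coverage
rule; it is exactly homogeneous of degree 1 and monotone in both arguments
(tested).

## Synthetic gaze simulator

The simulator generates the three standard evaluation settings. The 3×3
grid is constructed **from the stated angular eccentricities** (edge 12.13°
on the axes, corner 18.25° on the ±45° diagonals, at the grid distance): a
uniform rectangular lattice cannot satisfy both angles simultaneously, so
the angles win and the lattice spacing is derived. The grid plane is a quad
scene collider; each target carries a sphere AOI collider (angular radius
configurable, default 2°).

Measured gaze = true gaze perturbed by (a) one session-constant rotation of
`offset_deg` at a random azimuth, applied in each direction's local frame so
the angular error is exactly the configured offset (modeling calibration
error), then (b) per-sample isotropic noise: rotation by |N(0, σ)| degrees
at a uniform azimuth. Saccades are minimum-jerk angular sweeps
(s(τ) = 10τ³ − 15τ⁴ + 6τ⁵) over a configurable duration (default ~67 ms);
their samples carry ground-truth `saccade` labels, replacing manual
annotation. Walking is sinusoidal forward/backward head translation
(default ±0.2 m at 0.25 Hz) with the grid rigid to the head; any accuracy
degradation while moving is an *input* (larger offset/noise), not an
emergent effect, since no mechanism for it is established. The
vestibulo-ocular setting yaws the head sinusoidally (default ±30° at
0.25 Hz) about the bearing to a world-fixed 1 cm sphere 15 cm above a 75 cm
table while the eye counter-rotates; the head rotates in place, so the
configured head-to-target distance is reproduced exactly. A large backing
quad through the sphere center catches noisy rays, as the tabletop scene
does in practice. Head-motion amplitudes are documented guesses exposed in
the config; no published values exist.

Relative timestamps lie on the exact 1000/rate grid, then quantize to
0.0001 ms (the device clock quantum) — hence the mean inter-sample delta
matches 1000/rate to 1e-4 ms rather than exactly. Dropouts blank a random
fraction of samples; duplicate timestamps are injected by repeating rows and
dropped frames by deleting interior rows, with the fault positions recorded
in the ground truth. All randomness flows from one seeded generator
(default seed 42); identical configs are bit-identical.

What the simulator does **not** emulate: pupil/eyelid physiology, blinks,
smooth pursuit, device-specific error anisotropies, slippage, or the
vergence-accommodation behavior of real displays. Passing tests therefore
demonstrate the correctness of the analysis chain under the stated noise
model, not device performance on real participants.

## Problem sizes and statistical checks

The parameter-recovery check uses 20 seeded sessions of ~10⁴ fixation
samples each (offset 1.0°, noise SD 0.3°): the seed-mean centroid accuracy
must fall within 3 standard errors of the injected offset, and the mean
measured precision within 5% of a 10⁶-sample Monte-Carlo estimate of the
distance-to-centroid SD under the same noise model (the folded-normal
eccentricity model has no tidy closed form; the oracle is direct
simulation). The I-DT equivalence check runs 1000 random streams of ≤ 200
samples against the pure-Python brute force. These sizes keep the full test
suite under a minute while leaving comfortable statistical margins.

## Pipeline

`run_pipeline` chains validate → preprocess → detect → evaluate from one
YAML/JSON config and writes events, metrics and a manifest (version,
parameters, seed, input SHA-256 hashes — no wall-clock data, so outputs are
byte-identical across runs). When a detect stage ran, evaluation is
restricted to samples inside detected fixations — the automated counterpart
of removing saccade samples before computing accuracy, which would otherwise
be contaminated by transition samples. Without ground truth, samples are
attributed to the nearest target by visual angle; this heuristic is
appropriate for calibration-style scenes with well-separated targets and is
not a general AOI mapper.

## Known limitations

* Single combined gaze ray only (as the device reports); no per-eye rays,
  hence no vergence-based depth.
* Display-screen projections are unpopulated; camera intrinsics default to a
  placeholder.
* The nearest-target evaluator assumes separated targets; overlapping AOIs
  need the I-AOI route.
* `drop_gap_samples=True` validation is not idempotent (documented above).
* The simulator's degradation-while-moving is configured, not mechanistic.
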