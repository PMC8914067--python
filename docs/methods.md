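# Methods

## The measurement model

The task being quantified is rapid lateral tongue movement: the
participant, mouth half-open, moves the tongue repeatedly between the
two mouth commissures as fast as possible for at least five seconds.
The tongue's per-frame position is reduced to a single symbol — `L` or
`R` for which side of the mouth midline the segmented tongue centroid
falls on, `U` when no tongue is detected — and all kinematic features
are functions of this location record. The reduction assumes the mouth
midline is fixed within a clip, which is why one union crop per video
(rather than per-frame crops) is used throughout.

A *dwell run* is a maximal block of consecutive same-side frames. A
*sweep* runs from the midpoint of one dwell to the midpoint of the next:
the tongue passes the mouth centre mid-dwell, so each half-dwell belongs
to the adjacent sweep. Consequently `n_sweeps = n_runs − 1`, and both
movement directions count. Half-run boundaries are kept as exact
fractional halves (no rounding): sweep counts are unaffected and
durations are unbiased. Counting both directions is the reading
consistent with healthy adults producing on the order of 27 sweeps in
five seconds; counting only one direction would halve that.

An *error* is a dwell abnormally longer than average — a stalled
movement (confusion about direction) or a spasm. The rule is
operationalised as: pool the run lengths of both sides, compute their
mean and sample (n−1) SD, and flag runs longer than mean + k·SD with
k = 2 by default. With fewer than two runs or zero spread no run is
flagged. Error-flagged runs still contribute their sweeps: errors are
counted, not excised. The per-side-versus-pooled choice and the value of
k are genuinely open parameters of the method; pooled with k = 2 is the
default because a two-SD exceedance is the conventional outlier cut and
pooling is more stable at the short run counts a 5-s clip yields
(10–30 runs).

Undetected frames (`U`) are handled conservatively: a gap of at most
`gap_tolerance_frames` (default 3, i.e. 0.1 s at 30 fps) flanked by the
*same* side is absorbed into that dwell; any longer gap, or one with
discordant flanks, is dropped, and same-side runs left adjacent by a
dropped gap are concatenated. An undetected stretch therefore never
fabricates a transition, which keeps the sweep count a lower-bound-style
estimate under detection dropout. A record with no detected frames at
all is a quality failure, not a zero-sweep measurement.

## Video pre-processing

* **Trim**: the first `floor(5 · fps)` frames; fractional-frame
  remainder dropped. Shorter clips are rejected (re-record) rather than
  padded.
* **Stabilization**: inter-frame camera motion is estimated per
  consecutive pair; the cumulative trajectory is smoothed with a
  centred moving average (default window 30 frames ≈ 1 s) and each
  frame is warped by the smooth-minus-raw difference, so slow intended
  motion survives while jitter is removed. The default motion model is
  translation only, estimated by phase cross-correlation with 0.1-px
  upsampling — sufficient for handheld/laptop shake. An affine model is
  available: Shi–Tomasi corners, coarse translation pre-alignment, ILK
  optical-flow refinement, RANSAC affine fit (identity fallback with a
  warning when fewer than four features track). Translation corrections
  are applied as integer-pixel shifts with edge-replicated borders:
  this avoids interpolation blur and makes an already-static clip pass
  through bit-identically. Frame count, dimensions and frame rate are
  never changed.
* **Resize**: optional fixed target height with aspect preserved and
  width rounded to the nearest even integer. The pipeline default keeps
  the input resolution; all location decisions are made in fractions of
  the crop width, so features are scale-invariant.

## Regions of interest

Face detection is attempted once per frame; misses are recorded, never
interpolated, and a clip with more than 20 % missing detections is
rejected (the task protocol requires the full face visible in every
frame; frame-level tolerance below that threshold is this package's
choice). The per-frame boxes are collapsed by the union rule —
componentwise minima of the lower corners and maxima of the upper
corners — into one crop used for every frame. Mouth boxes are built from
mouth-corner landmarks expanded by 15 % of the face-crop dimensions
(the tongue protrudes past the lip corners), then unioned the same way.
Left/right refer to image space; the participant's anatomical sides are
mirrored, and every feature is symmetric under that flip.

No pretrained face or tongue network is bundled. Detection and
segmentation are interfaces; the bundled implementations are the
ground-truth (sidecar) detector for synthetic clips and a
chroma-threshold segmenter (hue 300–355°, saturation ≥ 0.5,
morphological open/close of radius 1, largest connected component,
frames with foreground below 0.5 % of the crop treated as
tongue-absent). On real recordings a trained segmentation model would
replace the chroma backend via `ExternalMaskBackend` or a custom
backend class.

## Statistics

Single cases are compared against a normative sample summarised as
(mean m, sample SD s, size n) with `t = (m − x)/(s/√n)`, df = n − 1,
two-tailed Student-t p. The sign convention is positive when the case
scores *below* the reference mean. Group comparisons use the
pooled-variance two-sample t-test on summary statistics. Manual-versus-
automated validation uses Pearson's r with the usual t-based p value.
Multiple comparisons are handled by Bonferroni division; in the report
builder the family defaults to the number of single-case tests against
the control group (21 for the bundled cohort: seven patient blocks ×
three features), reported at four decimal places. SDs are treated as
sample (n−1) SDs throughout. The bulbar-impairment rule interprets the
"≤ 11" cut-off as the ALSFRS-R *bulbar sub-score* (range 0–12); the
total score (0–48) reading would classify nearly no one and does not
match the cohort's five impaired limb-onset patients.

## The synthetic generator: what it does and does not emulate

Fixtures render a flat background, a skin-tone face ellipse with eye
blobs (trackable structure for stabilization), a near-neutral dark mouth
rectangle, and a tongue ellipse of hue 330° jumping discretely between
two stations at ±25 % of the mouth width from the midline, on an
alternating dwell schedule. Pause insertions lengthen chosen dwells
(ground-truth errors); jitter applies seeded integer translations with
edge-replicated borders. Ground truth (per-frame side, boxes, sweep
count, mean duration, error count) is derived from the realised
schedule by the same half-dwell arithmetic and outlier rule the
kinematics stage defines, making round-trip tests exact by
construction of the *rules*, while the video path (rendering, I/O,
stabilization, cropping, segmentation, centroid logic) is exercised for
real.

What passing these tests shows: the geometry, record extraction and
feature arithmetic are correct, and stabilization at up to 8 px of
jitter leaves features untouched. What it does not show: robustness to
real-world segmentation noise, lighting, lip/tongue colour overlap,
out-of-plane head rotation, or gradual (non-discrete) tongue motion —
those depend on the detector and segmenter backends used in deployment.
Default generator conditions mirror the task's study conditions: 30 fps,
~5 s schedules, dwells of 3–15 frames (sweep rates spanning impaired to
healthy), jitter 0–8 px.

## Numerical choices and degenerate inputs

* Mask centroids use the pixel-centre convention (x + 0.5); a centroid
  exactly on the midline inherits the previous frame's side (`U` on the
  first frame).
* A clip with no sweeps has `mean_sweep_duration_s = None` (flagged
  absent), never zero.
* Uncompressed AVI is the lossless interchange format (bit-exact
  round trips for fixture tests); MP4/MOV input is dispatched to
  imageio and requires an ffmpeg plugin in the environment.
* CSV outputs round floats to 4 decimal places so repeated runs are
  byte-identical.

## Bundled example cohort

`tonguekin/data/` carries a small published-style ALS cohort as three
CSVs: per-patient kinematic feature values with their comparison group,
reference-group summaries (16 healthy controls, 8 limb-onset patients,
10 patients overall), and clinical scores (ALSFRS-R total and bulbar
sub-score, CNS-BFS, disease duration). It drives the statistics layer's
tests and the acceptance script. Raw per-participant sweep counts for
the control group are not available, so control-group statistics enter
only as summaries; correlation-based validation against manual counts
therefore cannot be reproduced from bundled data and is exposed as the
`pearson_validation` function for users with their own ratings.

## Known limitations

* The chroma reference segmenter is not a tongue detector for real
  video; it exists to isolate the kinematic logic from segmentation
  quality.
* Sweep counting assumes the discrete-side model; extremely slow
  movements that straddle the midline for many frames would need the
  midline dead-band this package does not implement.
* The error rule's k = 2 threshold is a convention, not a fitted value;
  sensitivity analyses should vary `KinematicsParams.error_sd_multiplier`.
* Jaw-movement tracking and fasciculation analysis (still-tongue task)
  are out of scope.

## Problem sizes

The test suite and acceptance script use 20 random clips (~50–160
frames each at 256×192) for the round trip, six jittered/plain twin
pairs for stabilization adequacy, and 1,000 random records for the
brute-force cross-check — sizes chosen so the full check runs on a
laptop in well under a minute per stage while covering the schedule
space densely.
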