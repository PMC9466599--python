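# Methods

This note documents the models, parameter choices, and numerical decisions
behind `nematrack`, and what validation on synthetic data does and does not
establish.

## Synthetic plate videos

The generator renders elongated dark bodies on a bright plate at the
instrument scale: 40 µm/pixel, 8-bit grayscale, background intensity 200,
body intensity 110 (contrast 200:110 ≈ 1.8:1, above the 1.6:1 floor a
bright-field rig needs for reliable segmentation).  Defaults are desk-scale
— 256 × 256 px (10.24 mm square), 10 frames/s, ≤ 60 s — so the test suite
runs in minutes; the instrument's full resolution and frame rate are
reached purely through configuration.

**Body model.**  Each worm is a capsule along an 11-point-resampled
sinusoidal midline: arc length equal to `body_length` (default 1.0 mm,
tip-to-tip), maximum width `body_width` (80 µm), lateral undulation
amplitude 0.08 mm with 1.5 wavelengths along the body, phase advancing with
distance travelled.  The half-width tapers to near zero over the outer 15%
of the body at each end.  Rendering is anti-aliased: each pixel's intensity
interpolates between background and body by its coverage (1 px signed-
distance ramp), emulating optical blur; hard-edged rendering would quantize
centroid positions to the pixel grid in a way real optics do not.

**Motion.**  A persistent random walk: per frame the heading receives a
Gaussian perturbation scaled by `(1 − heading_persistence)·2·√dt` rad
(default persistence 0.9), the centre advances by `speed·dt`, and the arena
boundary reflects.  Each tap sets an arousal state to
`arousal_multiplier − 1` (default multiplier 2.0) which decays
exponentially with time constant 90 s; speed is baseline × (1 + arousal).
The 90 s constant makes activity still clearly elevated 30–40 s after the
last tap of the train — the aroused scoring window — while the calm window
at 275–295 s is unaffected by taps delivered at 300 s onward.  With this
decay, the expected aroused/calm speed ratio for multiplier 2.0 is ≈ 1.7
(1 + e^(−35/90)), which is what the end-to-end recovery finds.

**Ground truth.**  Per worm per frame: the coverage-weighted centroid of
the rendered body (the image centroid an ideal detector would report),
commanded speed, true length, and the 11-point midline.  Recording the
image centroid rather than the abstract midline centroid makes
position-accuracy comparisons measure the detector, not the difference
between two centroid definitions.

**What the generator does not emulate:** bacterial lawn texture, eggs and
progeny, omega turns and reversals, body-shape change with age, lid
reflections, illumination drift.  Passing recovery tests therefore
demonstrates the correctness of the algorithms under clean but realistic
geometry and noise, not robustness to every artefact of real plates.

## Segmentation

The background estimate starts as a verbatim copy of the first frame.
Worms present at start are burned in and become detectable as they move
off their ghosts; with the default decay rates the burn-in is roughly 5–10
s (about one body length of travel plus ghost decay), and tests measure
detection only after it.

Update rates: `alpha_dark = 0.08`, `alpha_light = 0.02` per frame at 10
frames/s.  The asymmetry (dark changes accepted four times faster) quickly
absorbs shadows and debris while vacated bright areas recover slowly.  The
dark rate trades off two failure modes: too fast and an animal's body is
absorbed into the background in the interval between its arrival and its
first detection (at 0.25/frame a worm vanishes within ~5 frames); too slow
and transient dark artefacts persist as false detections.  0.08 keeps a
fresh worm above the fill threshold for ~15 frames, ample for detection,
and was tuned on simulator fixtures with known ground truth.

Detection thresholds are fractions of the local background — robust to
absolute illumination — with `detect_contrast = 0.30` and `fill_contrast =
0.15` against a true body deficit of 45%.  Components are filled 8-connected
from 4-connected seed groups, filtered to [20, 3000] px.  The outer contour
is traced with Moore boundary following, clockwise from the
topmost-leftmost boundary pixel.  Centroids are intensity-weighted over the
component plus a 1 px dilated ring: edge pixels below the fill threshold
still carry part of the body's deficit, and including them recovers
sub-pixel position (frame-to-frame centroid jitter drops ~4×, which is what
makes 0.2 s windowed speeds accurate at 40 µm pixels).

The background freezes within 3 px of every detection (rebuilt per frame,
so departed regions unfreeze), keeping stopped animals at full contrast
indefinitely — verified by a scripted stop-motion test.

## Tracking

Frame-to-frame linking is greedy nearest-centroid within `max_step`
(default 0.5 mm per frame interval).  A blob that is the nearest feasible
choice of two or more records is a collision: the claimants are terminated
and the merged blob starts a fresh record (no identity is maintained
through contact).  A record whose exclusively-feasible blobs number two or
more has split and is likewise terminated.  An area jump beyond
`area_ratio_max = 1.8` against the record's running mean also terminates
(merge suspected).

Joining asks whether one animal could account for two fragments: gap in
(0, 30 s], end-to-start distance ≤ 1.0 mm/s × gap (about twice a vigorous
aroused crawl, so feasibility is generous but bounded), and mean areas
within 50%.  Fragments are visited in start-time order; the
earliest-ending eligible chain wins, ties broken by distance; each chain
takes one predecessor and one successor.  On randomized small instances the
greedy pass achieves the same number of joins as exhaustive search (tested
against a brute-force enumerator); the pass is idempotent and never
increases the record count.

Counting animals: the number of joined records overlapping a window,
after the quality filters below — animals are counted only when they move
enough to be measured.  At realistic plate density (40 animals on a 41 mm
arena, matching 40–60 on a 5 cm plate) the filtered count lands within
±10% of truth; at several times that density merged pairs inflate it.

## Per-animal metrics

**Midline.**  The two contour points of extremal turning sharpness
(computed over chords of ~1/12 the contour length, second endpoint
constrained ≥ a quarter-perimeter away) split the outline into two arcs;
points paired by fractional arc length give midpoints, resampled to 11
equidistant points whose polyline length is the body length.  The traced
contour runs through boundary-pixel centres, so each spine end stops about
half a pixel short of the true tip, plus a sub-pixel loss from the tapered
tip; both ends are extended 0.9 px along the end tangent — calibrated once
on rendered bodies of known spine length.  Accuracy on a 25 px body:
individual frames mostly within 10% (tight S-postures cost more), means
over ≥ 50 frames within 3%; a 50 × 6 px rectangle measures 2.00 mm ± 5%
at any rotation.  Outlines with fewer than 12 contour points or under 3 px
of area carry no length.

**Speed** is the centroid displacement over a centred 0.2 s window using
nearest available samples, one-sided at track ends — exact for uniform
motion.  Windowed-speed MAE on simulated plates spanning calm and aroused
locomotion is < 10% of the mean true speed; at a purely calm 0.15 mm/s the
noise floor of ~0.015 mm/s approaches that bound, which is one reason the
scoring pipeline median-filters before taking maxima.

**Filters.**  Animals kept only if followed ≥ 30 s and displaced ≥ 1.5
mean body lengths.  Displacement is the maximum centroid excursion from the
start (configurable to a path integral, which jitter inflates).  Records
with no measurable length cannot pass the movement criterion and are
rejected.

## Window scores and aggregation

Scores per animal per window: mean length, mean area, mean speed, and the
maximum of the 5-point running median of speed (replicate-padded ends;
maxima require ≥ 5 samples).  The median filter's output maximum is
bounded by the raw extrema (property-tested), so a single-sample spike
cannot set the score.  Plate summaries report n, mean and SEM (sample SD,
n − 1) per window; a plate enters condition curves only when ≥ 3 animals
were measured in the designated counting window (default: aroused, i.e.
the animals actually measured for the headline metric).  Condition
timecourses bin by session start time into [k·6 h, (k+1)·6 h) and average
across included plates with SEM across plates; a bin with no included
plate emits no point — absence of data is never rendered as zero.

The calm window is 275–295 s.  One figure caption in the source protocol
describes a 10 s calm window at 275 s; the running text says 275–295 s in
two places, so 20 s is the default and the window is configurable.

## Lifespan

Overlays place the three inverted snapshots in R, G, B with no
normalization, so each original frame is recoverable bit-exactly and
motionless regions satisfy R = G = B.  Colorfulness of a region is the mean
channel range — 0 for gray, 255 for a saturated single-channel patch.
Automated death calling — the first overlay index after the last colorful
one at the death site — is provided as an experimental assist; the
reference procedure remains scoring the overlays by eye, as colorfulness at
a site can also come from a neighbour passing through.

The Kaplan–Meier estimator is the standard product limit over event times;
interval-scored deaths enter at the interval midpoint (configurable to
either endpoint; which convention instrument scorers used historically is
not recorded, and at 6 h sessions the difference is below a third of a
day).  Censored records leave the risk set without an event.  The
implementation is cross-checked against `lifelines` and against the
empirical survival function in the uncensored case.  Median recovery on
exponential cohorts is validated on the mean of five n = 300 cohorts
because a single median at n = 300 has ~8% sampling noise of its own.

## Variability and power

`decompose_variability` computes, per timepoint: the CV of per-experiment
means about the population mean (between-experiment), and the CV of plate
scores after rescaling each experiment's mean onto the population mean
(within-experiment plate).  Sample SDs throughout; scale-invariant by
construction.  The stochastic-sampling null normalizes each animal score by
its plate mean, pools, and draws ≥ 1000 fictitious plates of n animals with
replacement; the SD of fictitious-plate means is the CV expected from
sampling alone and scales as n^(−1/2) (fitted exponent −0.5 ± 0.05).

The cohort generator draws lognormal effects with unit mean — lognormal so
scores stay positive at large CVs — independently per (experiment,
timepoint), per (plate, timepoint) and per (animal, plate, timepoint).
Drawing experiment effects independently per timepoint models
session-level batch variation and makes the per-timepoint CV estimable by
averaging across sessions; real experiment effects are temporally
correlated (a whole experiment runs warm, say), which the generator does
not emulate — with only 10 experiments, a single scalar effect per
experiment would leave ~24% sampling noise on any CV estimate regardless
of implementation.

Power analysis: the minimum detectable shift is
`(Φ⁻¹(tail) + Φ⁻¹(power)) · σ₀` with σ₀ the measurement SD of the
peak-to-day-3 ratio as a fraction of its mean, obtained by naive error
propagation from the peak and day-3 CVs.  Those CVs (defaults 0.055 and
0.077) are measurement-level — the CV of a 4-plate condition mean — so the
Monte Carlo generator scales per-plate CVs by √(plates per condition).
The default generator realizes the normal-ratio model exactly
(day3 = peak × ratio, ratio drawn normal at the propagated CV, fold change
shifting only the mean): a plain ratio of independent normals is skewed
and over-dispersed enough to cost ~7 points of power relative to the
analytic value, which would conflate distributional mismatch with
implementation error.  The default test compares the condition set-mean
ratio against a null estimated by resampling fictitious same-size sets
from the 30 control plates (normal tail at α).  Because the null mean and
SD are estimated from finite data, the realized null rejection rate is
slightly above α (~0.07–0.09 at 30 control plates) while the power at the
analytic fold change is ~0.78–0.80; the analytic formula assumes the null
known.  A `test="rank"` variant runs a plate-level Mann–Whitney (exactly
calibrated under the null); it needs a ~1.31× fold change for 80% power at
30-vs-4 plates, since individual plates are twice as noisy as a 4-plate
mean.

All Monte Carlo draws come from numpy's PCG64 generator with one stated
seed per run; equal seeds give bit-identical videos, tables and rates.

## Pipeline

The batch pipeline (segment → track → choreograph → summarize) depends
only on files on disk plus the configuration.  Each stage records a
SHA-256 parameter hash in a manifest; a rerun with identical inputs and
parameters skips every stage and leaves outputs byte-identical.  Failures
raise a `StageError` naming the stage and leave earlier outputs untouched.
Outputs are plain text: a line-oriented blobs format
(`frame t_s blob_id area cx cy n_contour x1 y1 ...`) with a JSON parameter
sidecar, and CSVs whose column names carry units (`x_mm`, `t_s`,
`area_mm2`).

## Problem sizes used in validation

Tests and the acceptance script simulate at desk scale chosen to keep the
whole suite within minutes: 256 × 256 px plates at 10 frames/s for
detection, length and speed recovery; two full 530 s protocol plates for
the arousal contrast; one 1024 × 1024 px, 60 s plate with 40 animals at
realistic density for count recovery; 10 × 20-plate cohorts for variance
decomposition; 2000-repetition Monte Carlo for power.  Quantities with
sampling noise are validated at tolerances consistent with those sizes.

## Known limitations

- No identity through collisions; heavily crowded plates inflate counts.
- The midline is undefined for tightly coiled postures and loses a few
  percent on strong S-bends.
- Automated death calling is experimental; neighbours crossing a death
  site produce late calls.
- The set-level Monte Carlo test is mildly anticonservative under the
  null (estimated-null effect, quantified above).
- Shadows, lawn texture and multi-animal occlusion beyond simple merging
  are out of scope.
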