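# Methods

This note documents the models and procedures implemented in `ethotrack`,
the parameter choices that matter, what the synthetic data does and does not
emulate, and the numerical decisions a maintainer would want written down.

## Coordinate and unit conventions

Image coordinates are 0-based pixels, origin top-left, x rightward,
y downward. Arena templates live in millimetres with the same orientation.
Within a tube, position is reported as millimetres from the food end along
the tube axis; the tube midline used by the yoked trigger is half the tube
length (12.5 mm for the default 25 mm tube). Velocities are dimensionless
*relative units*: displacement per nominal frame interval, measured in body
lengths (2.5 mm). One relative unit therefore means "one body length per
nominal frame interval", which puts the movement and walking thresholds at
1.0 and 2.5 regardless of the frame rate actually achieved.

## Registration

The three fiducials are segmented by thresholding dark pixels (halfway
between the image minimum and median), filtering connected components by
equivalent radius (within ±50 % of the expected mark radius) and circularity
(4πA/P² ≥ 0.6), and scoring each candidate by circularity minus relative
radius error. Sub-pixel centers are darkness-weighted centroids over a
padded bounding box, which uses the anti-aliased mark edge. With more than
three candidates, all triplets are scored by the maximum deviation of their
sorted side-length ratios from the template triangle's (tolerance 0.08);
no acceptable triplet raises an ambiguity error.

Correspondence orders both triangles' vertices by the length of the
opposite side; the template triangle must be scalene (adjacent normalized
side lengths differing by ≥ 1 %). The 2×3 affine is solved exactly from the
three point pairs (zero residual), and the per-ROI mm-per-px is recomputed
from the fitted scale √|det| rather than trusted from the template.
Registration runs once on the first frame and is held fixed: the arena is
mechanically locked, so tracking camera motion would only add noise. An
affine (rather than similarity) map is used because three points determine
it exactly and it absorbs mild shear from imperfect mounting.

Measured on the built-in 20-tube template under 100 random placements
(rotation ≤ 10°, translation ≤ 30 px, pixel noise SD 2), the worst ROI
corner RMS error is ≈ 0.02 px — the error budget is dominated by fiducial
centroid noise, amplified by the lever arm from the fiducials to the far
ROI corners.

## Tracking

Per ROI, the background model is seeded with the per-pixel median of the
first `n_init = 5` crops. If the fly never moved during those frames the
median still contains it, which would both hide the fly (zero difference)
and later seed a permanent ghost; any high-contrast fly-sized dark
component is therefore inpainted with the median of the remaining pixels
before tracking starts.

Foreground is the signed difference `background − frame` thresholded from
above: the imaging polarity is fixed (the animal is dark on a backlit
field), and the signed difference — unlike the absolute one — cannot lock
onto the bright residue left where a previously parked fly stood. The
threshold defaults to Otsu's method over the first ≤ 50 difference images,
clipped to [20, 120] grey levels so that an empty or low-contrast start
cannot produce a degenerate threshold. Components smaller than 30 % of the
nominal body area (π·1.25·0.5 mm² at the ROI calibration) are discarded as
noise.

The update `B ← (1−α)·B + α·F` with `α = 0.05` is applied only outside the
detected blob dilated by 3 px. The selective update is what makes long
sleep bouts trackable: a naive update absorbs a parked fly into the
background within ~1/α frames (this is asserted in the test suite), while
the selective one preserves it indefinitely and still adapts everywhere
else to slow illumination drift.

Centroid, ellipse axes and orientation derive from intensity-weighted
central moments of the difference blob; axes are reported as 4√λ (the full
axes of a uniform ellipse with those second moments), with 1/12 px² added
to the diagonal as the finite-pixel correction, and the orientation modulo
180° because second moments cannot distinguish head from tail. With
multiple blobs, the one nearest the previous position wins (largest blob
when there is no history). Blob-free frames carry the previous position
forward flagged `is_inferred`; inferred points are excluded from velocity
computation, so occlusion gaps neither create nor hide motion.

On 20 synthetic single-fly videos (300 s each, frame rates drawn from
1–5 FPS with 10 % interval jitter, pixel noise SD 5, 0.1 mm/px), the median
centroid discrepancy against ground truth is ≈ 4 µm with no frame off by
more than 0.02 mm — far below a body length. This reflects the clean
synthetic imaging model (no shadows, reflections, occlusions or body-pose
changes); real-video accuracy is bounded by annotation uncertainty and
should be expected on the order of a tenth of a body length.

## Behavior classification

Corrected velocity between consecutive non-inferred points i−1, i:

    v_i = (‖Δxy‖ mm / 2.5 mm) · (Δt_nominal / Δt_i)

Ten-second tumbling windows aligned to the trajectory start take
`max_velocity = max v_i` (steps assigned by their end time) and
`cum_distance = Σ ‖Δxy‖`. The label rule is
immobile `< 1.0` ≤ micromovement `< 2.5` ≤ walking, with boundary values
assigned upward. Windows with no steps are flagged missing and inherit the
previous window's label; leading missing windows stay unlabelled. The
walking threshold of 2.5 is configurable, as is the movement threshold.

Consensus ground truth requires ≥ 3 annotators per window and a strict
majority; windows without one are excluded as ambiguous rather than forced.
Per-class "detection accuracy" is per-class recall — the fraction of
consensus windows of a class that the classifier also assigns to it —
because that is the natural reading of "detection" for a per-class figure.

Feature screening uses random-forest variable importance
(scikit-learn, 200 trees, seeded). On generator data the ranking
`max_velocity > cum_distance` is stable across forest seeds precisely
because micromovement is in-place activity: it shares low walked distance
with quiescence but not its velocity signature, so cumulative distance
cannot separate immobile from micromoving windows while max velocity can.

## The synthetic arena

Imaging model: background 200/255, tube interior 215 (backlit), fiducials
and fly 40, additive Gaussian noise clipped to [0, 255]; the fly is an
anti-aliased 2.5 × 1 mm filled ellipse; anti-aliasing is 4×4 supersampled
coverage. Frame intervals are `nominal × (1 + U(0, jitter))` with the
nominal rate in the 1–5 FPS regime of real-time tracking.

Within a behavior program, per-step corrected velocities follow the state's
activity pattern:

| state | pattern | event velocity (rel. units) |
|---|---|---|
| walking | sustained, persistent heading (3 % reversal/step), turns at tube ends | N(3.5, 0.3) |
| micromovement | in-place bursts at 0.15 Hz, one forced per 8 s, over quiescent baseline | N(1.75, 0.2) |
| immobile | baseline jitter \|N(0.05, 0.05)\| with rare posture shifts at 0.15 Hz | U(0.3, 0.9) |

Event velocities sit ≥ 3.3 SD from both thresholds, the forced burst
guarantees every full micromovement window at least one supra-threshold
event, and posture shifts are capped strictly below 1.0 — so the generator's
labels are recoverable by the threshold classifier by construction, and the
classifier-recovery study measures the pipeline, not distributional overlap.
Axial displacement is `v · 2.5 mm · Δt/Δt_nominal` with direction flipping
at the tube ends (flipping, not mirror reflection, so the step magnitude —
and hence the realized velocity — survives wall encounters). A small
mean-reverting transverse jitter (SD 0.02 mm, clamp ±0.8 mm) keeps the fly
near the tube centerline.

What the generator does **not** emulate: body-pose deformation, wing/leg
motion, shadows and reflections, uneven illumination, condensation, food
meniscus, multi-fly occlusion, lens distortion, or appearance variation
between individuals. Passing tests therefore demonstrate the correctness of
the geometry, the estimator chain and the event semantics — not robustness
to real-video nuisance factors.

## Trigger engine

Predicates are trees over four leaves and three combinators (grammar in the
README). `behavior_is(s, d)` is true iff the state equals `s` at the
current sample and the current uninterrupted run started at or before
`t_now − d`; the run start is maintained incrementally in O(1) per sample.
`position_crossed` requires a strict sign change of (x − boundary) across
the two most recent samples: landing exactly on the boundary and retreating
is not a crossing. Empty histories evaluate to false, never to an error.
Evaluation is sliding — once per processed frame — matching a real-time
loop at 1–5 Hz.

The incremental evaluator is verified exhaustively against a naive
re-scan-from-scratch evaluator over all 3,244 distinct predicate trees of
depth ≤ 3 built from a fixed four-leaf set, at every step of 200-step
random state/position sequences (≈ 1.3 M comparisons, zero tolerance), plus
randomized deeper trees via property tests.

Closed-loop semantics: when the trigger fires inside the armed schedule, an
event is emitted at the triggering sample, samples with
`t ∈ (event, event + 5 s]` are suppressed (the stimulus motion artefact
would corrupt tracking), and the behavior continuity clock restarts at mask
end — a fly immobile throughout therefore receives one stimulus per
`trigger + mask` seconds (144 in an hour for 20 s + 5 s), which is checked
against an independent discrete-event step-through. The clock reset is the
conservative choice: the fly's state during the mask is unobserved, and a
stimulus is presumed arousing. Rotation stimuli carry the conventional
(60°, 0.12 s) parameters as metadata only; hardware is abstracted to the
event log.

## Virtual fly and the three-arm deprivation design

The virtual fly is a minimal homeostat stepped at 10 s: sleep pressure
gains 1 unit/h awake and loses 2 units/h asleep; the per-step probability
of falling asleep is `0.005 + 0.02·pressure`, suppressed ×0.3 in light;
spontaneous waking is 0.008/step, boosted ×3 in light (mean dark sleep
bout ≈ 21 min, comfortably past the 5-minute sleep criterion). Awake steps
are walking/micromovement/quiet-rest with probabilities 0.4/0.4/0.2;
walking moves N(0, 4 mm) per step in a 25 mm tube, so midline crossings are
frequent. A stimulus wakes the fly and forces one walking step; it does not
change pressure. These constants were chosen once to give a plausible
baseline (roughly two-thirds of the night asleep, consolidated bouts) and
a pressure scale on which a lost night is large; they are not fitted to any
dataset.

The experiment runs 27 h from lights-on: 12 h baseline day, stimulation
armed through the 12 h night, rebound read out in the first 3 h of the next
day; n = 20 flies per arm, three arms from the same model (deprived: 20-s
immobility trigger; yoked: midline crossing; mock: never stimulated), all
driven through the same closed-loop engine used on tracked data. Rebound is
per-fly minutes asleep (5-minute rule) in the readout window, compared
pairwise by rank-sum test. Across 10 seeded replicates the deprived arm
exceeds mock in all 10 (median p ≈ 10⁻⁷) and the yoked arm in none, with
both stimulated arms receiving hundreds of rotations per night — the
design's signature: rebound follows lost sleep, not stimulation per se.

## Statistics

- Bootstrap: percentile CI of the mean over individuals, 5,000 resamples,
  95 % level, seeded. Empirical coverage on standard-normal samples
  (n = 50, 500 repetitions) is ≈ 93–95 %; the small undercoverage is the
  known finite-n behavior of the percentile method.
- Wilcoxon rank-sum: two-sided; exact null for tie-free samples with
  n ≤ 25, otherwise the tie-corrected normal approximation (via
  `scipy.stats.mannwhitneyu`). Verified against full enumeration of the
  null for n ≤ 10 (agreement to machine precision).
- Stimulus counts report mean ± sample SD (ddof = 1); the population/sample
  choice is a convention, stated here because nothing upstream fixes it.
- Boxplot whiskers follow Tukey's rule: the most extreme data within
  ±1.5 IQR of the hinges (hinges = quartiles via linear interpolation).
- Sleep profiles conserve total bout time exactly: Σ(bin fraction × bin
  width) equals summed bout duration, asserted in tests.

## Problem sizes and determinism

The validation studies run at desk scale by choice: 100 registration
placements; 20 tracking videos × 300 s; ≥ 1,000 classification windows;
10-seed feature screening; the full depth-≤3 trigger enumeration on two
200-step sequences; 10 × three-arm experiments with 60 flies each; 500
bootstrap-coverage repetitions. Every stochastic component draws from
`numpy.random.Generator` seeded through `SeedSequence.spawn`, so identical
seeds give bit-identical frames, trajectories and statistics; the
acceptance script derives all study seeds from its single `--seed`.

## Known limitations

Single fly per ROI (no identity maintenance); no lens-distortion model or
continuous re-registration; the renderer's realism limits noted above; the
virtual fly is a design-validation model, not a calibrated sleep model —
its rebound is qualitative, and no quantitative agreement with any animal
dataset is claimed; HDF5 output is optional and CSV is the canonical
round-trip format.
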