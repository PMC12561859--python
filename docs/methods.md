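# Methods

This note documents the models, geometry, synthetic data and numerical
choices behind `periomet`, in the order the pipeline runs.

## Problem setting

In acquired (involutional) ptosis the upper eyelid droops and patients
compensate by elevating the eyebrow. Surgical planning needs objective
periocular measurements: the margin reflex distances MRD1/MRD2 (pupil
center to upper/lower lid margin) and the eyebrow height above the pupil
center at five standard columns (medial brow end, medial limbus, pupil
center, lateral limbus, lateral brow end). The pipeline derives all seven
from two binary masks — visible iris and eyebrow — produced either by the
built-in segmentation networks or by any external annotator.

All images are normalized to left-periocular framing (right-side images are
mirrored), so the medial (nasal) side is image-left by default; the
orientation is configurable everywhere it matters.

## Scale calibration and the pupil-center proxy

Photographs carry no physical scale, so the pipeline uses the horizontal
corneal diameter as a scale bar, fixed at 11 mm (the standard adult value;
individual deviation of ±0.5–1 mm propagates proportionally into every
measurement — a known limitation of the approach). The eyelids typically
cover the top and often the bottom of the cornea, so the visible iris mask
is a chord-bounded region. The full corneal outline is recovered as a
circle fitted to the visible region in three stages:

1. **Minimum enclosing circle** (`min_enclosing_circle`) of the mask's
   boundary pixels — randomized incremental (Welzl-type) construction,
   expected linear time, order-independent, verified against an O(n⁴)
   brute-force oracle. Boundary pixels (foreground with a 4-neighbor
   background, frame border counting as background) are sufficient: every
   convex-hull vertex of the foreground is boundary, so the circle is
   identical to that of the full pixel set. As long as the horizontal iris
   diameter is visible between the lids, the minimum enclosing circle of
   the *continuous* region equals the true corneal circle.

2. **Trimmed least-squares arc fit.** On a pixel grid the enclosing circle
   is supported by a handful of quantized extreme pixels; with both the
   corneal apex and base occluded its vertical position is conditioned on
   half-pixel chord effects and can tilt by several pixels. The estimate is
   therefore polished by an iteratively trimmed Kasa circle fit restricted
   to horizontally exposed boundary pixels (the left/right limbus arcs, not
   the lid margins), with shrinking inlier bands (1.5, 1.0, 0.75 px) and a
   +0.5 px radius correction for the inward bias of boundary pixel centers
   relative to the true region edge. The fit falls back to the enclosing
   circle when ill-conditioned or when the radius drifts more than 15%.

3. **Exact-rasterization run fit.** For the true circle, every
   eyelid-unclipped mask row reproduces the rasterized chord exactly
   (leftmost column `ceil(cx − h(y))`, rightmost `floor(cx + h(y))`), and
   clipped rows are contiguous at the top and bottom of the visible band.
   A local grid search (0.04 px in center-x, 0.03 px in center-y and
   radius) maximizes the longest contiguous run of exactly matching rows;
   the centroid of the top-scoring cluster is the final estimate. This
   exploits the full quantization information instead of treating edges as
   ±0.5 px noise and roughly halves the residual center error of stage 2.
   Masks that are not 1-px-quantized circle rasterizations (e.g.
   block-upscaled network predictions) produce short runs and fall back to
   stage 2.

The circle center is the pupil-center proxy (the anatomical pupil is
invisible under occlusion; the circle center is the only stable reference)
and `mm_per_px = 11 / (2·radius)`.

Accuracy on synthetic scenes: across 1000 scenes spanning the default
severity range, all seven landmarks measured from ground-truth masks track
the closed-form ground truth within 3 px · mm_per_px (99.5% of scenes
within 2 px). The residual tail is information-theoretic, not algorithmic:
interval-arithmetic feasibility analysis of individual scenes shows that
when both lid margins occlude the cornea, the set of circle parameters
consistent with the binary mask can span ~3 px in the error combination
that governs tall brow heights (center-y error plus height/radius times
radius error), so no estimator reading the 256-px mask can do better. The
package's property tests assert the demonstrated 3 px bound.

## Landmark measurement

With circle (c, r) and scale s, 0-based coordinates, y growing downward:

- columns: PC = round(c_x); ML/LL = round(c_x ∓ r) (minus on the medial
  side); MBE/LBE = the extreme eyebrow columns on the medial/lateral side;
- MRD1/MRD2: extremal iris rows within a 3-px band at the PC column,
  distances from c_y clipped at 0. A mask-based MRD cannot be negative
  (a true lid margin below the pupil center is invisible); the
  `occluded_top`/`occluded_bottom` flags record when the lid covers the
  circle apex/base by more than 1 px so downstream consumers can treat the
  value as a lid position rather than a corneal extent.
- brow heights: `(c_y − top brow row within ±2 columns) · s`, vertical
  distances per the reference measurement scheme (not Euclidean from PC —
  the two readings differ off-center; the vertical one matches "height
  above the PC baseline"). A column with no brow pixels in the band yields
  NaN plus a flag, not an exception.

Masks are cleaned to their largest 8-connected component first (speckle
robustness), with a deterministic row-major tie-break. Measurement is
mirror- and translation-invariant and scale-covariant (property-tested).

## Segmentation networks

Two independent binary segmenters (iris, eyebrow), following the separate
annotation protocols of clinical practice. The architecture is an
encoder-decoder with skip connections: a compact depthwise-separable
convolution hierarchy (widths w, 2w, 4w at resolutions 1, ½, ¼; SiLU
activations) and a decoder of 2×2 transpose convolutions with concatenated
skips and a single-channel logit head. Inputs are 3-channel 64×64 (bilinear
resize, [0,1]); masks are nearest-neighbor resampled. The default width is
w = 8 — sufficient for the synthetic task and trainable in minutes on one
CPU; no pretrained encoder weights are bundled (`pretrained=True` raises).

Everything — convolutions, backpropagation, Adam, the loss — is hand-written
numpy (float32, im2col/matmul), which keeps runs bit-reproducible for a
fixed seed on one machine and the package dependency-light.

Training recipe (defaults follow the clinical study): batch size 16, Adam,
BCE-with-logits, initial learning rate 0.005, halved when validation loss
fails to improve by >1e-6 for 10 consecutive epochs (the improvement
threshold and the best-validation-loss checkpointing are this package's
choices; the reference recipe is silent on both), nominal maximum 1000
epochs — the synthetic task converges in well under 30.

Threshold 0.5 on the sigmoid probability map turns predictions into masks
(exposed as a CLI flag).

### Explainability and latency

`saliency_map` backpropagates the summed foreground logit to the input and
reports the max-normalized per-pixel gradient L2 magnitude. `grad_cam`
records activations and gradients at a decoder depth ("bottleneck",
"dec1", "dec2"), weights channels by spatially averaged gradients,
rectifies, upsamples and min-max normalizes. On trained models both
concentrate inside the (dilated) target region on average — asserted
statistically over 20 held-out scenes.

`measure_latency` times the bare forward pass per image (preprocessing
excluded, warm-up passes discarded) and reports mean/median/p90. Absolute
numbers are hardware-dependent context, not assertions.

## Synthetic scene generator

The generator stands in for the IRB-restricted clinical photographs. Each
256×256 scene is defined by `SceneParams` — iris center/radius, quadratic
upper/lower lid curves, quadratic eyebrow arc with thickness, density and
span, skin tone, noise — from which masks and landmarks follow in closed
form. Rendering draws skin with an illumination gradient, sclera, a shaded
iris with dark pupil, a lid fold shadow, per-column hair strokes, and
Gaussian noise. All randomness flows from one integer seed through
SeedSequence spawning, so scene *i* is reproducible in isolation and
datasets are bit-identical across runs.

Key default choices (pixel units on the 256 canvas):

- iris radius 28–36 px, center near mid-frame: mm_per_px ≈ 0.15–0.20,
  a ~40–50 mm field of view;
- MRD1 ~ U(1.5, 3.38) mm and MRD2 ~ U(2.58, 4.5) mm — means exactly
  2.44/3.54 mm, the clinical cohort means. Ptosis severity is
  `1 − MRD1/5.5`, so severity 1 puts the lid at the pupil center. The
  1.5 mm MRD1 floor emulates the cohort's exclusion of severe-ptosis
  images; below it the doubly occluded iris leaves too short a limbus arc
  for sub-pixel circle recovery, and landmark ground truth stops being
  identifiable to rasterization accuracy (see the feasibility argument
  above). Scenes outside the range remain constructible explicitly.
- lid curvature is parameterized as *sag*: the lid drops by
  sag × (apex-to-center gap) across the iris span (upper sag 0.2–0.8,
  lower 0.1–0.5). This keeps the horizontal diameter visible — the
  geometric precondition of circle recovery — and makes heavier ptosis
  come with flatter lids, as drooping lids do.
- the eyebrow ground-truth mask is the ideal arc band; the *image* renders
  only a `brow_density` fraction (0.5–1.0) of its columns as hair strokes,
  so segmenters must bridge gaps as they must for natural hair-density
  variation while ground truth stays analytic. Sparse brows below density
  0.5 were excluded from the clinical cohort and are likewise outside the
  default range.
- half the scenes are stored mirrored with `side = "right"` to exercise
  side normalization.

Geometry ranges are bounded so the invariants (lids ordered over the iris
span, brow band disjoint from the iris, iris inside the frame) hold for
every sample, not just on average; `SceneParams.validate()` re-checks them.

What the generator does **not** emulate: photorealistic texture, eyelashes
(a documented clinical segmentation confound), specular highlights,
glasses, makeup, off-axis gaze, and inter-subject corneal-diameter
variation (the 11 mm assumption is exactly true in synthesis). Passing
tests therefore demonstrate the correctness of the geometry, training
machinery and metrics — not clinical-grade segmentation accuracy, which
requires the real dataset.

## Dataset handling

Manifest CSVs link image, iris mask and brow mask per sample with optional
ground-truth landmark columns. Splitting is image-level by default
(matching the reference protocol's wording): ratios 0.8/0.1/0.1, floor
allocation with remainders to the training split, and a positive test
ratio guaranteed at least one item (612 → 490/61/61; 10 → 8/1/1;
7 → 6/0/1 with a degeneracy warning). An optional patient-grouped mode
keeps all of a patient's images in one split for leakage control, filling
the smallest splits first. Masks are 8-bit 0/255 PNG; any nonzero value
reads as foreground.

## Evaluation

Pixel metrics come from pooled confusion counts; undefined ratios (zero
denominators) propagate as NaN, never silently 0 or 1, so degenerate masks
stay visible in reports. The F1/IoU identity F1 = 2·IoU/(1+IoU) is
property-tested to 1e-12.

Landmark errors: RMSE = √(Σ(a−p)²/n) in mm and MAPE = (100/n)Σ|a−p|/|a|
in %, with the reference value as denominator. Reports are per-landmark
first; the overall RMSE/MAPE are **unweighted means of the seven
per-landmark values** — the only aggregation under which a per-landmark
table reproduces its printed overall means — plus the five-brow-landmark
subgroup mean. Pairs with a missing (NaN) value are excluded per landmark
with counts reported; zero-reference pairs are additionally skipped for
MAPE only (MRD1 is 0 when the lid reaches the pupil center, where relative
error is undefined while RMSE remains valid). Occlusion flags are
advisory and do not exclude pairs by default: an occluded-top MRD1 is
still the clinically defined lid-margin distance.

## Numerical conventions

- Coordinates 0-based, origin top-left, x = column, y = row (downward);
  points are pixel centers; "above" = smaller row.
- Circle solver tolerance 1e-10 relative; near-collinear circumcircle
  guard at 1e-12; brute-force containment tolerance 1e-9.
- Ties: largest component by first row-major foreground pixel; extremal
  rows by topmost; scheduler "improvement" = strict decrease > 1e-6.
- float32 throughout the network; float64 in geometry and metrics.
- Training shuffles with a generator seeded from `TrainConfig.seed`,
  independent of model-init seeds.

## Problem sizes in the shipped tests

The suite trains width-8 models for 30 epochs on 200 synthetic scenes
(20 validation, 20 held-out test) — the scale at which the synthetic task
saturates (held-out IoU ≈ 0.96 for both tasks, against bars of 0.85/0.70)
— and runs all geometry statistics on 100–1000 scenes. These sizes are the
package's demonstration conditions; the clinical study they emulate used
612 images and 1000 epochs on GPU hardware.
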