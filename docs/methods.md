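# Methods

`scintidet` implements a complete lesion-detection workflow for planar
whole-body bone scintigraphy (WBBS): intensity normalization, anterior/
posterior (AP/PA) view fusion, offline augmentation, a pluggable hotspot
detector trained with automated negative mining, and lesion- and
patient-level cross-validated evaluation. Because clinical WBBS cohorts are
not publicly distributable, every stage is exercised end to end on a
synthetic phantom generator that emulates the statistical structure of real
scans. This note records the model, the parameters that matter, and the
design choices made where the design was genuinely open.

## Imaging model and preprocessing

A WBBS acquisition is a 1024 x 512 frame of 16-bit photon counts holding
both planar views. The toolkit treats the two views as side-by-side
1024 x 256 halves (AP left), consistent with a 1024 x 256 per-view
acquisition matrix; a `--layout` override selects a vertically stacked
variant. All box coordinates are 0-based and half-open, so a box's area is
exactly `(x_max - x_min) * (y_max - y_min)` and IoU arithmetic carries no
off-by-one ambiguity.

Scan intensity varies widely between patients (tracer dose, uptake time,
metabolism, injection leakage), so detection operates on normalized 8-bit
images produced in three steps:

1. **Body-range detection.** Row- and column-sum projection profiles are
   thresholded at `tau = 0.01` of the profile maximum; the smallest
   half-open interval whose exterior falls below threshold is the body
   range. The 1% default ignores isolated stray counts; `tau` is
   configurable, and `tau -> 0` reduces to the nonzero bounding rectangle.
2. **Centering.** Each view's body crop is placed centered on a zero
   512 x 950 canvas with no resampling; ground-truth boxes are translated
   by the same rigid offset.
3. **Mean-controlled normalization.** The canvas mean (double precision,
   full canvas including zero background) is driven into the open interval
   `(T1, T2) = (7, 14)` by iterative multiplicative scaling: scale all
   pixels by `midpoint / mean`, clip to [0, 255], round half away from
   zero, re-check (max 10 iterations). The re-check loop exists because
   8-bit saturation can drag the mean back below target. Scaling aims at
   the interval midpoint rather than the nearest bound — the midpoint keeps
   the loop maximally far from both exits, so one iteration almost always
   suffices. The operation is idempotent: once the mean is in range the
   image passes through untouched. Rounding is half-away-from-zero
   everywhere intensities are quantized.

The chest region of interest is a **fixed fractional band of the detected
body height** — rows `[top + 0.10 H, top + 0.45 H)` across the full canvas
width, the same rectangle for both views (the body span is the union of the
two views' placements). This deterministic rule stands in for a learned
chest localizer; the fractions are configurable (`--chest-band`). Boxes
wholly outside the band are dropped; straddling boxes are clipped.

## View fusion

Feeding AP and PA separately discards their spatial correspondence, so the
detector input is a three-channel image: **red** = AP chest, **green** =
left-right-flipped PA chest, **third** = pixelwise red x green product,
rescaled so its mean equals the mean of the two view means. A true lesion
projects to mirrored positions in the two views and therefore lights up all
three channels at one location, whereas single-view artifacts do not. The
product scale is refined by a short fixed-point iteration (<= 5 rounds,
tolerance 0.25 gray levels) because saturating bright hotspot products at
255 would otherwise pull the channel mean more than the 0.5-gray-level
contract allows; on images without clipping the first iteration already
equals the closed-form scale. Ground truth on the fused image is the union
of AP boxes and flipped PA boxes; duplicates are merged only at evaluation
time (IoU >= 0.5 within category), since the merge rule is an evaluation
concern, not an annotation one.

## Offline augmentation

Each fused chest is emitted at six average intensities evenly placed in the
open range (25, 48) — below ~25 faint ribs disappear, above ~48 images
approach superscan ambiguity — and each variant is also emitted mirrored,
multiplying the dataset by exactly 12. The six targets are the midpoints of
six equal sub-intervals (26.917, 30.75, ..., 46.083): uniform over the
range while staying clear of both boundaries, which would otherwise clip.
All three channels are rescaled jointly (one factor) so channel ratios are
preserved; box geometry is untouched by re-leveling. The original image is
*not* additionally emitted, keeping the factor exactly 12.

Augmentation targets CNN-style backends that must see intensity diversity
to become robust to it. The bundled reference backend instead builds
intensity invariance into its features (below), so its training default is
the native-intensity image: re-leveling an 8-bit image can only add
saturation artifacts to a detector that is already intensity-invariant, and
measurements during development showed exactly that (cross-image candidate
AUC drops from ~0.94 to ~0.87 when the classical classifier is trained on
re-leveled copies). `run_shuffles` accepts an `augment_plan` for backends
that want the full x12 set.

## Detector backend

The detector contract is two functions over toolkit types — `fit(images,
config, n_categories) -> model` and `predict(model, image, floor) ->
detections` — registered by name. External one-stage detectors plug in
through an adapter; the published GPU training defaults (150 000
iterations, batch 64, learning rate 0.00261) are stored as adapter metadata
and never executed here.

The **reference backend** is deliberately classical so the whole training
loop runs in seconds per cohort on one CPU:

* **Proposal:** multi-scale difference-of-Gaussian blob detection
  (sigma in {2, 4, 8}, threshold 0.06 on the unit-scaled channel maximum),
  followed by a peak-over-ring contrast gate (>= 12 gray levels), a
  cross-scale NMS at IoU 0.5, and a per-image budget of 150 candidates
  (strongest contrast kept). On phantom chests this recovers ~0.9 of
  ground-truth lesions at IoU >= 0.3.
* **Features (16):** per-channel interior mean/max/std and the ring
  contrast, all divided by the global channel-max mean (intensity
  invariance); log area and aspect; a left/right mirror-symmetry
  correlation (osteoarthritic joint pairs are symmetric, metastases are
  not); normalized position; and a collinearity count over the other
  candidates (post-traumatic rib chains line up along a rib arc).
* **Classifier:** standard-scaled features into an L2-regularized logistic
  regression (background vs. 1 or 2 hotspot classes). The detection
  confidence is the calibrated class probability. Fine-tuning warm-starts
  from the previous coefficients with the feature scaler frozen. Ground-
  truth boxes are added to the training set as positive examples so the
  classifier sees lesion appearance even when the proposal stage misses
  one.
* **Prediction:** propose, featurize, classify; keep the argmax hotspot
  class when its probability strictly exceeds the confidence floor
  (default 0.1); greedy per-category NMS at IoU 0.5; sort by descending
  confidence. Output is monotone in the floor by set inclusion.

## Negative mining and transfer

The training loop needs no manually labeled negatives. A 1-class
(metastasis-only) model is pre-trained on images that each contain at least
one metastasis. Running it over images known to be metastasis-free makes
every detection a guaranteed false positive; all detections with confidence
**strictly greater than 0.1** are harvested, relabeled `normal_hotspot`,
and stored with provenance (model digest, threshold) in a separate store —
ground-truth label files are never mutated. A 2-class model is then trained
on the original metastasis boxes plus the mined negatives, and finally
fine-tuned on the target cohort. Harvesting uses the standard prediction
post-processing (NMS included) so mined negatives mirror deployment-time
false positives. Equivocal target boxes are folded into the normal class at
training time (they are too few to carry a class); at evaluation they are
ignored instead — the `--equivocal ignore|as-normal` switch exposes both
policies.

## Evaluation

* **Matching** is greedy in descending confidence (ties: ascending x, then
  y); each detection claims the unmatched same-category ground-truth box of
  highest IoU >= 0.3. A detection whose only qualifying overlap is an
  unmatched equivocal box is *ignored* (neither TP nor FP; the equivocal
  box is consumed and never counts as a miss). Greedy confidence-ordered
  matching is standard detection-evaluation practice; the test suite
  characterizes it against a brute-force optimal-assignment oracle (exact
  on small instances, >= 95% agreement on 1 000 random ones).
* **Lesion-based** metrics are sensitivity and precision over metastasis
  boxes (per-box true negatives are undefined). Zero-denominator ratios
  are reported as undefined, never as 0, and are excluded from aggregation.
* **Patient-based** metrics call a whole image positive when any metastasis
  detection exceeds a decision confidence (default 0.5, configurable — the
  published workflow does not state its rule), giving sensitivity and
  specificity against the image-level label.
* **Cross-validation:** one *shuffle* = one re-randomized stratified split
  (positives and negatives shuffled independently, dealt round-robin into
  k = 10 folds) with a single held-out tenth, matching the literal
  description of the published protocol; `--full-cv` instead rotates every
  fold through the test position and averages. Aggregates are the mean and
  the *sample* (n-1) standard deviation, rendered at two decimals with
  ties away from zero. (The published +- values are not fully consistent
  with either the sample or the population convention across columns; the
  sample convention is emitted and the discrepancy documented here.)

## Phantom generator

The phantom emulates what the pipeline needs and nothing more: a schematic
body silhouette (ellipse head/torso/pelvis, capsule legs) with elevated
uptake along the spine, eight parametric rib arcs per side, and shoulder/
pelvic/knee joints; the PA view is the left-right mirror with posterior-
weighted spine intensity. Metastases are focal Gaussian blobs (sigma 1.6-5
px, i.e. ~6-22 px box diameter; the true clinical size distribution is
unreported, so this is a free choice) with peak 3-8x the local background,
placed in the chest band with a tight box in each view. Benign confounders
are >= 3 collinear blobs along a rib arc (injury chain) or an
intensity-matched symmetric pair at the shoulders. Optional bladder and
injection-leak artifacts are bright, carry no box, and sit outside the
chest band. Cohort sampling: positives carry 1-5 metastases plus 0-2
benign hotspots, negatives 1-4 benign hotspots; the global gain is
log-uniform in [0.25, 4] so normalization has real work to do; Poisson
noise is applied to the count image last (gamma-camera counting
statistics). Everything is bit-reproducible from the seed.

The phantom does **not** model anatomy, attenuation, scatter, collimator
blur, superscans, or the appearance statistics of real metastatic disease.
Passing property tests therefore demonstrates that the pipeline's
*mechanics* are correct and that mining helps under controlled conditions;
they say nothing about clinical sensitivity or precision, and the published
clinical numbers are reproduced only at the aggregation-arithmetic level.

## Problem sizes and runtime choices

Desk-scale defaults were chosen so the full loop runs comfortably on one
CPU: the bundled demo uses a 30+30 pre-train cohort, a 40-image target
cohort and 2 shuffles of stratified 10-fold CV (~1 minute); the paired
mining ablation uses 5 seeds, a 20+20 pre-train cohort and a 60-phantom
target cohort with a k = 5 stratified split (~3 minutes); property sweeps
use 500 phantoms. Candidate features are computed once per image and
shared between the mined and baseline arms of the ablation, so the two
arms differ only in their labels and classifier.

## Known limitations

* The reference backend's absolute precision at floor 0.1 is modest
  (~0.4-0.8 on phantoms); it is a workbench for the pipeline, not a
  clinical detector.
* Greedy matching can under-count TP by one on adversarial geometry
  (quantified by the oracle tests).
* The chest band is a fixed fraction of body height and will mis-crop
  bodies whose proportions differ grossly from the phantom's.
* DICOM support is read-only, single-frame, MONOCHROME2; de-identification
  is assumed upstream.
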