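# scintidet

A toolkit for **hotspot (lesion) detection in whole-body bone scintigraphy
(WBBS)** — the planar gamma-camera scan acquired after Tc-99m MDP
injection that is the workhorse of bone-metastasis screening in prostate
and breast cancer. It is aimed at researchers building or evaluating
bone-scan CAD pipelines who need the full workflow around a detector:
reproducible preprocessing, anterior/posterior view fusion, an automated
hard-negative-style training loop, and detection-grade evaluation — all
runnable end to end on synthetic phantoms, because clinical WBBS cohorts
are rarely shareable.

## What it implements

A WBBS frame (1024 x 512, 16-bit counts; AP and PA views side by side) is
taken through:

1. **Preprocessing** — projection-profile body detection, centering of
   each view on a 512 x 950 canvas without resampling, and mean-controlled
   intensity normalization: iteratively scale by `((T1+T2)/2)/mean`, clip
   to 8 bits, until `mean ∈ (T1, T2) = (7, 14)`; then a rule-based chest
   crop (rows `[0.10 H, 0.45 H)` of the body height).
2. **Fusion** — a 3-channel chest image: red = AP, green = mirrored PA,
   third = `s · (AP ⊙ PA_flipped)` with `s` chosen so
   `mean(third) = (mean(AP) + mean(PA))/2`. A lesion appears at one
   location in all three channels; single-view artifacts do not.
3. **Augmentation** — six intensity levels uniformly placed in (25, 48)
   plus horizontal mirrors: exactly x12 offline.
4. **Detection** — a pluggable backend contract (`fit`/`predict` over
   toolkit types). The bundled CPU reference backend uses
   difference-of-Gaussian blob proposals and a logistic classifier over
   clinically motivated features (contrast, left/right mirror symmetry,
   rib-line collinearity).
5. **Negative mining** — pre-train a 1-class (metastasis) model on
   positives only; run it over known metastasis-free images so that every
   detection with confidence > 0.1 is a guaranteed false positive; relabel
   those as a `normal_hotspot` class; retrain with 2 classes; fine-tune on
   the target cohort. No negative is ever labeled by hand.
6. **Evaluation** — greedy IoU-0.3 matching (equivocal ground truth is
   ignored, absorbing at most one detection), lesion-based
   sensitivity/precision = TP/(TP+FN), TP/(TP+FP), patient-based
   sensitivity/specificity, and shuffled stratified 10-fold
   cross-validation reported as mean ± sample SD per column.

A seeded phantom generator (body silhouette, rib arcs, focal metastatic
blobs, rib-line injury chains, symmetric joint pairs, bladder/injection
artifacts, log-uniform gain, Poisson noise) makes every stage testable.
See `docs/methods.md` for the full model description and design choices.

## Worked example

Run the bundled desk-scale demo (synthetic 30+30 pre-train cohort, 40-image
target cohort, 2 shuffles of stratified 10-fold CV; ~1 minute on one CPU):

```bash
scintidet cv --config configs/demo.yaml
```

which ends with (exact output, deterministic for this config):

```
 shuffle  lesion_sensitivity  lesion_precision  patient_sensitivity  patient_specificity
       1            0.500000          0.666667                  0.5                  1.0
       2            0.857143          0.500000                  1.0                  0.5
lesion_sensitivity: 0.68 ± 0.25
lesion_precision: 0.58 ± 0.12
patient_sensitivity: 0.75 ± 0.35
patient_specificity: 0.75 ± 0.35
artifacts: scratch/demo_run
```

Each row is one shuffle: the target cohort is re-split into 10 stratified
folds, the mined 2-class model is fine-tuned on 9 folds and evaluated on
the held-out tenth (4 images here, hence the coarse patient-level steps).
`lesion_sensitivity = TP/(TP+FN)` counts metastasis boxes matched at
IoU >= 0.3; `lesion_precision = TP/(TP+FP)` measures how many metastasis
calls were right; the patient columns score the per-image metastasis call.
The final lines are the column means ± sample SD. Artifacts (models, the
mined-negative store, `cv_report.csv/json`, replay digests) land in
`scratch/demo_run/`.

The same loop is available piecewise: `scintidet phantom`, `preprocess`,
`fuse-augment`, `train`, `mine`, `evaluate`, `report` — see `--help`.

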