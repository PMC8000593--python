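# Desk-scale demo: synthetic 30+30 pre-train cohort, 40-image target cohort,
# 2 shuffles of stratified 10-fold cross-validation on one CPU.
base_seed: 1
out_dir: scratch/demo_run
pretrain_positives: 30
pretrain_negatives: 30
target_size: 40
target_positive_fraction: 0.5
t1: 7.0
t2: 14.0
chest_band: [0.10, 0.45]
augment_range: [25.0, 48.0]
augment_levels: 6
augment_flips: true
harvest_confidence: 0.1
iou_threshold: 0.3
decision_conf: 0.5
confidence_floor: 0.1
n_shuffles: 2
k_folds: 10
full_cv: false
backend: reference
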