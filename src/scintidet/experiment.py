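"""Paired ablation: does negative mining reduce false positives?

The experiment trains two detectors per seed under identical conditions —
same phantom cohorts, same candidate proposals and features, same
fine-tuning budget — differing only in whether the pre-trained model went
through the negative-mining stage:

* **mined arm**: positives-only pre-training, harvest of false positives
  from metastasis-free images, 2-category retraining, transfer fine-tuning
  on the target cohort's full labels;
* **baseline arm**: the same positives-only pre-model fine-tuned on the
  target cohort's metastasis labels alone (no mined class).

Both arms are evaluated on the same held-out target fold; the comparison
metric is lesion-based precision of the metastasis category, where an
explicit non-metastasis class should absorb benign hotspots (rib injury
chains, symmetric joints) that the baseline can only call metastases or
miss.  Candidate proposal and featurization run once per image and are
shared by both arms, so "same training budget" is literal.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import detector as det_mod
from ._util import child_seed
from .detector import BackendConfig, predict_from_features
from .evalcv import EvalConfig, evaluate_images, make_folds
from .fusion import FusedImage
from .mining import MiningConfig, harvest_negatives
from .phantom import generate_scan, sample_cohort_config
from .pipeline import prepare_fused
from .preprocess import NormalizationRange
from .scan_io import Category, DatasetManifest, ManifestEntry

__all__ = ["mining_ablation"]


def _phantom_fused(
    patient_positive: bool, seed: int, norm: NormalizationRange
) -> FusedImage:
    cfg = sample_cohort_config(patient_positive, seed=seed)
    scan, ap_boxes, pa_boxes = generate_scan(cfg)
    img = prepare_fused(scan, ap_boxes, pa_boxes, norm=norm)
    return replace(img, source_id=f"abl_{seed}_{int(patient_positive)}")


def _cohort(n_pos: int, n_neg: int, seed: int, norm: NormalizationRange, tag: str):
    items = []
    for i in range(n_pos + n_neg):
        positive = i < n_pos
        img = _phantom_fused(positive, child_seed(seed, tag, i), norm)
        items.append((replace(img, source_id=f"{tag}_{i:03d}"), positive))
    return items


class _FeatureCache:
    """propose + featurize exactly once per (augmented) image."""

    def __init__(self):
        self._store: dict[int, tuple[list, np.ndarray]] = {}

    def get(self, image: FusedImage):
        key = id(image)
        if key not in self._store:
            self._store[key] = det_mod.image_candidates(image)
        return self._store[key]

    def training_arrays(self, images, n_categories: int, metastasis_only: bool = False):
        X, y = [], []
        for img in images:
            cands, Xc = self.get(img)
            gts = img.boxes
            if metastasis_only:
                gts = [b for b in gts if b.category == Category.METASTASIS]
            Xi, yi = det_mod.image_training_examples(img, gts, cands, Xc, n_categories)
            X.append(Xi)
            y.append(yi)
        return np.concatenate(X), np.concatenate(y)


def mining_ablation(
    seeds: list[int],
    n_pretrain_pos: int = 20,
    n_pretrain_neg: int = 20,
    n_target: int = 60,
    k_folds: int = 5,
    norm: NormalizationRange = NormalizationRange(),
    harvest_confidence: float = 0.1,
    eval_config: EvalConfig = EvalConfig(),
) -> pd.DataFrame:
    """Run the paired experiment for each seed; one result row per seed.

    Columns: ``precision_mined``, ``precision_baseline``, their sensitivities,
    and the mined-negative count.  The target cohort is split with a
    stratified k-fold; fold 0 is held out for evaluation in both arms.
    """
    rows = []
    for seed in seeds:
        cache = _FeatureCache()
        backend = det_mod.get_backend("reference")
        bcfg = BackendConfig(seed=seed)
        mcfg = MiningConfig(harvest_confidence=harvest_confidence, seed=seed, backend=bcfg)

        pre = _cohort(n_pretrain_pos, n_pretrain_neg, child_seed(seed, "pre"), norm, "pre")
        tgt = _cohort(n_target // 2, n_target - n_target // 2, child_seed(seed, "tgt"), norm, "tgt")

        # stratified split of the target cohort; fold 0 held out
        manifest = DatasetManifest(entries=[
            ManifestEntry(image=f"{img.source_id}.png", label=f"{img.source_id}.txt",
                          patient_id=img.source_id, cohort="synthetic",
                          patient_positive=positive)
            for img, positive in tgt
        ])
        folds = make_folds(manifest, k=k_folds, seed=child_seed(seed, "fold"))
        tgt_train = [t for t, f in zip(tgt, folds) if f != 0]
        tgt_test = [t for t, f in zip(tgt, folds) if f == 0]

        pre_pos = [
            replace(img, boxes=[b for b in img.boxes if b.category == Category.METASTASIS])
            for img, positive in pre if positive
        ]
        pre_neg = [img for img, positive in pre if not positive]
        tgt_train_imgs = [img for img, _p in tgt_train]

        # shared 1-category pre-model
        Xp, yp = cache.training_arrays(pre_pos, n_categories=1, metastasis_only=True)
        pre_model = backend.fit_arrays(Xp, yp, bcfg, n_categories=1)

        # --- mined arm: harvest -> 2-class retrain -> 2-class fine-tune
        mined = harvest_negatives(pre_model, pre_neg, mcfg)
        mined_imgs = [replace(img, boxes=mined.boxes_for(img.source_id)) for img in pre_neg]
        Xm, ym = cache.training_arrays(pre_pos + mined_imgs, n_categories=2)
        two_class = backend.fit_arrays(Xm, ym, bcfg, n_categories=2)
        Xf, yf = cache.training_arrays(tgt_train_imgs, n_categories=2)
        mined_final = backend.fit_arrays(Xf, yf, bcfg, n_categories=2, init_model=two_class)

        # --- baseline arm: same pre-model fine-tuned on metastasis labels only
        Xb, yb = cache.training_arrays(tgt_train_imgs, n_categories=1, metastasis_only=True)
        base_final = backend.fit_arrays(Xb, yb, bcfg, n_categories=1, init_model=pre_model)

        def held_out_metrics(model):
            per_image = []
            for img, positive in tgt_test:
                cands, Xc = cache.get(img)
                dets = predict_from_features(model, cands, Xc, eval_config.confidence_floor)
                per_image.append((dets, img.boxes, positive))
            return evaluate_images(per_image, config=eval_config)

        lesion_m, _pm = held_out_metrics(mined_final)
        lesion_b, _pb = held_out_metrics(base_final)
        rows.append(
            {
                "seed": seed,
                "n_mined": len(mined),
                "precision_mined": lesion_m.precision,
                "precision_baseline": lesion_b.precision,
                "sensitivity_mined": lesion_m.sensitivity,
                "sensitivity_baseline": lesion_b.sensitivity,
            }
        )
    return pd.DataFrame(rows)
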