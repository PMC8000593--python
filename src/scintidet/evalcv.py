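"""IoU matching, lesion- and patient-level metrics, and shuffled
cross-validation with tabular aggregation.

Scoring conventions:

* a detection matches ground truth at **IoU >= 0.3** (half-open box
  convention throughout);
* matching is greedy in descending confidence with deterministic
  tie-breaks — standard detection-evaluation practice, characterized
  against a brute-force optimal-assignment oracle in the test suite;
* *equivocal* ground truth is ignored: it can absorb one overlapping
  detection (neither TP nor FP) and is never counted as a miss;
* lesion-based scoring reports sensitivity and precision (true negatives
  are undefined per box); patient-based scoring calls a whole image
  positive/negative and therefore also has a specificity.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import child_seed, render_2dp
from .errors import SplitError, ValidationError
from .scan_io import Box, Category, DatasetManifest

__all__ = [
    "iou",
    "merge_duplicate_truth",
    "match_detections",
    "MatchResult",
    "LesionMetrics",
    "PatientMetrics",
    "patient_call",
    "make_folds",
    "run_shuffles",
    "aggregate",
    "CVReport",
]


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two half-open boxes; 0 when disjoint."""
    if a.area <= 0 or b.area <= 0:
        raise ValidationError("degenerate box in IoU")
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def _det_box(d) -> Box:
    return d.box if hasattr(d, "box") else d


def merge_duplicate_truth(gts: Sequence[Box], merge_iou: float = 0.5) -> list[Box]:
    """Deduplicate fused-view ground truth.

    The fused image carries each lesion's AP box and flipped-PA box as
    separate entries; same-category boxes overlapping at IoU >= 0.5 are
    collapsed to the first (deterministic input order).
    """
    kept: list[Box] = []
    for g in gts:
        if any(k.category == g.category and iou(k, g) >= merge_iou for k in kept):
            continue
        kept.append(g)
    return kept


@dataclass
class MatchResult:
    pairs: list[tuple[int, int, float]]  # (detection idx, ground-truth idx, IoU)
    tp: dict[Category, int]
    fp: dict[Category, int]
    fn: dict[Category, int]
    ignored: int  # detections absorbed by equivocal ground truth
    n_truth: int  # non-equivocal ground-truth boxes after merging

    def totals(self, category: Category | None = None) -> tuple[int, int, int]:
        if category is not None:
            return self.tp[category], self.fp[category], self.fn[category]
        return (
            sum(self.tp.values()),
            sum(self.fp.values()),
            sum(self.fn.values()),
        )


def match_detections(
    dets: Sequence,
    gts: Sequence[Box],
    iou_threshold: float = 0.3,
    merge_duplicates: bool = True,
) -> MatchResult:
    """Greedy confidence-ordered matching of detections to ground truth.

    Detections are visited in descending confidence (ties broken by
    ascending x_min then y_min).  Each detection claims the unmatched
    same-category ground-truth box of highest IoU >= threshold (TP); failing
    that, if its best qualifying overlap is an unmatched equivocal box it is
    ignored and the equivocal box consumed; otherwise it is an FP.
    Unmatched non-equivocal ground truth counts as FN.
    """
    if not (0.0 < iou_threshold <= 1.0):
        raise ValidationError(f"iou_threshold {iou_threshold} outside (0, 1]")
    gts = merge_duplicate_truth(gts) if merge_duplicates else list(gts)
    order = sorted(
        range(len(dets)),
        key=lambda i: (-_det_box(dets[i]).confidence, _det_box(dets[i]).x_min, _det_box(dets[i]).y_min),
    )
    matched_gt: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    cats = [Category.METASTASIS, Category.NORMAL_HOTSPOT]
    tp = {c: 0 for c in cats}
    fp = {c: 0 for c in cats}
    ignored = 0
    for i in order:
        box = _det_box(dets[i])
        best_j, best_iou = -1, 0.0
        best_eq_j, best_eq_iou = -1, 0.0
        for j, g in enumerate(gts):
            if j in matched_gt:
                continue
            v = iou(box, g)
            if v < iou_threshold:
                continue
            if g.category == box.category and v > best_iou:
                best_j, best_iou = j, v
            elif g.category == Category.EQUIVOCAL and v > best_eq_iou:
                best_eq_j, best_eq_iou = j, v
        if best_j >= 0:
            matched_gt.add(best_j)
            pairs.append((i, best_j, best_iou))
            tp[box.category] += 1
        elif best_eq_j >= 0:
            matched_gt.add(best_eq_j)
            ignored += 1
        else:
            fp[box.category] += 1
    fn = {c: 0 for c in cats}
    for j, g in enumerate(gts):
        if g.category == Category.EQUIVOCAL:
            continue
        if j not in matched_gt:
            fn[g.category] += 1
    n_truth = sum(1 for g in gts if g.category != Category.EQUIVOCAL)
    return MatchResult(pairs=pairs, tp=tp, fp=fp, fn=fn, ignored=ignored, n_truth=n_truth)


@dataclass(frozen=True)
class LesionMetrics:
    """Per-box counts; undefined ratios are ``None``, never silently 0."""

    tp: int
    fp: int
    fn: int

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def precision(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None


@dataclass(frozen=True)
class PatientMetrics:
    """Image-level confusion for the metastasis-present call."""

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self) -> float | None:
        d = self.tn + self.fp
        return self.tn / d if d else None


def patient_call(dets: Sequence, decision_conf: float = 0.5) -> bool:
    """Image-level call: metastasis present iff any metastasis detection
    has confidence strictly above ``decision_conf``."""
    if not (0.0 <= decision_conf <= 1.0):
        raise ValidationError("decision_conf outside [0,1]")
    return any(
        _det_box(d).category == Category.METASTASIS and _det_box(d).confidence > decision_conf
        for d in dets
    )


def make_folds(manifest: DatasetManifest, k: int = 10, seed: int = 0) -> list[int]:
    """Stratified k-fold assignment, one fold id per manifest entry.

    Positives and negatives are shuffled independently with the given seed
    and dealt round-robin, so fold sizes within each stratum differ by at
    most one.  The assignment is a plain list and serializes for replay.
    """
    if k < 2:
        raise SplitError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds = [-1] * len(manifest.entries)
    for positive in (True, False):
        idx = [i for i, e in enumerate(manifest.entries) if e.patient_positive == positive]
        if 0 < len(idx) < k:
            raise SplitError(
                f"stratum patient_positive={positive} has {len(idx)} members < k={k}"
            )
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            folds[i] = pos % k
    return folds


def aggregate(values: Sequence[float]) -> tuple[float, float]:
    """Mean and sample (n-1) standard deviation of a metric column.

    Rendered values (2 decimals, ties away from zero) come from
    :func:`scintidet._util.render_2dp`.
    """
    vals = [float(v) for v in values]
    if not vals:
        raise ValidationError("cannot aggregate an empty list")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return mean, sd


METRIC_COLUMNS = [
    "lesion_sensitivity",
    "lesion_precision",
    "patient_sensitivity",
    "patient_specificity",
]


@dataclass
class CVReport:
    """Per-shuffle metric rows plus mean +- sample-SD aggregates."""

    rows: pd.DataFrame  # columns: shuffle + METRIC_COLUMNS
    fold_assignments: list[list[int]]
    seeds: list[int]

    def aggregates(self) -> dict[str, tuple[float, float]]:
        out = {}
        for col in METRIC_COLUMNS:
            vals = [v for v in self.rows[col].tolist() if v is not None and not np.isnan(v)]
            out[col] = aggregate(vals)
        return out

    def rendered(self) -> dict[str, str]:
        return {
            col: f"{render_2dp(m):.2f} ± {render_2dp(s):.2f}"
            for col, (m, s) in self.aggregates().items()
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "rows": self.rows.to_dict(orient="records"),
            "aggregates": {c: {"mean": m, "sd": s} for c, (m, s) in self.aggregates().items()},
            "fold_assignments": self.fold_assignments,
            "seeds": self.seeds,
        }
        path.write_text(json.dumps(payload, indent=2))
        return path

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        rows = self.rows.copy()
        agg = self.aggregates()
        avg_row = {"shuffle": "Average"}
        avg_row.update({c: render_2dp(m) for c, (m, _s) in agg.items()})
        out = pd.concat([rows, pd.DataFrame([avg_row])], ignore_index=True)
        out.to_csv(path, index=False)
        return path


@dataclass(frozen=True)
class EvalConfig:
    """Evaluation-time parameters (see CLI flags of the same names)."""

    iou_threshold: float = 0.3
    decision_conf: float = 0.5
    confidence_floor: float = 0.1
    full_cv: bool = False


def evaluate_images(
    per_image: Iterable[tuple[Sequence, Sequence[Box], bool]],
    config: EvalConfig = EvalConfig(),
) -> tuple[LesionMetrics, PatientMetrics]:
    """Score a set of images given (detections, ground truth, positive flag).

    Lesion metrics accumulate metastasis-category counts over all images;
    patient metrics compare the image-level call with the positive flag.
    """
    tp = fp = fn = 0
    p_tp = p_fn = p_tn = p_fp = 0
    for dets, gts, positive in per_image:
        res = match_detections(dets, gts, iou_threshold=config.iou_threshold)
        t, f, n = res.totals(Category.METASTASIS)
        tp, fp, fn = tp + t, fp + f, fn + n
        called = patient_call(dets, decision_conf=config.decision_conf)
        if positive:
            p_tp, p_fn = p_tp + called, p_fn + (not called)
        else:
            p_fp, p_tn = p_fp + called, p_tn + (not called)
    return LesionMetrics(tp, fp, fn), PatientMetrics(p_tp, p_fn, p_tn, p_fp)


def run_shuffles(
    manifest: DatasetManifest,
    images: Mapping[str, "object"],
    pretrained,
    n_shuffles: int = 10,
    k: int = 10,
    base_seed: int = 0,
    eval_config: EvalConfig = EvalConfig(),
    backend_config=None,
    augment_plan=None,
) -> CVReport:
    """Shuffled cross-validation of the fine-tune + evaluate stage.

    One *shuffle* is one re-randomized stratified split: fold 0 is held out
    for testing and the model is fine-tuned on the remaining folds; with
    ``eval_config.full_cv`` every fold takes a turn as the test set and the
    shuffle row averages them.  ``images`` maps patient_id to that patient's
    fused chest image.  ``augment_plan`` applies offline intensity/flip
    augmentation to the fine-tuning set; the default (``None``) trains on
    the native-intensity images, which is what the intensity-normalized
    reference backend expects (re-leveling is aimed at CNN backends).
    """
    from . import detector as det_mod
    from .fusion import augment
    from .mining import fold_equivocal_to_normal

    if pretrained.n_categories != 2:
        raise ValidationError("run_shuffles requires a 2-category pretrained model")
    backend_config = backend_config or det_mod.BackendConfig()

    rows = []
    assignments: list[list[int]] = []
    seeds: list[int] = []
    for s in range(1, n_shuffles + 1):
        seed = child_seed(base_seed, "shuffle", s)
        seeds.append(seed)
        folds = make_folds(manifest, k=k, seed=seed)
        assignments.append(folds)
        test_fold_ids = range(k) if eval_config.full_cv else [0]
        fold_metrics = []
        for test_fold in test_fold_ids:
            train_imgs = []
            for e, f in zip(manifest.entries, folds):
                if f == test_fold:
                    continue
                fused = fold_equivocal_to_normal(images[e.patient_id])
                if augment_plan is not None:
                    train_imgs.extend(augment(fused, augment_plan))
                else:
                    train_imgs.append(fused)
            model = det_mod.fit(
                train_imgs, config=backend_config, n_categories=2, init_model=pretrained
            )
            per_image = []
            for e, f in zip(manifest.entries, folds):
                if f != test_fold:
                    continue
                fused = images[e.patient_id]
                dets = det_mod.predict(model, fused, confidence_floor=eval_config.confidence_floor)
                gts = [b for b in fused.boxes]
                per_image.append((dets, gts, e.patient_positive))
            lesion, patient = evaluate_images(per_image, config=eval_config)
            fold_metrics.append((lesion, patient))

        def _nanmean(vals):
            vals = [v for v in vals if v is not None]
            return float(np.mean(vals)) if vals else float("nan")

        rows.append(
            {
                "shuffle": s,
                "lesion_sensitivity": _nanmean([l.sensitivity for l, _ in fold_metrics]),
                "lesion_precision": _nanmean([l.precision for l, _ in fold_metrics]),
                "patient_sensitivity": _nanmean([p.sensitivity for _, p in fold_metrics]),
                "patient_specificity": _nanmean([p.specificity for _, p in fold_metrics]),
            }
        )
    return CVReport(rows=pd.DataFrame(rows), fold_assignments=assignments, seeds=seeds)
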