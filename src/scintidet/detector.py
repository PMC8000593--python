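"""Pluggable hotspot-detector backends and the CPU reference detector.

The pipeline around the detector (normalization, fusion, negative mining,
cross-validated evaluation) is backend-agnostic: any object implementing
``fit(train, config, n_categories) -> DetectorModel`` and
``predict(model, image, confidence_floor) -> list[Detection]`` over the
toolkit's types can be registered.  External one-stage detectors plug in
through this contract; their published training defaults (150 000
iterations, batch 64, learning rate 0.00261) are recorded as adapter
metadata only.

The bundled **reference backend** is deliberately classical so the whole
workflow trains in seconds on one CPU:

* proposals from multi-scale difference-of-Gaussian blob detection on the
  channelwise maximum of the fused image;
* a fixed-length feature vector per candidate encoding the clinical cues a
  physician uses — local intensity and contrast, left/right mirror
  symmetry (osteoarthritic joints), collinearity with other candidates
  (rib injury chains);
* a regularized logistic classifier (background vs. 1 or 2 hotspot
  categories) whose calibrated probability is the detection confidence.
"""
from __future__ import annotations

import pickle
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
from skimage.feature import blob_dog
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from ._util import config_digest
from .errors import FeatureError, ModelStateError, TrainingError, ValidationError
from .evalcv import iou
from .fusion import FusedImage
from .scan_io import Box, Category, LabeledImage

__all__ = [
    "Detection",
    "DetectorModel",
    "BackendConfig",
    "ReferenceBackend",
    "propose",
    "featurize",
    "fit",
    "predict",
    "get_backend",
    "register_backend",
    "save_model",
    "load_model",
]

# Published training defaults of the external GPU backend this contract was
# designed around; adapter metadata only — never executed here.
EXTERNAL_BACKEND_DEFAULTS = {
    "iterations": 150_000,
    "batch_size": 64,
    "learning_rate": 0.00261,
}

FEATURE_NAMES = [
    "red_mean", "red_max", "red_std",
    "green_mean", "green_max", "green_std",
    "third_mean", "third_max", "third_std",
    "ring_contrast",
    "log_area", "aspect",
    "mirror_symmetry",
    "rel_x_offset", "rel_y",
    "collinearity",
]


@dataclass(frozen=True)
class Detection:
    """One detector output: a box with its calibrated confidence."""

    box: Box
    confidence: float

    def __post_init__(self):
        if not (0.0 <= self.confidence <= 1.0):
            raise ValidationError(f"confidence {self.confidence} outside [0,1]")

    @property
    def category(self) -> Category:
        return self.box.category


@dataclass(frozen=True)
class BackendConfig:
    """Backend selection plus free-form training hyperparameters."""

    backend: str = "reference"
    confidence_floor: float = 0.1
    seed: int = 0
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.confidence_floor <= 1.0):
            raise ValidationError("confidence floor outside [0,1]")

    def digest(self) -> str:
        return config_digest(
            {"backend": self.backend, "floor": self.confidence_floor,
             "seed": self.seed, "hyperparams": self.hyperparams}
        )


@dataclass
class DetectorModel:
    """Opaque trained detector handle satisfying the backend contract."""

    backend: str
    n_categories: int
    state: dict
    seed: int
    config_digest: str

    def __post_init__(self):
        if self.n_categories not in (1, 2):
            raise ValidationError("n_categories must be 1 or 2")


# ---------------------------------------------------------------------------
# reference backend internals

_PROPOSAL_SIGMAS = (2.0, 4.0, 8.0)
_LABELS = {0: None, 1: Category.METASTASIS, 2: Category.NORMAL_HOTSPOT}


def _channel_max(image: FusedImage) -> np.ndarray:
    return np.maximum(np.maximum(image.red, image.green), image.third).astype(np.float64)


def propose(
    image: FusedImage,
    min_contrast: float = 12.0,
    threshold: float = 0.06,
    sigmas: Sequence[float] = _PROPOSAL_SIGMAS,
    max_candidates: int = 150,
) -> list[Box]:
    """Candidate boxes from multi-scale DoG blob detection.

    Blobs are found on the channelwise maximum; a candidate is kept only if
    its peak exceeds the surrounding-ring mean by ``min_contrast`` gray
    levels.  Deterministic for a fixed input.
    """
    img = _channel_max(image)
    H, W = img.shape
    if img.max() <= 0:
        return []
    blobs = blob_dog(
        img / 255.0,
        min_sigma=min(sigmas),
        max_sigma=max(sigmas),
        sigma_ratio=1.6,
        threshold=threshold,
        overlap=0.5,
    )
    scored: list[tuple[float, Box]] = []
    for r, c, sigma in blobs:
        half = max(3.0, 1.5 * sigma * np.sqrt(2.0))
        box = Box(
            category=Category.METASTASIS,  # placeholder until classified
            x_min=c - half, y_min=r - half, x_max=c + half, y_max=r + half,
            confidence=0.0,
        ).clip_to(W, H)
        if box is None or box.width < 2 or box.height < 2:
            continue
        ri, ci = int(round(r)), int(round(c))
        peak = img[max(0, ri - 1) : ri + 2, max(0, ci - 1) : ci + 2].max()
        contrast = peak - _ring_mean(img, box)
        if contrast >= min_contrast:
            scored.append((contrast, box))
    # safety NMS between surviving candidates of different scales
    scored.sort(key=lambda t: (-t[1].area, t[1].x_min, t[1].y_min))
    kept: list[tuple[float, Box]] = []
    for contrast, b in scored:
        if all(iou(b, k) <= 0.5 for _c, k in kept):
            kept.append((contrast, b))
    # bound the per-image candidate budget, strongest contrast first
    if len(kept) > max_candidates:
        kept.sort(key=lambda t: (-t[0], t[1].x_min, t[1].y_min))
        kept = kept[:max_candidates]
    boxes = [b for _c, b in kept]
    boxes.sort(key=lambda b: (b.y_min, b.x_min))
    return boxes


def _interior(arr: np.ndarray, box: Box) -> np.ndarray:
    y0, y1 = int(np.floor(box.y_min)), int(np.ceil(box.y_max))
    x0, x1 = int(np.floor(box.x_min)), int(np.ceil(box.x_max))
    return arr[max(0, y0) : y1, max(0, x0) : x1]


def _ring_mean(arr: np.ndarray, box: Box, margin: int = 4) -> float:
    H, W = arr.shape
    y0, y1 = int(np.floor(box.y_min)), int(np.ceil(box.y_max))
    x0, x1 = int(np.floor(box.x_min)), int(np.ceil(box.x_max))
    oy0, oy1 = max(0, y0 - margin), min(H, y1 + margin)
    ox0, ox1 = max(0, x0 - margin), min(W, x1 + margin)
    outer = arr[oy0:oy1, ox0:ox1]
    total, n_total = float(outer.sum()), outer.size
    inner = arr[max(0, y0) : min(H, y1), max(0, x0) : min(W, x1)]
    n_ring = n_total - inner.size
    if n_ring <= 0:
        return 0.0
    return (total - float(inner.sum())) / n_ring


def _mirror_symmetry(img: np.ndarray, box: Box) -> float:
    """Correlation of the box patch with its left-right mirrored location."""
    H, W = img.shape
    mirrored = Box(
        category=box.category,
        x_min=W - box.x_max, x_max=W - box.x_min,
        y_min=box.y_min, y_max=box.y_max,
        confidence=box.confidence,
    ).clip_to(W, H)
    if mirrored is None:
        return 0.0
    a = _interior(img, box)
    b = _interior(img, mirrored)[:, ::-1]
    h = min(a.shape[0], b.shape[0])
    w = min(a.shape[1], b.shape[1])
    a, b = a[:h, :w].ravel(), b[:h, :w].ravel()
    if a.size < 4 or a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _collinearity(box: Box, others: Sequence[Box], tol: float = 8.0, reach: float = 140.0) -> float:
    """Max count of other candidates lying near one line through this box."""
    c = np.array(box.center)
    centers = np.array([o.center for o in others if o is not box])
    if len(centers) < 2:
        return 0.0
    rel = centers - c
    dist = np.hypot(rel[:, 0], rel[:, 1])
    near = rel[(dist > 1.0) & (dist < reach)]
    if len(near) < 2:
        return 0.0
    u = near / np.hypot(near[:, 0], near[:, 1])[:, None]
    # perpendicular distance of every near center to the line through this
    # box along every candidate direction: (directions x centers) at once
    perp = np.abs(np.outer(u[:, 1], near[:, 0]) - np.outer(u[:, 0], near[:, 1]))
    best = int((perp < tol).sum(axis=1).max())
    return best / 5.0


def featurize(image: FusedImage, box: Box, context: Sequence[Box] = ()) -> np.ndarray:
    """Fixed-length descriptor of one candidate box.

    Encodes per-channel interior statistics, contrast against a surrounding
    ring, box geometry, a left/right mirror-symmetry score, normalized
    position, and a collinearity score over the other candidates in
    ``context`` (rib injury chains line up; isolated metastases do not).
    """
    return _featurize_one(image, _channel_max(image), box, context)


def featurize_many(
    image: FusedImage, boxes: Sequence[Box], context: Sequence[Box] = ()
) -> np.ndarray:
    """Batched :func:`featurize` sharing the channel-max computation."""
    if not boxes:
        return np.empty((0, len(FEATURE_NAMES)))
    chan_max = _channel_max(image)
    return np.asarray([_featurize_one(image, chan_max, b, context) for b in boxes])


def _featurize_one(
    image: FusedImage, chan_max: np.ndarray, box: Box, context: Sequence[Box]
) -> np.ndarray:
    if box.width <= 1 or box.height <= 1:
        raise FeatureError("box too small to featurize")
    # intensity statistics are expressed relative to the global image level,
    # so the descriptor is invariant to the offline intensity re-leveling
    # used for augmentation (a hotspot looks the same at every level)
    scale = max(float(chan_max.mean()), 1.0)
    feats = []
    for chan in (image.red, image.green, image.third):
        patch = _interior(np.asarray(chan, np.float64), box)
        if patch.size == 0:
            raise FeatureError("box interior is empty")
        feats.extend([patch.mean() / scale, patch.max() / scale, patch.std() / scale])
    interior = _interior(chan_max, box)
    feats.append((interior.mean() - _ring_mean(chan_max, box)) / scale)
    feats.append(np.log(box.area))
    feats.append(box.width / box.height)
    feats.append(_mirror_symmetry(chan_max, box))
    W, H = image.width, image.height
    cx, cy = box.center
    feats.append(abs(cx - W / 2.0) / (W / 2.0))
    feats.append(cy / H)
    feats.append(_collinearity(box, context))
    return np.asarray(feats, dtype=np.float64)


def _assign_labels(candidates: Sequence[Box], gts: Sequence[Box], n_categories: int,
                   iou_threshold: float = 0.3) -> list[int]:
    """Greedy candidate labeling against ground truth for training."""
    labels = [0] * len(candidates)
    matched: set[int] = set()
    order = sorted(
        range(len(candidates)),
        key=lambda i: -max((iou(candidates[i], g) for g in gts), default=0.0),
    )
    for i in order:
        best_j, best_iou = -1, iou_threshold
        for j, g in enumerate(gts):
            if j in matched:
                continue
            v = iou(candidates[i], g)
            if v >= best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            g = gts[best_j]
            if g.category == Category.METASTASIS:
                labels[i] = 1
                matched.add(best_j)
            elif n_categories == 2 and g.category == Category.NORMAL_HOTSPOT:
                labels[i] = 2
                matched.add(best_j)
            # equivocal / out-of-scope categories leave the candidate as background
    return labels


def extract_training_arrays(
    train: Sequence[LabeledImage | FusedImage], n_categories: int
) -> tuple[np.ndarray, np.ndarray]:
    """Candidate features and labels for a corpus (shared by fit/experiments)."""
    X, y = [], []
    for item in train:
        image, gts = _as_fused(item)
        candidates, Xc = image_candidates(image)
        Xg, yg = image_training_examples(image, gts, candidates, Xc, n_categories)
        X.append(Xg)
        y.append(yg)
    if not X:
        return np.empty((0, len(FEATURE_NAMES))), np.empty((0,), dtype=int)
    return np.concatenate(X), np.concatenate(y)


def image_candidates(image: FusedImage) -> tuple[list[Box], np.ndarray]:
    """Proposals and their features for one image (cacheable unit)."""
    candidates = propose(image)
    return candidates, featurize_many(image, candidates, context=candidates)


def image_training_examples(
    image: FusedImage,
    gts: Sequence[Box],
    candidates: Sequence[Box],
    Xc: np.ndarray,
    n_categories: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Label candidates against ground truth and append the GT boxes
    themselves as positive examples (the proposal stage may miss some; the
    classifier should still know what they look like)."""
    labels = _assign_labels(candidates, gts, n_categories)
    gt_boxes, gt_labels = [], []
    for g in gts:
        if g.category == Category.METASTASIS:
            lab = 1
        elif g.category == Category.NORMAL_HOTSPOT and n_categories == 2:
            lab = 2
        else:
            continue
        if g.width <= 1 or g.height <= 1:
            continue
        gt_boxes.append(g)
        gt_labels.append(lab)
    Xg = featurize_many(image, gt_boxes, context=candidates)
    X = np.concatenate([Xc, Xg]) if len(gt_boxes) else Xc.copy()
    y = np.asarray(list(labels) + gt_labels, dtype=int)
    return X, y


def _as_fused(item: LabeledImage | FusedImage) -> tuple[FusedImage, list[Box]]:
    if isinstance(item, FusedImage):
        return item, item.boxes
    arr = np.asarray(item.image)
    if arr.ndim == 3:
        fused = FusedImage(
            red=arr[..., 0], green=arr[..., 1], third=arr[..., 2],
            boxes=item.boxes, source_id=item.source_id,
        )
    else:
        fused = FusedImage(red=arr, green=arr, third=arr, boxes=item.boxes,
                           source_id=item.source_id)
    return fused, fused.boxes


class ReferenceBackend:
    """Classical CPU backend: DoG proposals + logistic classification."""

    name = "reference"

    def fit(
        self,
        train: Sequence[LabeledImage | FusedImage],
        config: BackendConfig,
        n_categories: int,
        init_model: DetectorModel | None = None,
    ) -> DetectorModel:
        """Train (or warm-start fine-tune) the candidate classifier.

        Candidates matched to ground truth at IoU >= 0.3 become positive
        examples of their category; unmatched candidates become background.
        With ``init_model`` the classifier is initialized from the previous
        parameters and the feature scaler is frozen, so fine-tuning moves
        the same decision surface rather than refitting from scratch.
        Deterministic for a fixed seed and input order.
        """
        X, y = extract_training_arrays(train, n_categories)
        return self.fit_arrays(X, y, config, n_categories, init_model=init_model)

    def fit_arrays(
        self,
        X: np.ndarray,
        y: np.ndarray,
        config: BackendConfig,
        n_categories: int,
        init_model: DetectorModel | None = None,
    ) -> DetectorModel:
        if X.shape[0] == 0 or not np.any(y > 0):
            raise TrainingError("no positive training examples; cannot fit detector")
        if n_categories == 1 and np.any(y > 1):
            raise TrainingError("found 2-category labels for a 1-category fit")
        hp = dict(config.hyperparams)
        C = float(hp.get("C", 1.0))
        max_iter = int(hp.get("max_iter", 500))
        if init_model is not None:
            scaler = init_model.state["scaler"]
        else:
            scaler = StandardScaler().fit(X)
        Xs = scaler.transform(X)
        clf = LogisticRegression(C=C, max_iter=max_iter, solver="lbfgs")
        if init_model is not None:
            prev: LogisticRegression = init_model.state["classifier"]
            # warm start requires identical class sets (coefficient shapes)
            if set(np.unique(y)) == set(prev.classes_):
                clf.warm_start = True
                clf.classes_ = prev.classes_.copy()
                clf.coef_ = prev.coef_.copy()
                clf.intercept_ = prev.intercept_.copy()
        clf.fit(Xs, y)
        return DetectorModel(
            backend=self.name,
            n_categories=n_categories,
            state={"scaler": scaler, "classifier": clf},
            seed=config.seed,
            config_digest=config.digest(),
        )

    def predict(
        self, model: DetectorModel, image: FusedImage, confidence_floor: float
    ) -> list[Detection]:
        """propose -> featurize -> classify -> threshold -> per-category NMS."""
        candidates, X = image_candidates(image)
        return predict_from_features(model, candidates, X, confidence_floor)


def predict_from_features(
    model: DetectorModel,
    candidates: Sequence[Box],
    X: np.ndarray,
    confidence_floor: float,
) -> list[Detection]:
    """Classification half of predict, reusing precomputed candidate features."""
    if "classifier" not in model.state:
        raise ModelStateError("model has no trained classifier")
    if not (0.0 <= confidence_floor <= 1.0):
        raise ValidationError("confidence floor outside [0,1]")
    if len(candidates) == 0:
        return []
    Xs = model.state["scaler"].transform(X)
    clf: LogisticRegression = model.state["classifier"]
    proba = clf.predict_proba(Xs)
    classes = list(clf.classes_)
    dets: list[Detection] = []
    for cand, p in zip(candidates, proba):
        best_label, best_p = 0, -1.0
        for lab in (1, 2):
            if lab in classes and (model.n_categories == 2 or lab == 1):
                v = float(p[classes.index(lab)])
                if v > best_p:
                    best_label, best_p = lab, v
        if best_label == 0 or best_p <= confidence_floor:
            continue
        box = replace(cand, category=_LABELS[best_label], confidence=best_p)
        dets.append(Detection(box=box, confidence=best_p))
    return _nms(dets)


def _nms(dets: list[Detection], iou_threshold: float = 0.5) -> list[Detection]:
    """Greedy per-category non-maximum suppression, confidence-descending."""
    order = sorted(dets, key=lambda d: (-d.confidence, d.box.x_min, d.box.y_min))
    kept: list[Detection] = []
    for d in order:
        if all(
            d.category != k.category or iou(d.box, k.box) <= iou_threshold for k in kept
        ):
            kept.append(d)
    return kept


_BACKENDS: dict[str, object] = {}


def register_backend(backend) -> None:
    _BACKENDS[backend.name] = backend


def get_backend(name: str):
    try:
        return _BACKENDS[name]
    except KeyError:
        raise ValidationError(f"unknown backend {name!r}; registered: {sorted(_BACKENDS)}")


register_backend(ReferenceBackend())


def fit(
    train: Sequence[LabeledImage | FusedImage],
    config: BackendConfig = BackendConfig(),
    n_categories: int = 2,
    init_model: DetectorModel | None = None,
) -> DetectorModel:
    """Train a detector with the configured backend."""
    return get_backend(config.backend).fit(train, config, n_categories, init_model=init_model)


def predict(
    model: DetectorModel, image: FusedImage, confidence_floor: float = 0.1
) -> list[Detection]:
    """Detections above the (strict) confidence floor, NMS-deduplicated.

    Output is monotone non-increasing in ``confidence_floor`` by set
    inclusion and contains no two same-category boxes with IoU > 0.5.
    """
    return get_backend(model.backend).predict(model, image, confidence_floor)


def save_model(model: DetectorModel, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "wb") as fh:
        pickle.dump(model, fh)
    return path


def load_model(path: str | Path) -> DetectorModel:
    with open(path, "rb") as fh:
        model = pickle.load(fh)
    if not isinstance(model, DetectorModel):
        raise ModelStateError(f"{path} does not contain a DetectorModel")
    return model
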