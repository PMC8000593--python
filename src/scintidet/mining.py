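"""Negative mining and transfer-learning training workflow.

The workflow turns a positives-only detector into a false-positive-aware
two-category detector without any manual negative labeling:

1. **pretrain_positive_only** — train a 1-category (metastasis) model on
   images that each contain at least one metastasis box;
2. **harvest_negatives** — run that model over images known to be free of
   metastasis; *every* detection above the harvest confidence (strictly
   greater than 0.1 by default) is by construction a false positive and is
   relabeled ``normal_hotspot``;
3. **retrain_two_class** — train a 2-category model on the original
   metastasis boxes plus the mined negatives;
4. **transfer_finetune** — adapt the 2-category model to a target cohort
   (equivocal target boxes are folded into the normal group for training,
   since they are too few to carry their own class).

Mining never mutates ground-truth label files: mined boxes live in their
own provenance-tracked store and are merged with truth only at training
time.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

from . import detector as det_mod
from .detector import BackendConfig, DetectorModel
from .errors import ModelStateError, TrainingError, ValidationError
from .fusion import FusedImage
from .scan_io import Box, Category

__all__ = [
    "MiningConfig",
    "MinedNegatives",
    "pretrain_positive_only",
    "harvest_negatives",
    "retrain_two_class",
    "transfer_finetune",
    "fold_equivocal_to_normal",
]


@dataclass(frozen=True)
class MiningConfig:
    """Harvesting parameters. ``harvest_confidence`` is a strict floor."""

    harvest_confidence: float = 0.1
    seed: int = 0
    backend: BackendConfig = field(default_factory=BackendConfig)

    def __post_init__(self):
        if not (0.0 <= self.harvest_confidence <= 1.0):
            raise ValidationError("harvest_confidence outside [0,1]")


@dataclass
class MinedNegatives:
    """False positives harvested from metastasis-free images.

    Each entry is ``(image_id, box relabeled normal_hotspot, originating
    confidence)``; every originating confidence is strictly greater than the
    harvest threshold.
    """

    entries: list[tuple[str, Box, float]]
    model_digest: str
    harvest_confidence: float

    def __len__(self) -> int:
        return len(self.entries)

    def boxes_for(self, image_id: str) -> list[Box]:
        return [b for iid, b, _c in self.entries if iid == image_id]

    def save(self, directory: str | Path) -> Path:
        """Write the mined store: one label-format block per image plus
        provenance JSON (kept apart from ground-truth label files)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        payload = {
            "model_digest": self.model_digest,
            "harvest_confidence": self.harvest_confidence,
            "entries": [
                {
                    "image_id": iid,
                    "box": [b.x_min, b.y_min, b.x_max, b.y_max],
                    "confidence": c,
                }
                for iid, b, c in self.entries
            ],
        }
        (directory / "mined_negatives.json").write_text(json.dumps(payload, indent=2))
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "MinedNegatives":
        payload = json.loads((Path(directory) / "mined_negatives.json").read_text())
        entries = [
            (
                e["image_id"],
                Box(
                    category=Category.NORMAL_HOTSPOT,
                    x_min=e["box"][0], y_min=e["box"][1],
                    x_max=e["box"][2], y_max=e["box"][3],
                    confidence=e["confidence"],
                ),
                e["confidence"],
            )
            for e in payload["entries"]
        ]
        return cls(
            entries=entries,
            model_digest=payload["model_digest"],
            harvest_confidence=payload["harvest_confidence"],
        )


def _metastasis_only(image: FusedImage) -> FusedImage:
    boxes = [b for b in image.boxes if b.category == Category.METASTASIS]
    return replace(image, boxes=boxes)


def fold_equivocal_to_normal(image: FusedImage) -> FusedImage:
    """Relabel equivocal ground truth as normal_hotspot (training-time rule)."""
    boxes = [
        replace(b, category=Category.NORMAL_HOTSPOT)
        if b.category == Category.EQUIVOCAL
        else b
        for b in image.boxes
    ]
    return replace(image, boxes=boxes)


def pretrain_positive_only(
    positives: Sequence[FusedImage], config: MiningConfig = MiningConfig()
) -> DetectorModel:
    """Train the 1-category (metastasis) pre-model.

    Every image must contain at least one metastasis box; normal/equivocal
    boxes present in positive images are ignored at this stage (their
    candidates fall into the background class).
    """
    for img in positives:
        if not any(b.category == Category.METASTASIS for b in img.boxes):
            raise ValidationError(
                f"image {img.source_id!r} has no metastasis box; "
                "positives-only pretraining requires one per image"
            )
    train = [_metastasis_only(img) for img in positives]
    return det_mod.fit(train, config=config.backend, n_categories=1)


def harvest_negatives(
    model: DetectorModel,
    normals: Sequence[FusedImage],
    config: MiningConfig = MiningConfig(),
) -> MinedNegatives:
    """Run the 1-category pre-model over metastasis-free images.

    All detections with confidence strictly greater than
    ``harvest_confidence`` are guaranteed false positives; they are
    relabeled ``normal_hotspot`` and collected with provenance.  Standard
    prediction post-processing (NMS) applies, so the mined set mirrors
    deployment-time false positives.
    """
    if model.n_categories != 1:
        raise ModelStateError("negative mining is defined on the 1-category pre-model")
    entries: list[tuple[str, Box, float]] = []
    for img in normals:
        if any(b.category == Category.METASTASIS for b in img.boxes):
            raise ValidationError(
                f"image {img.source_id!r} carries metastasis ground truth; "
                "it cannot serve as a mining normal"
            )
        dets = det_mod.predict(model, img, confidence_floor=config.harvest_confidence)
        for d in dets:
            if not d.confidence > config.harvest_confidence:
                continue  # strictly greater, whatever the backend's convention
            mined_box = replace(d.box, category=Category.NORMAL_HOTSPOT)
            entries.append((img.source_id, mined_box, d.confidence))
    return MinedNegatives(
        entries=entries,
        model_digest=model.config_digest,
        harvest_confidence=config.harvest_confidence,
    )


def retrain_two_class(
    positives: Sequence[FusedImage],
    normals: Sequence[FusedImage],
    mined: MinedNegatives,
    config: MiningConfig = MiningConfig(),
) -> DetectorModel:
    """Train the 2-category pre-trained model.

    Training truth is the union of the original metastasis boxes (from the
    positive images) and the mined ``normal_hotspot`` boxes attached to
    their originating normal images.  Ground-truth files are never touched.
    """
    if len(mined) == 0:
        raise TrainingError(
            "mined negative set is empty; lower the harvest confidence threshold"
        )
    train: list[FusedImage] = [_metastasis_only(img) for img in positives]
    for img in normals:
        mined_boxes = mined.boxes_for(img.source_id)
        train.append(replace(img, boxes=mined_boxes))
    return det_mod.fit(train, config=config.backend, n_categories=2)


def transfer_finetune(
    pretrained: DetectorModel,
    target: Sequence[FusedImage],
    config: MiningConfig = MiningConfig(),
    equivocal: str = "as-normal",
) -> DetectorModel:
    """Adapt the 2-category pre-trained model to a target cohort.

    ``equivocal`` is ``"as-normal"`` (fold equivocal boxes into
    normal_hotspot, the training-time default) or ``"ignore"`` (drop them).
    An empty target returns the pretrained model unchanged with a warning.
    """
    if pretrained.n_categories != 2:
        raise ModelStateError("transfer fine-tuning requires a 2-category pre-trained model")
    if equivocal not in {"as-normal", "ignore"}:
        raise ValidationError(f"unknown equivocal policy {equivocal!r}")
    if len(target) == 0:
        warnings.warn("empty target set; returning the pretrained model unchanged")
        return pretrained
    if equivocal == "as-normal":
        train = [fold_equivocal_to_normal(img) for img in target]
    else:
        train = [
            replace(img, boxes=[b for b in img.boxes if b.category != Category.EQUIVOCAL])
            for img in target
        ]
    return det_mod.fit(train, config=config.backend, n_categories=2, init_model=pretrained)
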