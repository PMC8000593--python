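"""End-to-end pipeline: phantom cohorts -> preprocess -> fuse -> pre-train ->
negative mining -> transfer fine-tuning -> shuffled cross-validation.

The pipeline is configured by a :class:`PipelineConfig` (YAML round-trip,
every CLI flag overrides its key) and writes a replayable artifact
directory: models, the mined-negative store, the CV report (CSV + JSON) and
a digest manifest of every input each stage consumed.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import detector as det_mod
from ._util import child_seed, config_digest
from .detector import BackendConfig
from .errors import PipelineError, ValidationError
from .evalcv import CVReport, EvalConfig, run_shuffles
from .fusion import AugmentPlan, FusedImage, fuse
from .mining import (
    MiningConfig,
    harvest_negatives,
    pretrain_positive_only,
    retrain_two_class,
)
from .phantom import generate_cohort
from .preprocess import NormalizationRange, extract_chest, normalize_pair, split_and_center
from .scan_io import DatasetManifest, read_labels, read_manifest, read_scan, split_frame_boxes

__all__ = ["PipelineConfig", "run_pipeline", "prepare_fused", "fused_from_manifest"]


@dataclass
class PipelineConfig:
    """All stage parameters plus the base seed and cohort sizes."""

    base_seed: int = 0
    out_dir: str = "scintidet_run"
    # synthetic cohort sizes (pre-train cohort mirrors a metastasis-positive
    # set plus a metastasis-free set; the target cohort is evaluated by CV)
    pretrain_positives: int = 30
    pretrain_negatives: int = 30
    target_size: int = 40
    target_positive_fraction: float = 0.5
    # stage parameters
    t1: float = 7.0
    t2: float = 14.0
    chest_band: tuple[float, float] = (0.10, 0.45)
    augment_range: tuple[float, float] = (25.0, 48.0)
    augment_levels: int = 6
    augment_flips: bool = True
    harvest_confidence: float = 0.1
    iou_threshold: float = 0.3
    decision_conf: float = 0.5
    confidence_floor: float = 0.1
    n_shuffles: int = 2
    k_folds: int = 10
    full_cv: bool = False
    backend: str = "reference"

    def validate(self) -> None:
        if not (0 < self.t1 < self.t2 <= 255):
            raise ValidationError(f"invalid normalization range ({self.t1}, {self.t2})")
        if not (0 <= self.chest_band[0] < self.chest_band[1] <= 1):
            raise ValidationError(f"invalid chest band {self.chest_band}")
        if self.augment_levels < 1:
            raise ValidationError("augment_levels must be >= 1")
        if not (0 <= self.harvest_confidence <= 1):
            raise ValidationError("harvest_confidence outside [0,1]")

    # -- YAML round trip ----------------------------------------------------
    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        cfg = cls(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
        })
        return cfg

    def digest(self) -> str:
        return config_digest(asdict(self))

    # -- derived stage configs ---------------------------------------------
    @property
    def normalization(self) -> NormalizationRange:
        return NormalizationRange(T1=self.t1, T2=self.t2)

    @property
    def augment_plan(self) -> AugmentPlan:
        return AugmentPlan(
            target_range=self.augment_range,
            n_levels=self.augment_levels,
            include_flips=self.augment_flips,
        )

    @property
    def backend_config(self) -> BackendConfig:
        return BackendConfig(backend=self.backend, confidence_floor=self.confidence_floor,
                             seed=self.base_seed)

    @property
    def mining_config(self) -> MiningConfig:
        return MiningConfig(
            harvest_confidence=self.harvest_confidence,
            seed=self.base_seed,
            backend=self.backend_config,
        )

    @property
    def eval_config(self) -> EvalConfig:
        return EvalConfig(
            iou_threshold=self.iou_threshold,
            decision_conf=self.decision_conf,
            confidence_floor=self.confidence_floor,
            full_cv=self.full_cv,
        )


def prepare_fused(
    scan, ap_boxes, pa_boxes, norm: NormalizationRange = NormalizationRange(),
    chest_band: tuple[float, float] = (0.10, 0.45),
) -> FusedImage:
    """Scan + view boxes -> centered -> normalized -> chest -> fused image."""
    pair = split_and_center(scan, ap_boxes=ap_boxes, pa_boxes=pa_boxes)
    pair, _info = normalize_pair(pair, norm)
    chest = extract_chest(pair, band=chest_band)
    return fuse(chest)


def fused_from_manifest(
    manifest: DatasetManifest,
    norm: NormalizationRange = NormalizationRange(),
    chest_band: tuple[float, float] = (0.10, 0.45),
) -> dict[str, FusedImage]:
    """Preprocess + fuse every manifest entry; keyed by patient_id."""
    out: dict[str, FusedImage] = {}
    for e in manifest.entries:
        scan = read_scan(manifest.resolve(e.image))
        h, w = scan.shape
        boxes = read_labels(manifest.resolve(e.label), width=w, height=h)
        ap_boxes, pa_boxes = split_frame_boxes(boxes)
        out[e.patient_id] = prepare_fused(scan, ap_boxes, pa_boxes, norm, chest_band)
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> tuple[CVReport, Path]:
    """Execute the full workflow; returns the CV report and artifact dir.

    Deterministic: rerunning with the same config reproduces the report
    exactly.  Any stage error aborts with the stage name and config digest.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    digest = config.digest()
    log_path = out_dir / "pipeline.log"
    log_lines: list[str] = []

    def log(stage: str, **kv):
        line = json.dumps({"stage": stage, "t": round(time.time(), 2), **kv})
        log_lines.append(line)

    def stage(name: str):
        class _Ctx:
            def __enter__(self_):
                return None

            def __exit__(self_, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(name, f"{exc} (config {digest})") from exc
                return False

        return _Ctx()

    with stage("cohorts"):
        pre_dir = out_dir / "pretrain_cohort"
        tgt_dir = out_dir / "target_cohort"
        pre_manifest = generate_cohort(
            config.pretrain_positives,
            config.pretrain_negatives,
            seed=child_seed(config.base_seed, "pretrain"),
            out_dir=pre_dir,
            cohort="synthetic",
        )
        n_pos = int(round(config.target_size * config.target_positive_fraction))
        tgt_manifest = generate_cohort(
            n_pos,
            config.target_size - n_pos,
            seed=child_seed(config.base_seed, "target"),
            out_dir=tgt_dir,
            cohort="synthetic",
        )
        log("cohorts", pretrain=len(pre_manifest), target=len(tgt_manifest))

    with stage("preprocess"):
        pre_fused = fused_from_manifest(pre_manifest, config.normalization, config.chest_band)
        tgt_fused = fused_from_manifest(tgt_manifest, config.normalization, config.chest_band)
        for pid, img in {**pre_fused, **tgt_fused}.items():
            log("fused", id=pid, n_boxes=len(img.boxes),
                red_mean=round(float(img.red.mean()), 3))

    with stage("pretrain"):
        positives = [pre_fused[e.patient_id] for e in pre_manifest.entries if e.patient_positive]
        normals = [pre_fused[e.patient_id] for e in pre_manifest.entries if not e.patient_positive]
        pre_model = pretrain_positive_only(positives, config.mining_config)
        det_mod.save_model(pre_model, out_dir / "model_pretrain_1class.pkl")
        log("pretrain", n_images=len(positives))

    with stage("mining"):
        mined = harvest_negatives(pre_model, normals, config.mining_config)
        mined.save(out_dir / "mined")
        log("mining", n_mined=len(mined))
        two_class = retrain_two_class(positives, normals, mined, config.mining_config)
        det_mod.save_model(two_class, out_dir / "model_pretrained_2class.pkl")

    with stage("cv"):
        report = run_shuffles(
            tgt_manifest,
            tgt_fused,
            two_class,
            n_shuffles=config.n_shuffles,
            k=config.k_folds,
            base_seed=config.base_seed,
            eval_config=config.eval_config,
            backend_config=config.backend_config,
            augment_plan=None,  # reference backend trains at native intensity
        )
        report.to_csv(out_dir / "cv_report.csv")
        report.to_json(out_dir / "cv_report.json")
        log("cv", **{k: v for k, (v, _s) in report.aggregates().items()})

    with stage("replay-manifest"):
        inputs = {
            "config_digest": digest,
            "pretrain_manifest": _sha256(pre_dir / "manifest.csv"),
            "target_manifest": _sha256(tgt_dir / "manifest.csv"),
            "models": {
                "pretrain_1class": pre_model.config_digest,
                "pretrained_2class": two_class.config_digest,
            },
        }
        (out_dir / "replay_manifest.json").write_text(json.dumps(inputs, indent=2))
        config.to_yaml(out_dir / "config.yaml")

    log_path.write_text("\n".join(log_lines) + "\n")
    return report, out_dir
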