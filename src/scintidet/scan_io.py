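"""I/O for whole-body bone-scan frames, box labels and dataset manifests.

This module owns every coordinate convention in the toolkit:

* Pixel coordinates are 0-based and **half-open**: a box covers the pixel
  grid ``[x_min, x_max) x [y_min, y_max)`` and its area is
  ``(x_max - x_min) * (y_max - y_min)``.  This removes all +-1 ambiguity
  from IoU arithmetic downstream.
* A native whole-body frame is 1024 rows x 512 columns of 16-bit counts,
  holding both planar views side by side: the anterior (AP) view occupies
  the left 256 columns and the posterior (PA) view the right 256 columns,
  consistent with a 1024x256 per-view acquisition matrix.  An alternative
  vertical layout can be requested explicitly.
* Label files use the de-facto one-stage-detector dialect: one box per
  line, ``<category> <x_center> <y_center> <w> <h>`` with the last four
  normalized to [0, 1].  Category indices are 0 = metastasis,
  1 = normal_hotspot, 2 = equivocal.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image

from .errors import DecodeError, LabelParseError, ValidationError

__all__ = [
    "Category",
    "Box",
    "RawScan",
    "LabeledImage",
    "ManifestEntry",
    "DatasetManifest",
    "read_scan",
    "write_scan",
    "read_labels",
    "write_labels",
    "flip_box",
    "split_frame_boxes",
]

NATIVE_SHAPE = (1024, 512)  # rows, cols of a whole-body frame
VIEW_WIDTH = 256  # columns per view in the side-by-side layout


class Category(str, Enum):
    """Hotspot category. ``metastasis`` is the clinically positive class;
    ``normal_hotspot`` covers injury, degenerative and physiological uptake;
    ``equivocal`` lacks expert consensus and is ignored at evaluation time."""

    METASTASIS = "metastasis"
    NORMAL_HOTSPOT = "normal_hotspot"
    EQUIVOCAL = "equivocal"


CATEGORY_TO_INDEX = {
    Category.METASTASIS: 0,
    Category.NORMAL_HOTSPOT: 1,
    Category.EQUIVOCAL: 2,
}
INDEX_TO_CATEGORY = {v: k for k, v in CATEGORY_TO_INDEX.items()}


@dataclass(frozen=True)
class Box:
    """One annotated or detected bounding region (half-open pixel coords)."""

    category: Category
    x_min: float
    y_min: float
    x_max: float
    y_max: float
    confidence: float = 1.0

    def __post_init__(self):
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValidationError(
                f"degenerate box: ({self.x_min},{self.y_min},{self.x_max},{self.y_max})"
            )
        if not (0.0 <= self.confidence <= 1.0):
            raise ValidationError(f"confidence {self.confidence} outside [0,1]")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    def shift(self, dx: float, dy: float) -> "Box":
        return replace(
            self,
            x_min=self.x_min + dx,
            x_max=self.x_max + dx,
            y_min=self.y_min + dy,
            y_max=self.y_max + dy,
        )

    def clip_to(self, width: float, height: float) -> "Box | None":
        """Intersect with the image rectangle; ``None`` if nothing remains."""
        x0, y0 = max(self.x_min, 0.0), max(self.y_min, 0.0)
        x1, y1 = min(self.x_max, float(width)), min(self.y_max, float(height))
        if x0 >= x1 or y0 >= y1:
            return None
        return replace(self, x_min=x0, y_min=y0, x_max=x1, y_max=y1)

    def validate_within(self, width: float, height: float, tol: float = 1e-6) -> None:
        if self.x_min < -tol or self.y_min < -tol or self.x_max > width + tol or self.y_max > height + tol:
            raise ValidationError(
                f"box ({self.x_min},{self.y_min},{self.x_max},{self.y_max}) "
                f"escapes {width}x{height} image"
            )


def flip_box(box: Box, width: float) -> Box:
    """Mirror a box left-right on an image of the given width.

    An involution: applying it twice returns the original box exactly.
    """
    return replace(box, x_min=width - box.x_max, x_max=width - box.x_min)


@dataclass
class RawScan:
    """One 16-bit whole-body acquisition (both planar views in one frame)."""

    pixels: np.ndarray
    scan_id: str
    layout: str = "side_by_side"  # or "stacked"

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValidationError(f"scan {self.scan_id}: expected 2-D pixel grid, got {px.ndim}-D")
        if px.dtype != np.uint16:
            if np.issubdtype(px.dtype, np.integer) and px.min() >= 0 and px.max() <= 65535:
                px = px.astype(np.uint16)
            else:
                raise ValidationError(f"scan {self.scan_id}: counts must be 16-bit non-negative")
        px = px.copy()
        px.setflags(write=False)  # dimensions and counts immutable after load
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def views(self) -> tuple[np.ndarray, np.ndarray]:
        """Return the (AP, PA) count grids according to the layout."""
        if self.layout == "side_by_side":
            half = self.pixels.shape[1] // 2
            return self.pixels[:, :half], self.pixels[:, half:]
        if self.layout == "stacked":
            half = self.pixels.shape[0] // 2
            return self.pixels[:half], self.pixels[half:]
        raise ValidationError(f"unknown layout {self.layout!r}")


@dataclass
class LabeledImage:
    """An image (2-D or HxWx3, 8-bit unless staging) with its boxes."""

    image: np.ndarray
    boxes: list[Box]
    source_id: str
    is_flipped: bool = False
    intensity_level: int | None = None

    def __post_init__(self):
        h, w = self.image.shape[:2]
        for b in self.boxes:
            b.validate_within(w, h)

    @property
    def width(self) -> int:
        return self.image.shape[1]

    @property
    def height(self) -> int:
        return self.image.shape[0]


# ---------------------------------------------------------------------------
# image files


def read_scan(path: str | Path, dialect: str | None = None) -> RawScan:
    """Read a single-frame 16-bit grayscale scan.

    ``dialect`` is ``"raw16"`` (16-bit PNG/TIFF, the canonical interchange
    format) or ``"dicom"``; when omitted it is inferred from the suffix.
    Counts are preserved bit-exactly — no rescaling of any kind.
    """
    path = Path(path)
    if dialect is None:
        dialect = "dicom" if path.suffix.lower() in {".dcm", ".dicom"} else "raw16"
    if dialect == "dicom":
        return _read_dicom(path)
    if dialect != "raw16":
        raise DecodeError(f"unknown dialect {dialect!r}")
    try:
        with Image.open(path) as im:
            im.load()
            arr = np.asarray(im)
    except FileNotFoundError:
        raise
    except Exception as exc:  # PIL raises a zoo of types
        raise DecodeError(f"cannot decode image file {path}: {exc}") from exc
    if arr.ndim != 2:
        raise DecodeError(f"{path}: expected single-channel image, got shape {arr.shape}")
    if arr.dtype == np.int32:  # PIL mode "I" for 16-bit PNG
        arr = arr.astype(np.int64)
    if not np.issubdtype(arr.dtype, np.integer):
        raise DecodeError(f"{path}: expected 16-bit integer pixels, got {arr.dtype}")
    if arr.min() < 0 or arr.max() > 65535:
        raise DecodeError(f"{path}: pixel values outside 16-bit range")
    return RawScan(pixels=arr.astype(np.uint16), scan_id=path.stem)


def _read_dicom(path: Path) -> RawScan:
    import pydicom

    try:
        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array
    except Exception as exc:
        raise DecodeError(f"cannot decode DICOM file {path}: {exc}") from exc
    if arr.ndim != 2:
        raise DecodeError(f"{path}: multi-frame DICOM not supported")
    if int(getattr(ds, "BitsAllocated", 16)) != 16:
        raise DecodeError(f"{path}: expected 16 bits allocated")
    return RawScan(pixels=arr.astype(np.uint16), scan_id=path.stem)


def write_scan(scan: RawScan, path: str | Path) -> Path:
    """Write a scan as a 16-bit single-channel PNG or TIFF (by suffix)."""
    path = Path(path)
    arr = np.ascontiguousarray(scan.pixels, dtype=np.uint16)
    if path.suffix.lower() in {".tif", ".tiff"}:
        Image.fromarray(arr).save(path)
    else:
        # uint16 input maps to PIL mode "I;16": a true 16-bit grayscale PNG
        Image.fromarray(arr).save(path, format="PNG")
    return path


def write_fused_png(image: np.ndarray, path: str | Path) -> Path:
    """Write an 8-bit 3-channel image (fused chest) as PNG."""
    path = Path(path)
    Image.fromarray(np.ascontiguousarray(image, dtype=np.uint8), mode="RGB").save(path)
    return path


# ---------------------------------------------------------------------------
# label files


def read_labels(path: str | Path, width: float, height: float) -> list[Box]:
    """Parse a one-box-per-line normalized label file into absolute boxes."""
    path = Path(path)
    boxes: list[Box] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 5:
                raise LabelParseError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
            try:
                idx = int(parts[0])
                xc, yc, w, h = (float(p) for p in parts[1:])
            except ValueError as exc:
                raise LabelParseError(f"{path}:{lineno}: {exc}") from exc
            if idx not in INDEX_TO_CATEGORY:
                raise LabelParseError(f"{path}:{lineno}: unknown category index {idx}")
            x_min = (xc - w / 2.0) * width
            y_min = (yc - h / 2.0) * height
            box = Box(
                category=INDEX_TO_CATEGORY[idx],
                x_min=x_min,
                y_min=y_min,
                x_max=x_min + w * width,
                y_max=y_min + h * height,
                confidence=1.0,
            )
            try:
                box.validate_within(width, height)
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            boxes.append(box)
    return boxes


def write_labels(boxes: Iterable[Box], path: str | Path, width: float, height: float) -> Path:
    path = Path(path)
    lines = []
    for b in boxes:
        b.validate_within(width, height)
        cx, cy = b.center
        lines.append(
            f"{CATEGORY_TO_INDEX[b.category]} "
            f"{cx / width:.8f} {cy / height:.8f} {b.width / width:.8f} {b.height / height:.8f}"
        )
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def split_frame_boxes(
    boxes: Sequence[Box], view_width: int = VIEW_WIDTH
) -> tuple[list[Box], list[Box]]:
    """Split native-frame boxes into (AP, PA) view-local boxes.

    A box belongs to the view containing its center; PA boxes are re-expressed
    in PA-local coordinates (origin at the left edge of the PA half).
    """
    ap, pa = [], []
    for b in boxes:
        cx, _ = b.center
        if cx < view_width:
            ap.append(b)
        else:
            pa.append(b.shift(-view_width, 0.0))
    return ap, pa


# ---------------------------------------------------------------------------
# manifests


@dataclass(frozen=True)
class ManifestEntry:
    image: str
    label: str
    patient_id: str
    cohort: str  # breast | prostate | synthetic
    patient_positive: bool


@dataclass
class DatasetManifest:
    entries: list[ManifestEntry]
    root: Path | None = None

    def __post_init__(self):
        paths = [e.image for e in self.entries]
        if len(set(paths)) != len(paths):
            raise ValidationError("manifest image paths are not unique")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_positive(self) -> int:
        return sum(e.patient_positive for e in self.entries)

    def subset(self, positive: bool | None = None) -> "DatasetManifest":
        kept = [e for e in self.entries if positive is None or e.patient_positive == positive]
        return DatasetManifest(entries=kept, root=self.root)

    def resolve(self, rel: str) -> Path:
        return (self.root / rel) if self.root is not None else Path(rel)


MANIFEST_HEADER = ["image", "label", "patient_id", "cohort", "patient_positive"]


def read_manifest(path: str | Path) -> DatasetManifest:
    path = Path(path)
    entries = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != MANIFEST_HEADER:
            raise ValidationError(f"{path}: bad manifest header {reader.fieldnames}")
        for row in reader:
            entries.append(
                ManifestEntry(
                    image=row["image"],
                    label=row["label"],
                    patient_id=row["patient_id"],
                    cohort=row["cohort"],
                    patient_positive=row["patient_positive"].strip().lower() == "true",
                )
            )
    return DatasetManifest(entries=entries, root=path.parent)


def write_manifest(manifest: DatasetManifest, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_HEADER)
        for e in manifest.entries:
            writer.writerow([e.image, e.label, e.patient_id, e.cohort, str(e.patient_positive).lower()])
    return path
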