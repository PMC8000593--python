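"""Whole-body scan preprocessing.

The acquired scans show wide patient-to-patient variation in count density
(tracer dose, metabolism, leakage), so before any detection the pipeline

1. finds the body extent in each view from row/column projection profiles,
2. cuts the body and centers it — without scaling or any other geometric
   transform — on a zero 512 x 950 canvas, and
3. controls the average canvas intensity into a target range ``(T1, T2)``
   (default (7, 14)) by iterative multiplicative scaling with 8-bit
   saturation, producing the 8-bit working image.

A rule-based chest extractor then cuts a fixed fractional band of the
detected body height — identical in both views — standing in for a learned
chest localizer.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._util import round_half_away
from .errors import (
    CenteringError,
    DetectionRangeError,
    ExtractionError,
    NormalizationError,
)
from .scan_io import Box, RawScan

CANVAS_SHAPE = (950, 512)  # rows, cols of the per-view working canvas

__all__ = [
    "NormalizationRange",
    "ViewPair",
    "ChestROI",
    "detect_body_range",
    "split_and_center",
    "normalize_intensity",
    "normalize_pair",
    "extract_chest",
]


@dataclass(frozen=True)
class NormalizationRange:
    """Open target interval for the average canvas intensity."""

    T1: float = 7.0
    T2: float = 14.0
    max_iterations: int = 10

    def __post_init__(self):
        if not (0 < self.T1 < self.T2 <= 255):
            raise NormalizationError(f"invalid range ({self.T1}, {self.T2})")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.T1 + self.T2)


def detect_body_range(
    image: np.ndarray, tau: float = 0.01
) -> tuple[int, int, int, int]:
    """Locate the body from projection profiles.

    Returns the smallest half-open ``(row_min, row_max, col_min, col_max)``
    such that the row-sum and column-sum profiles outside it are each below
    ``tau * max(profile)``.  ``tau`` defaults to 1% of the profile maximum,
    which is robust to isolated stray counts.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0 or image.sum() <= 0:
        raise DetectionRangeError("cannot detect body range on an all-zero image")
    row_profile = image.sum(axis=1)
    col_profile = image.sum(axis=0)
    rows = np.flatnonzero(row_profile >= tau * row_profile.max())
    cols = np.flatnonzero(col_profile >= tau * col_profile.max())
    return int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1


@dataclass
class ViewPair:
    """Centered AP/PA canvases with placement bookkeeping.

    ``*_offset`` is the (row, col) of the body crop's top-left corner on the
    canvas; ``*_body_rows`` the half-open row span the body occupies on the
    canvas.  Boxes are carried per view in canvas coordinates.
    """

    ap: np.ndarray
    pa: np.ndarray
    ap_offset: tuple[int, int]
    pa_offset: tuple[int, int]
    ap_body_rows: tuple[int, int]
    pa_body_rows: tuple[int, int]
    ap_boxes: list[Box] = field(default_factory=list)
    pa_boxes: list[Box] = field(default_factory=list)
    source_id: str = ""

    def __post_init__(self):
        for name in ("ap", "pa"):
            arr = getattr(self, name)
            if arr.shape != CANVAS_SHAPE:
                raise CenteringError(f"{name} canvas is {arr.shape}, expected {CANVAS_SHAPE}")
        h, w = CANVAS_SHAPE
        for b in self.ap_boxes + self.pa_boxes:
            b.validate_within(w, h)


def _center_view(
    view: np.ndarray, boxes: list[Box], tau: float
) -> tuple[np.ndarray, tuple[int, int], tuple[int, int], list[Box]]:
    r0, r1, c0, c1 = detect_body_range(view, tau=tau)
    crop = view[r0:r1, c0:c1]
    ch, cw = crop.shape
    H, W = CANVAS_SHAPE
    if ch > H or cw > W:
        raise CenteringError(f"body crop {ch}x{cw} exceeds canvas {H}x{W}")
    off_r = (H - ch) // 2
    off_c = (W - cw) // 2
    canvas = np.zeros(CANVAS_SHAPE, dtype=np.float64)
    canvas[off_r : off_r + ch, off_c : off_c + cw] = crop
    # rigid shift: crop origin -> canvas offset
    moved = [b.shift(off_c - c0, off_r - r0) for b in boxes]
    moved = [m for m in (b.clip_to(W, H) for b in moved) if m is not None]
    return canvas, (off_r, off_c), (off_r, off_r + ch), moved


def split_and_center(
    scan: RawScan,
    ap_boxes: list[Box] | None = None,
    pa_boxes: list[Box] | None = None,
    tau: float = 0.01,
) -> ViewPair:
    """Cut each view's body and center it on a zero 512-wide x 950-tall canvas.

    No resampling occurs; ground-truth boxes are translated by the same
    rigid offsets.  The returned pair is a 16-bit staging object (float
    counts); :func:`normalize_pair` converts it to 8-bit.
    """
    ap_view, pa_view = scan.views()
    ap, ap_off, ap_rows, ap_b = _center_view(np.asarray(ap_view, float), list(ap_boxes or []), tau)
    pa, pa_off, pa_rows, pa_b = _center_view(np.asarray(pa_view, float), list(pa_boxes or []), tau)
    return ViewPair(
        ap=ap,
        pa=pa,
        ap_offset=ap_off,
        pa_offset=pa_off,
        ap_body_rows=ap_rows,
        pa_body_rows=pa_rows,
        ap_boxes=ap_b,
        pa_boxes=pa_b,
        source_id=scan.scan_id,
    )


def normalize_intensity(
    image: np.ndarray, range_: NormalizationRange = NormalizationRange()
) -> tuple[np.ndarray, float, int]:
    """Control the average canvas intensity into the open range ``(T1, T2)``.

    Iterates: compute the full-canvas mean in double precision; if it lies in
    the open interval, stop; otherwise scale every pixel by
    ``midpoint / mean``, clip to [0, 255] and round half away from zero.
    Saturation can drag the mean back below target, hence the re-check loop
    (at most ``max_iterations`` rounds; a warning is emitted on pathological
    non-convergence).  Idempotent: a second application sees the mean already
    in range and returns the image unchanged.

    Returns ``(uint8 image, achieved mean, iterations used)``.
    """
    work = np.asarray(image, dtype=np.float64)
    m = float(work.mean())
    if m <= 0:
        raise NormalizationError("zero-mean input cannot be normalized")
    iterations = 0
    while not (range_.T1 < m < range_.T2):
        if iterations >= range_.max_iterations:
            warnings.warn(
                f"intensity normalization exhausted {range_.max_iterations} iterations "
                f"(mean={m:.3f}, target=({range_.T1},{range_.T2}))",
                stacklevel=2,
            )
            break
        scale = range_.midpoint / m
        work = round_half_away(np.clip(work * scale, 0.0, 255.0))
        m = float(work.mean())
        iterations += 1
        if m <= 0:
            raise NormalizationError("normalization collapsed the image to zero")
    return work.astype(np.uint8), m, iterations


def normalize_pair(
    pair: ViewPair, range_: NormalizationRange = NormalizationRange()
) -> tuple[ViewPair, dict]:
    """Normalize both canvases of a staged pair to 8-bit; boxes unchanged."""
    ap8, m_ap, it_ap = normalize_intensity(pair.ap, range_)
    pa8, m_pa, it_pa = normalize_intensity(pair.pa, range_)
    out = ViewPair(
        ap=ap8,
        pa=pa8,
        ap_offset=pair.ap_offset,
        pa_offset=pair.pa_offset,
        ap_body_rows=pair.ap_body_rows,
        pa_body_rows=pair.pa_body_rows,
        ap_boxes=list(pair.ap_boxes),
        pa_boxes=list(pair.pa_boxes),
        source_id=pair.source_id,
    )
    info = {"ap_mean": m_ap, "pa_mean": m_pa, "ap_iterations": it_ap, "pa_iterations": it_pa}
    return out, info


@dataclass
class ChestROI:
    """Equal-sized chest crops of both views with translated/clipped boxes."""

    ap_chest: np.ndarray
    pa_chest: np.ndarray
    crop: tuple[int, int, int, int]  # row0, row1, col0, col1 in canvas coords
    ap_boxes: list[Box] = field(default_factory=list)
    pa_boxes: list[Box] = field(default_factory=list)
    source_id: str = ""

    def __post_init__(self):
        if self.ap_chest.shape != self.pa_chest.shape:
            raise ExtractionError("chest crops differ in size between views")
        h, w = self.ap_chest.shape[:2]
        for b in self.ap_boxes + self.pa_boxes:
            b.validate_within(w, h)


def extract_chest(pair: ViewPair, band: tuple[float, float] = (0.10, 0.45)) -> ChestROI:
    """Cut the chest band — a fixed fraction of the detected body height.

    The crop spans the full canvas width and rows
    ``[body_top + band[0]*H_body, body_top + band[1]*H_body)`` where the body
    span is the union of the two views' placements, so one identical
    rectangle applies to both views.  Boxes are translated into crop
    coordinates; boxes wholly outside are dropped, straddling ones clipped.
    """
    body_top = min(pair.ap_body_rows[0], pair.pa_body_rows[0])
    body_bottom = max(pair.ap_body_rows[1], pair.pa_body_rows[1])
    h_body = body_bottom - body_top
    if h_body < 100:
        raise ExtractionError(f"detected body height {h_body} px is too short")
    r0 = int(round(body_top + band[0] * h_body))
    r1 = int(round(body_top + band[1] * h_body))
    H, W = CANVAS_SHAPE
    r0, r1 = max(0, r0), min(H, r1)

    def move(boxes: list[Box]) -> list[Box]:
        shifted = (b.shift(0.0, -float(r0)) for b in boxes)
        return [m for m in (b.clip_to(W, r1 - r0) for b in shifted) if m is not None]

    return ChestROI(
        ap_chest=pair.ap[r0:r1, :].copy(),
        pa_chest=pair.pa[r0:r1, :].copy(),
        crop=(r0, r1, 0, W),
        ap_boxes=move(pair.ap_boxes),
        pa_boxes=move(pair.pa_boxes),
        source_id=pair.source_id,
    )
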