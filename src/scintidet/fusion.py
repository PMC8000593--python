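"""Three-channel AP/PA fusion and offline intensity/flip augmentation.

Feeding the two planar views separately loses their spatial correspondence,
so the detector input is a color image built from both: the AP chest is the
red channel, the left-right-flipped PA chest the green channel, and the
third channel is the pixelwise AP x flipped-PA product rescaled so its mean
matches the mean of the two view means.  A metastasis projects to roughly
mirrored positions in the two views, so it lights up all three channels at
one location.

Offline augmentation then emits each fused chest at ``n_levels`` average
intensities evenly placed inside the open range (25, 48) — below 25 faint
ribs vanish, above 48 images approach superscan ambiguity — and a
horizontal mirror of each, multiplying the dataset by 12 with the defaults.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._util import round_half_away
from .errors import FusionError, ValidationError
from .preprocess import ChestROI
from .scan_io import Box, flip_box

__all__ = ["FusedImage", "AugmentPlan", "fuse", "augment"]


@dataclass
class FusedImage:
    """8-bit three-channel chest image with merged AP/PA ground truth.

    Channels (equal size): red = AP chest, green = flipped PA chest,
    third = scaled product.  ``boxes`` is the union of the AP boxes and the
    flipped PA boxes — duplicates from the two views are kept here and
    merged only at evaluation time.
    """

    red: np.ndarray
    green: np.ndarray
    third: np.ndarray
    boxes: list[Box] = field(default_factory=list)
    source_id: str = ""
    intensity_level: int | None = None
    is_flipped: bool = False

    def __post_init__(self):
        if not (self.red.shape == self.green.shape == self.third.shape):
            raise FusionError("fused channels differ in size")
        h, w = self.red.shape
        for b in self.boxes:
            b.validate_within(w, h)

    @property
    def width(self) -> int:
        return self.red.shape[1]

    @property
    def height(self) -> int:
        return self.red.shape[0]

    def stack(self) -> np.ndarray:
        """HxWx3 uint8 array (red, green, third)."""
        return np.stack([self.red, self.green, self.third], axis=-1)


@dataclass(frozen=True)
class AugmentPlan:
    """Offline augmentation parameters."""

    target_range: tuple[float, float] = (25.0, 48.0)
    n_levels: int = 6
    include_flips: bool = True

    def __post_init__(self):
        low, high = self.target_range
        if not low < high:
            raise ValidationError(f"invalid target range {self.target_range}")
        if self.n_levels < 1:
            raise ValidationError("n_levels must be >= 1")

    def level_targets(self) -> list[float]:
        """Evenly spaced midpoints of ``n_levels`` equal sub-intervals.

        For the defaults: 26.917, 30.75, 34.583, 38.417, 42.25, 46.083 —
        uniform over (25, 48) while keeping clear of both boundaries.
        """
        low, high = self.target_range
        n = self.n_levels
        return [low + (high - low) * (2 * k - 1) / (2 * n) for k in range(1, n + 1)]


def _scale_to_mean(
    channels: list[np.ndarray], target: float, tol: float = 0.5, max_iterations: int = 10
) -> tuple[list[np.ndarray], float]:
    """Jointly rescale 8-bit channels so the first channel's mean hits target.

    One factor for all channels (preserving channel ratios), with the same
    clip-round-recheck iteration as intensity normalization to absorb
    saturation losses.
    """
    work = [np.asarray(c, dtype=np.float64) for c in channels]
    m = float(work[0].mean())
    if m <= 0:
        raise FusionError("cannot rescale a zero-mean image")
    for _ in range(max_iterations):
        if abs(m - target) <= tol:
            break
        factor = target / m
        work = [round_half_away(np.clip(c * factor, 0.0, 255.0)) for c in work]
        m = float(work[0].mean())
        if m <= 0:
            raise FusionError("rescaling collapsed the image to zero")
    return [c.astype(np.uint8) for c in work], m


def fuse(chest: ChestROI) -> FusedImage:
    """Build the three-channel detector input from a chest ROI.

    The product channel's scale is chosen so its mean equals the mean of the
    two view means; a short fixed-point refinement compensates for 8-bit
    saturation of bright hotspot products (constant images are unaffected —
    there the single-shot scale is already exact).
    """
    ap = np.asarray(chest.ap_chest, dtype=np.float64)
    pa = np.asarray(chest.pa_chest, dtype=np.float64)
    if ap.shape != pa.shape:
        raise FusionError(f"view size mismatch: {ap.shape} vs {pa.shape}")
    pa_flipped = pa[:, ::-1]
    product = ap * pa_flipped
    target = 0.5 * (ap.mean() + pa_flipped.mean())
    prod_mean = product.mean()
    if prod_mean <= 0:
        third = np.zeros_like(ap)
    else:
        s = target / prod_mean
        third = round_half_away(np.clip(s * product, 0.0, 255.0))
        for _ in range(5):  # absorb saturation loss
            m = third.mean()
            if abs(m - target) <= 0.25 or m <= 0:
                break
            third = round_half_away(np.clip(third * (target / m), 0.0, 255.0))
    w = ap.shape[1]
    boxes = list(chest.ap_boxes) + [flip_box(b, w) for b in chest.pa_boxes]
    return FusedImage(
        red=ap.astype(np.uint8),
        green=pa_flipped.astype(np.uint8),
        third=third.astype(np.uint8),
        boxes=boxes,
        source_id=chest.source_id,
    )


def augment(fused: FusedImage, plan: AugmentPlan = AugmentPlan()) -> list[FusedImage]:
    """Emit the offline augmentation set for one fused image.

    For each of ``n_levels`` target means the three channels are jointly
    rescaled so the red-channel mean reaches the target; if flips are on,
    each variant is also emitted horizontally mirrored with its boxes
    flipped.  Output count = ``n_levels * (2 if include_flips else 1)`` —
    exactly 12 with the defaults.  Box geometry is untouched by intensity
    re-leveling.
    """
    out: list[FusedImage] = []
    for level, target in enumerate(plan.level_targets()):
        channels, _achieved = _scale_to_mean([fused.red, fused.green, fused.third], target)
        red, green, third = channels
        leveled = FusedImage(
            red=red,
            green=green,
            third=third,
            boxes=list(fused.boxes),
            source_id=fused.source_id,
            intensity_level=level,
            is_flipped=False,
        )
        out.append(leveled)
        if plan.include_flips:
            w = leveled.width
            out.append(
                FusedImage(
                    red=leveled.red[:, ::-1].copy(),
                    green=leveled.green[:, ::-1].copy(),
                    third=leveled.third[:, ::-1].copy(),
                    boxes=[flip_box(b, w) for b in leveled.boxes],
                    source_id=fused.source_id,
                    intensity_level=level,
                    is_flipped=True,
                )
            )
    return out
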