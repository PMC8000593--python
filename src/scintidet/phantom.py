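"""Synthetic whole-body scintigraphy phantoms.

The phantom emulates the statistical structure of planar gamma-camera bone
scans well enough to exercise every downstream stage without clinical data:

* a schematic body silhouette (head/torso/pelvis/legs) with elevated uptake
  along the spine, rib arcs, shoulder and knee joints;
* focal metastatic hotspots: bright Gaussian blobs (peak 3-8x the local
  background) placed in the chest region, each with a tight ground-truth box
  in both views;
* benign patterns that mimic the two classic confounders — post-trauma
  "injury chains" of >=3 collinear blobs along a rib arc, and intensity-
  matched left/right symmetric pairs at the shoulder joints;
* optional bladder and injection-leak artifacts (bright, un-annotated, and
  outside the chest band);
* wide global-intensity variation (log-uniform gain) and Poisson counting
  noise applied to the count image last.

Geometry is schematic, not anatomical: nothing downstream depends on anatomy
beyond left/right mirror symmetry between the AP and PA views and the
existence of a chest sub-region.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._util import child_seed
from .errors import GenerationError
from .scan_io import (
    Box,
    Category,
    DatasetManifest,
    ManifestEntry,
    RawScan,
    write_labels,
    write_manifest,
    write_scan,
)

VIEW_SHAPE = (1024, 256)  # rows, cols of one view
FRAME_SHAPE = (1024, 512)

# Body geometry in view coordinates (row, col); the view is 256 wide with
# the midline at column 128.  The body spans rows ~36..950 (height ~914) so
# that the crop always fits the 512x950 preprocessing canvas.
_MID = 128.0
_BODY_TOP = 36.0
_BODY_BOTTOM = 950.0
# Chest band used for lesion placement: matches the fractional chest rule
# (0.10..0.45 of body height below the body top) with a safety margin.
CHEST_ROWS = (150, 430)
SHOULDER = (170.0, 75.0)  # row, |col offset from midline| of the joints


@dataclass(frozen=True)
class PhantomConfig:
    """Generation parameters for one synthetic scan.

    ``global_gain`` multiplies the whole expected count image and emulates
    the large patient-to-patient variation in tracer uptake / acquisition
    time; when sampled by :func:`generate_cohort` it is log-uniform in
    [0.25, 4] so the normalization stage has real work to do.
    """

    seed: int = 0
    n_metastases: int = 0
    n_benign: int = 0
    global_gain: float = 1.0
    add_bladder: bool = False
    add_injection_leak: bool = False
    noise: str = "poisson"  # or "none"

    def __post_init__(self):
        if self.n_metastases < 0 or self.n_benign < 0:
            raise GenerationError("lesion counts must be >= 0")
        if self.global_gain <= 0:
            raise GenerationError("global_gain must be positive")
        if self.noise not in {"poisson", "none"}:
            raise GenerationError(f"unknown noise model {self.noise!r}")


def _ellipse_mask(shape, center, radii):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / radii[0]) ** 2 + ((cc - center[1]) / radii[1]) ** 2 <= 1.0


_TEMPLATE_CACHE: dict[str, np.ndarray] = {}


def _base_template(view: str) -> np.ndarray:
    """Noise-free baseline uptake for one view (cached; geometry is fixed)."""
    if view in _TEMPLATE_CACHE:
        return _TEMPLATE_CACHE[view]
    H, W = VIEW_SHAPE
    img = np.zeros(VIEW_SHAPE, dtype=np.float64)

    # soft-tissue silhouette
    img[_ellipse_mask(VIEW_SHAPE, (72, _MID), (36, 27))] += 5.0          # head
    img[140:175, int(_MID) - 12 : int(_MID) + 12] += 5.0                 # neck
    img[_ellipse_mask(VIEW_SHAPE, (330, _MID), (210, 80))] += 5.0        # torso
    img[_ellipse_mask(VIEW_SHAPE, (590, _MID), (95, 72))] += 5.0         # pelvis
    for side in (-1, 1):
        leg_c = _MID + side * 36
        img[_ellipse_mask(VIEW_SHAPE, (805, leg_c), (146, 23))] += 5.0   # legs

    def stamp(r, c, sigma, amp):
        _stamp_blob(img, r, c, sigma, amp)

    # skeleton: spine column (posterior view sees it brighter)
    spine_amp = 8.0 if view == "pa" else 6.0
    cols = np.arange(W, dtype=np.float64)
    spine_profile = spine_amp * np.exp(-((cols - _MID) ** 2) / (2 * 5.0**2))
    img[150:650, :] += spine_profile[None, :]

    # rib arcs: thin drooping curves from the spine to the lateral margin
    rib_amp = 3.5 if view == "ap" else 2.8
    for i in range(8):
        r0 = 195 + 30 * i
        for t in np.linspace(0.05, 1.0, 40):
            dr = 30.0 * t**1.6
            dx = 12.0 + 63.0 * t
            for side in (-1, 1):
                stamp(r0 + dr, _MID + side * dx, 2.0, rib_amp)

    # joints: shoulders, sacro-pelvic rim, knees
    for side in (-1, 1):
        stamp(SHOULDER[0], _MID + side * SHOULDER[1], 6.0, 7.0)
        stamp(640.0, _MID + side * 40.0, 6.0, 5.0)
        stamp(805.0, _MID + side * 36.0, 5.0, 5.0)

    if view == "pa":
        img = img[:, ::-1]  # posterior acquisition mirrors left/right
    img = np.ascontiguousarray(img)
    img.setflags(write=False)
    _TEMPLATE_CACHE[view] = img
    return img


def _stamp_blob(img: np.ndarray, r: float, c: float, sigma: float, amp: float) -> None:
    """Add a truncated Gaussian blob in-place (local window for speed)."""
    H, W = img.shape
    rad = int(np.ceil(3.5 * sigma))
    r0, r1 = max(0, int(r) - rad), min(H, int(r) + rad + 1)
    c0, c1 = max(0, int(c) - rad), min(W, int(c) + rad + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1].astype(np.float64)
    img[r0:r1, c0:c1] += amp * np.exp(-(((rr - r) ** 2 + (cc - c) ** 2) / (2 * sigma**2)))


@dataclass
class _Hotspot:
    row: float
    col: float  # AP-view column; PA column is mirrored
    sigma: float
    amp_ap: float
    amp_pa: float
    category: Category | None  # None -> artifact, carries no box

    def box(self, view: str, jitter: tuple[float, float] = (0.0, 0.0)) -> Box | None:
        if self.category is None:
            return None
        W = VIEW_SHAPE[1]
        col = self.col if view == "ap" else W - self.col
        half = max(3.0, 2.2 * self.sigma)
        b = Box(
            category=self.category,
            x_min=col - half + jitter[1],
            y_min=self.row - half + jitter[0],
            x_max=col + half + jitter[1],
            y_max=self.row + half + jitter[0],
            confidence=1.0,
        )
        return b.clip_to(W, VIEW_SHAPE[0])


def _inside_torso(r: float, c: float) -> bool:
    return ((r - 330) / 195) ** 2 + ((c - _MID) / 72) ** 2 <= 1.0


def _plan_hotspots(config: PhantomConfig, rng: np.random.Generator) -> list[_Hotspot]:
    spots: list[_Hotspot] = []
    template = _base_template("ap")

    def local_bg(r, c):
        return max(5.0, float(template[int(r), int(c)]))

    # --- metastases: focal blobs in the chest band, peak 3-8x local background
    placed = 0
    for _ in range(200):
        if placed == config.n_metastases:
            break
        r = rng.uniform(*CHEST_ROWS)
        c = rng.uniform(_MID - 68, _MID + 68)
        if not _inside_torso(r, c):
            continue
        if any(abs(s.row - r) < 24 and abs(s.col - c) < 24 for s in spots):
            continue
        sigma = rng.uniform(1.6, 5.0)
        factor = rng.uniform(3.0, 8.0)
        amp = factor * local_bg(r, c)
        spots.append(_Hotspot(r, c, sigma, amp, amp * rng.uniform(0.75, 1.0), Category.METASTASIS))
        placed += 1
    if placed < config.n_metastases:
        raise GenerationError("could not place all metastases after bounded retries")

    # --- benign patterns: rib-line injury chains and symmetric joint pairs
    for j in range(config.n_benign):
        kind = "chain" if (j + int(rng.integers(0, 2))) % 2 == 0 else "pair"
        if kind == "chain":
            rib = int(rng.integers(1, 7))
            r0 = 195 + 30 * rib
            side = -1 if rng.random() < 0.5 else 1
            n_blobs = int(rng.integers(3, 6))
            ts = np.sort(rng.uniform(0.25, 0.95, size=n_blobs))
            amp = rng.uniform(3.0, 5.0)
            for t in ts:
                r = r0 + 30.0 * t**1.6
                c = _MID + side * (12.0 + 63.0 * t)
                sigma = rng.uniform(1.6, 2.6)
                a = amp * local_bg(r, c)
                spots.append(
                    _Hotspot(r, c, sigma, a, a * rng.uniform(0.8, 1.0), Category.NORMAL_HOTSPOT)
                )
        else:
            dr = rng.uniform(-8, 8)
            dc = rng.uniform(-6, 6)
            sigma = rng.uniform(2.0, 4.0)
            amp = rng.uniform(3.0, 6.0) * local_bg(SHOULDER[0], _MID + SHOULDER[1])
            for side in (-1, 1):  # intensity-matched left/right pair
                spots.append(
                    _Hotspot(
                        SHOULDER[0] + dr,
                        _MID + side * (SHOULDER[1] + dc),
                        sigma,
                        amp,
                        amp * 0.9,
                        Category.NORMAL_HOTSPOT,
                    )
                )

    # --- artifacts (no ground-truth box; outside the chest band)
    if config.add_bladder:
        amp = rng.uniform(30.0, 80.0)
        spots.append(_Hotspot(620.0, _MID + rng.uniform(-5, 5), 7.0, amp, amp * 0.8, None))
    if config.add_injection_leak:
        amp = rng.uniform(25.0, 60.0)
        spots.append(_Hotspot(rng.uniform(480, 520), _MID - 98.0, 4.0, amp, amp * 0.7, None))
    return spots


def render_expectation(config: PhantomConfig) -> tuple[np.ndarray, list[Box], list[Box]]:
    """Noise-free expected count image (float, full frame) plus view boxes.

    This is the Poisson intensity surface; :func:`generate_scan` quantizes it
    (``noise="none"``) or samples from it (``noise="poisson"``).  Gain scales
    the expectation exactly, so two renders at gains g1, g2 with the same
    seed have pixelwise ratio g2/g1 before any clipping/quantization.
    """
    rng = np.random.default_rng(config.seed)
    # small whole-body placement jitter so phantoms are not pixel-aligned
    dr = float(rng.integers(-8, 9))
    dc = float(rng.integers(-6, 7))
    spots = _plan_hotspots(config, rng)

    ap = _base_template("ap").copy()
    pa = _base_template("pa").copy()
    W = VIEW_SHAPE[1]
    for s in spots:
        _stamp_blob(ap, s.row, s.col, s.sigma, s.amp_ap)
        _stamp_blob(pa, s.row, W - s.col, s.sigma, s.amp_pa)
    ap = np.roll(ap, (int(dr), int(dc)), axis=(0, 1))
    pa = np.roll(pa, (int(dr), -int(dc)), axis=(0, 1))

    ap_boxes = [b for s in spots if (b := s.box("ap", (dr, dc))) is not None]
    pa_boxes = [b for s in spots if (b := s.box("pa", (dr, -dc))) is not None]
    frame = np.concatenate([ap, pa], axis=1) * config.global_gain
    return frame, ap_boxes, pa_boxes


def generate_scan(config: PhantomConfig) -> tuple[RawScan, list[Box], list[Box]]:
    """Generate one synthetic whole-body scan with per-view ground truth.

    Returns ``(scan, ap_boxes, pa_boxes)``; boxes are view-local (each view
    is 256 wide), all with confidence 1.0.  Output is bit-reproducible for a
    fixed config.
    """
    expectation, ap_boxes, pa_boxes = render_expectation(config)
    if config.noise == "poisson":
        noise_rng = np.random.default_rng(child_seed(config.seed, "poisson"))
        counts = noise_rng.poisson(expectation)
    else:
        counts = np.floor(expectation + 0.5).astype(np.int64)
    counts = np.clip(counts, 0, 32767).astype(np.uint16)
    scan = RawScan(pixels=counts, scan_id=f"phantom_{config.seed}")
    return scan, ap_boxes, pa_boxes


def frame_boxes(ap_boxes: list[Box], pa_boxes: list[Box]) -> list[Box]:
    """Express view-local boxes in native-frame coordinates (PA shifted right)."""
    return list(ap_boxes) + [b.shift(VIEW_SHAPE[1], 0.0) for b in pa_boxes]


def sample_cohort_config(
    patient_positive: bool, seed: int, noise: str = "poisson"
) -> PhantomConfig:
    """Draw one patient's generation parameters.

    Lesion multiplicities follow the cohort structure the phantom emulates:
    positives carry 1-5 metastases (cohort mean ~2.7 per scan) plus 0-2
    benign hotspots; negatives are metastasis-free with 1-4 benign hotspots
    (the "normal with injury" group).  Gain is log-uniform in [0.25, 4].
    """
    rng = np.random.default_rng(child_seed(seed, "cohort-config"))
    gain = float(np.exp(rng.uniform(np.log(0.25), np.log(4.0))))
    if patient_positive:
        n_met = int(rng.integers(1, 6))
        n_benign = int(rng.integers(0, 3))
    else:
        n_met = 0
        n_benign = int(rng.integers(1, 5))
    return PhantomConfig(
        seed=seed,
        n_metastases=n_met,
        n_benign=n_benign,
        global_gain=gain,
        add_bladder=bool(rng.random() < 0.3),
        add_injection_leak=bool(rng.random() < 0.15),
        noise=noise,
    )


def generate_cohort(
    n_positive: int,
    n_negative: int,
    seed: int,
    out_dir: str | Path,
    cohort: str = "synthetic",
    noise: str = "poisson",
) -> DatasetManifest:
    """Write a cohort of phantom scans + labels + manifest to ``out_dir``.

    Exactly ``n_positive`` manifest entries have ``patient_positive=True``.
    Labels are written in native-frame coordinates (512 x 1024 normalized).
    Deterministic: the same arguments produce byte-identical output.
    """
    out_dir = Path(out_dir)
    scans_dir = out_dir / "scans"
    labels_dir = out_dir / "labels"
    scans_dir.mkdir(parents=True, exist_ok=True)
    labels_dir.mkdir(parents=True, exist_ok=True)

    entries = []
    flags = [True] * n_positive + [False] * n_negative
    for i, positive in enumerate(flags):
        pid = f"{cohort}_{i:04d}"
        cfg = sample_cohort_config(positive, seed=child_seed(seed, cohort, i), noise=noise)
        scan, ap_boxes, pa_boxes = generate_scan(cfg)
        img_rel = f"scans/{pid}.png"
        lab_rel = f"labels/{pid}.txt"
        write_scan(scan, out_dir / img_rel)
        write_labels(
            frame_boxes(ap_boxes, pa_boxes),
            out_dir / lab_rel,
            width=FRAME_SHAPE[1],
            height=FRAME_SHAPE[0],
        )
        entries.append(
            ManifestEntry(
                image=img_rel,
                label=lab_rel,
                patient_id=pid,
                cohort=cohort,
                patient_positive=positive,
            )
        )
    manifest = DatasetManifest(entries=entries, root=out_dir)
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
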