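"""Preprocessing: contrast stretching, ray-cast boundary masks, ROI
extraction, annulus patch tiling and class-asymmetric augmentation.

The contrast map sends normalized intensity x to 0 below L, to 1 above H and
to x**gamma in between; L and H default to the 1st and 99th percentiles of
the image.  The lesion boundary is found by casting equally spaced radial
rays from the probe center and marking, on each smoothed intensity profile,
the first persistent drop below a fraction of the running maximum past the
probe disc; radii are median-filtered over angle and the closed polygon is
filled into a mask.

Patches are the 32x32 windows of a greedy row-major tiling whose four corner
pixels all lie inside (2–5 mm annulus) ∩ lesion; windows never overlap.
Coordinates are 0-based (row, col) with half-open windows [r, r+32) x
[c, c+32).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import draw as skdraw

from .types import (BoundaryError, Cohort, DegenerateContrastError, EbusImage,
                    LesionMask, PatientRecord)

__all__ = [
    "ContrastParams",
    "RingSpec",
    "Patch",
    "PatchSet",
    "contrast_stretch",
    "percentile_thresholds",
    "detect_boundary",
    "extract_roi",
    "select_patches",
    "augment",
]


@dataclass
class ContrastParams:
    L: float
    H: float
    gamma: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.L < self.H <= 1.0):
            raise ValueError("need 0 <= L < H <= 1")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass
class RingSpec:
    """The 2–5 mm annulus around the probe and the 32-px window side."""

    r_inner_mm: float = 2.0
    r_outer_mm: float = 5.0
    patch_side: int = 32

    def __post_init__(self):
        if self.r_inner_mm >= self.r_outer_mm:
            raise ValueError("r_inner must be < r_outer")
        if self.patch_side < 1:
            raise ValueError("patch_side must be >= 1")


@dataclass
class Patch:
    row: int
    col: int
    side: int
    pixels: np.ndarray


@dataclass
class PatchSet:
    patches: list[Patch]
    image_id: str = ""

    def __len__(self) -> int:
        return len(self.patches)

    @property
    def origins(self) -> list[tuple[int, int]]:
        return [(p.row, p.col) for p in self.patches]


def contrast_stretch(image: EbusImage, params: ContrastParams) -> EbusImage:
    """Piecewise power-law contrast stretch on the normalized grayscale image."""
    x = image.gray / 255.0
    out = np.empty_like(x)
    low = x < params.L
    high = x > params.H
    mid = ~(low | high)
    out[low] = 0.0
    out[high] = 1.0
    out[mid] = x[mid] ** params.gamma
    stretched = np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8)
    return image.with_pixels(stretched)


def percentile_thresholds(image: EbusImage, lo: float = 1.0, hi: float = 99.0) -> ContrastParams:
    """L and H at the given intensity percentiles (normalized to [0, 1])."""
    x = image.gray.ravel() / 255.0
    if x.size == 0:
        raise ValueError("empty image")
    L = float(np.percentile(x, lo))
    H = float(np.percentile(x, hi))
    if L >= H:
        raise DegenerateContrastError(
            f"percentile thresholds coincide (L={L:.4f}, H={H:.4f})")
    return ContrastParams(L=L, H=H)


def _ray_profiles(gray: np.ndarray, center: tuple[int, int], n_rays: int,
                  r_max: int) -> np.ndarray:
    """(n_rays, r_max) bilinear samples along equally spaced rays."""
    angles = np.linspace(0, 2 * np.pi, n_rays, endpoint=False)
    radii = np.arange(r_max, dtype=float)
    rr = center[0] + np.outer(np.sin(angles), radii)
    cc = center[1] + np.outer(np.cos(angles), radii)
    return ndimage.map_coordinates(gray, [rr, cc], order=1, mode="constant")


def detect_boundary(enhanced: EbusImage, n_rays: int = 180, *,
                    drop_fraction: float = 0.35, persistence_px: int = 40,
                    median_window: int = 9, smooth_px: float = 3.0) -> LesionMask:
    """Ray-cast lesion boundary detection around the probe.

    Along each radial intensity profile (Gaussian-smoothed with
    ``smooth_px``), the probe disc is skipped first (intensity falling below
    half the central brightness), the running maximum is then restarted, and
    the boundary radius is the first sample where the profile stays below
    ``drop_fraction`` of that running maximum for ``persistence_px``
    consecutive samples.  Radii are circular-median filtered over angle with
    window ``median_window``; the closed polygon is filled into the mask.
    """
    if n_rays < 8:
        raise ValueError("need at least 8 rays")
    gray = enhanced.gray
    if gray.max() <= 0:
        raise BoundaryError("all-dark image")
    h, w = gray.shape
    cr, cc = enhanced.probe_center
    r_max = int(min(cr, cc, h - 1 - cr, w - 1 - cc))
    prof = _ray_profiles(gray, (cr, cc), n_rays, r_max)
    prof = ndimage.gaussian_filter1d(prof, smooth_px, axis=1)

    center_level = float(prof[:, :3].mean())
    radii = np.empty(n_rays)
    for i in range(n_rays):
        p = prof[i]
        # skip the bright probe disc
        inside = np.nonzero(p < 0.5 * center_level)[0]
        if len(inside) == 0:
            raise BoundaryError("a ray never exits the probe disc")
        start = int(inside[0])
        runmax = np.maximum.accumulate(p[start:])
        below = p[start:] < drop_fraction * runmax
        # first index where `below` holds for persistence_px consecutive samples
        hit = None
        run = 0
        for j, b in enumerate(below):
            run = run + 1 if b else 0
            if run >= persistence_px:
                hit = j - persistence_px + 1
                break
        if hit is None:
            radii[i] = start + len(below) - 1
            continue
        # refine to the half-maximum crossing of the smoothed edge
        half = 0.5 * runmax[hit]
        j = start + hit
        while j > start and p[j] < half:
            j -= 1
        radii[i] = j

    # circular median filter over angle
    k = median_window
    pad = k // 2
    ext = np.concatenate([radii[-pad:], radii, radii[:pad]])
    radii = np.array([np.median(ext[i:i + k]) for i in range(n_rays)])

    angles = np.linspace(0, 2 * np.pi, n_rays, endpoint=False)
    poly_r = cr + radii * np.sin(angles)
    poly_c = cc + radii * np.cos(angles)
    rr, ccs = skdraw.polygon(poly_r, poly_c, shape=gray.shape)
    mask = np.zeros(gray.shape, dtype=bool)
    mask[rr, ccs] = True
    return LesionMask(mask)


def extract_roi(image: EbusImage, mask: LesionMask) -> EbusImage:
    """Pixel-wise AND of image and mask: outside-mask pixels become 0."""
    px = image.pixels
    m = mask.mask
    if px.shape[:2] != m.shape:
        raise ValueError("image and mask shapes differ")
    out = px * (m if px.ndim == 2 else m[..., None])
    return image.with_pixels(out.astype(px.dtype))


def ring_mask(shape: tuple[int, int], center: tuple[int, int], mm_per_px: float,
              ring: RingSpec, probe_radius_mm: float) -> np.ndarray:
    """Boolean annulus r_inner..r_outer mm beyond the probe surface."""
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
    dist = np.hypot(rows - center[0], cols - center[1])
    inner = (probe_radius_mm + ring.r_inner_mm) / mm_per_px
    outer = (probe_radius_mm + ring.r_outer_mm) / mm_per_px
    return (dist >= inner) & (dist <= outer)


def select_patches(image: EbusImage, mask: LesionMask, ring: RingSpec = RingSpec(),
                   *, probe_radius_mm: float = 2.0) -> PatchSet:
    """Greedy row-major tiling of 32x32 windows in the annulus ∩ lesion.

    A window origin (r, c) qualifies when the four corner pixels (r, c),
    (r, s-1 offsets) all lie inside ring ∩ mask; origins are scanned in
    row-major order and a qualifying window is accepted whenever it does not
    overlap a previously accepted one.
    """
    region = ring_mask(image.gray.shape, image.probe_center, image.mm_per_px,
                       ring, probe_radius_mm) & mask.mask
    s = ring.patch_side
    h, w = region.shape
    if h < s or w < s:
        return PatchSet([], image_id=image.id)
    corner_ok = (region[: h - s + 1, : w - s + 1]
                 & region[s - 1:, : w - s + 1]
                 & region[: h - s + 1, s - 1:]
                 & region[s - 1:, s - 1:])
    occupied = np.zeros((h, w), dtype=bool)
    patches: list[Patch] = []
    for r, c in zip(*np.nonzero(corner_ok)):
        if occupied[r:r + s, c:c + s].any():
            continue
        occupied[r:r + s, c:c + s] = True
        patches.append(Patch(int(r), int(c), s, image.pixels[r:r + s, c:c + s].copy()))
    return PatchSet(patches, image_id=image.id)


def _transform(px: np.ndarray, op: str) -> np.ndarray:
    if op == "rot90":
        return np.rot90(px, 1)
    if op == "rot180":
        return np.rot90(px, 2)
    if op == "fliph":
        return np.fliplr(px)
    if op == "flipv":
        return np.flipud(px)
    raise ValueError(op)


MALIGNANT_OPS = ("rot90", "rot180")
BENIGN_OPS = ("rot90", "rot180", "fliph", "flipv")


def augment(cohort: Cohort) -> Cohort:
    """Class-asymmetric augmentation of the *training* split.

    Malignant training images gain 90 and 180 degree rotations (x3 total);
    benign training images additionally gain horizontal and vertical flips
    (x5 total).  Masks and labels are transformed consistently; the test
    split passes through untouched.  Square images are required so the
    90-degree rotation is lossless.
    """
    images, masks, records, split = [], [], [], []
    for i in range(len(cohort)):
        part = cohort.split[i] if cohort.split else "train"
        img, msk, rec = cohort.images[i], cohort.masks[i], cohort.records[i]
        images.append(img)
        masks.append(msk)
        records.append(rec)
        split.append(part)
        if part != "train":
            continue
        if img.pixels.shape[0] != img.pixels.shape[1]:
            raise ValueError("augmentation requires square images")
        ops = MALIGNANT_OPS if rec.label == 1 else BENIGN_OPS
        for op in ops:
            px = _transform(img.pixels, op)
            m = _transform(msk.mask, op)
            cr, cc = img.probe_center
            n = img.pixels.shape[0]
            if op == "rot90":
                center = (n - 1 - cc, cr)
            elif op == "rot180":
                center = (n - 1 - cr, n - 1 - cc)
            elif op == "fliph":
                center = (cr, n - 1 - cc)
            else:  # flipv
                center = (n - 1 - cr, cc)
            images.append(EbusImage(pixels=px.copy(), probe_center=center,
                                    mm_per_px=img.mm_per_px, id=f"{img.id}-{op}"))
            masks.append(LesionMask(m.copy()))
            records.append(PatientRecord(gender=rec.gender, smoking=rec.smoking,
                                         age=rec.age, lesion_size=rec.lesion_size,
                                         label=rec.label, id=f"{rec.id}-{op}"))
            split.append("train")
    return Cohort(images=images, masks=masks, records=records, split=split)
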