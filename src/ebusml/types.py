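"""Shared domain containers for the EBUS classification pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "EbusImage",
    "LesionMask",
    "PatientRecord",
    "Cohort",
    "GeometryError",
    "DegenerateContrastError",
    "BoundaryError",
    "EmptyPatchSetError",
    "UnavailableBackboneError",
]


class GeometryError(ValueError):
    """Phantom or ring geometry cannot host a single 32x32 window."""


class DegenerateContrastError(ValueError):
    """Constant image: the 1st and 99th percentile thresholds coincide."""


class BoundaryError(RuntimeError):
    """Ray-cast boundary detection failed (e.g. all-dark image)."""


class EmptyPatchSetError(ValueError):
    """No 32x32 window fits in ring ∩ lesion; the patch model must be skipped."""


class UnavailableBackboneError(RuntimeError):
    """Requested a pretrained backbone that is not present on this machine."""


@dataclass
class EbusImage:
    """One radial-probe EBUS frame.

    pixels is an 8-bit grid, either (H, W) grayscale or (H, W, 3) RGB.  The
    probe sits at ``probe_center`` (row, col) and ``mm_per_px`` calibrates
    the 2–5 mm annulus used for patch selection.
    """

    pixels: np.ndarray
    probe_center: tuple[int, int]
    mm_per_px: float
    id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        r, c = self.probe_center
        if not (0 <= r < self.pixels.shape[0] and 0 <= c < self.pixels.shape[1]):
            raise ValueError("probe_center outside the image")
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")

    @property
    def gray(self) -> np.ndarray:
        """Grayscale view as float in [0, 255]."""
        px = self.pixels
        if px.ndim == 3:
            return px.mean(axis=2)
        return px.astype(float)

    def with_pixels(self, pixels: np.ndarray, id: str | None = None) -> "EbusImage":
        return replace(self, pixels=pixels, id=self.id if id is None else id)


@dataclass
class LesionMask:
    """Binary lesion region aligned with its image."""

    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def boundary(self) -> np.ndarray:
        """Ordered (row, col) polygon of the outer contour (longest contour)."""
        from skimage import measure

        contours = measure.find_contours(self.mask.astype(float), 0.5)
        if not contours:
            return np.zeros((0, 2))
        return max(contours, key=len)


@dataclass
class PatientRecord:
    gender: str           # "male" | "female"
    smoking: str          # "non-smoker" | "ex-smoker" | "smoker"
    age: float            # years
    lesion_size: str      # "<3cm" | ">=3cm"
    label: int            # 0 benign, 1 malignant
    id: str = ""

    GENDERS = ("male", "female")
    SMOKING = ("non-smoker", "ex-smoker", "smoker")
    SIZES = ("<3cm", ">=3cm")

    def __post_init__(self):
        if self.gender not in self.GENDERS:
            raise ValueError(f"gender {self.gender!r}")
        if self.smoking not in self.SMOKING:
            raise ValueError(f"smoking {self.smoking!r}")
        if self.lesion_size not in self.SIZES:
            raise ValueError(f"lesion_size {self.lesion_size!r}")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 (benign) or 1 (malignant)")


@dataclass
class Cohort:
    """Index-aligned images, masks, patient records and a train/test split."""

    images: list[EbusImage]
    masks: list[LesionMask]
    records: list[PatientRecord]
    split: list[str] = field(default_factory=list)  # "train" | "test" per index

    def __post_init__(self):
        n = len(self.images)
        if not (len(self.masks) == len(self.records) == n):
            raise ValueError("images, masks and records must be index-aligned")
        if self.split and len(self.split) != n:
            raise ValueError("split must cover every index")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    def indices(self, part: str) -> list[int]:
        return [i for i, s in enumerate(self.split) if s == part]

    def subset(self, idx: list[int]) -> "Cohort":
        return Cohort(
            images=[self.images[i] for i in idx],
            masks=[self.masks[i] for i in idx],
            records=[self.records[i] for i in idx],
            split=[self.split[i] for i in idx] if self.split else [],
        )
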