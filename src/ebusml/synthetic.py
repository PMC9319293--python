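"""Seed-reproducible phantom EBUS images, masks and patient metadata.

A radial-probe EBUS frame shows the bright probe disc at the image center
surrounded by the lesion echotexture out to the lesion boundary, with a dark
far field beyond.  The phantoms emulate the two texture classes radiologists
describe: benign lesions are homogeneous speckle, malignant lesions add
hyperechoic dots and arcs (coagulation-necrosis-like foci) and anechoic
patches, all on a multiplicative Rayleigh speckle base smoothed with a small
Gaussian kernel — standard B-mode phantom practice.

Patient metadata is drawn class-conditionally with the published cohort
statistics (sex ratio, smoking history, age mean/SD clipped to 17–86 years,
lesion-size split) so the clinical features carry real signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import Cohort, EbusImage, GeometryError, LesionMask, PatientRecord

__all__ = ["PhantomSpec", "TextureParams", "generate_phantom", "generate_cohort",
           "COHORT_STATS"]


@dataclass
class TextureParams:
    """Echotexture knobs; the malignant defaults add heterogeneity."""

    speckle_scale: float = 0.35      # Rayleigh sigma of the multiplicative envelope
    smooth_px: float = 1.2           # Gaussian blur of the envelope (speckle grain)
    mean_level: float = 120.0        # mean lesion brightness (8-bit)
    dot_density: float = 0.0         # hyperechoic dots per 1000 lesion px
    arc_count: int = 0               # bright arcs around the probe
    anechoic_fraction: float = 0.0   # fraction of lesion area under dark patches


BENIGN_TEXTURE = TextureParams()
MALIGNANT_TEXTURE = TextureParams(smooth_px=0.8, dot_density=1.8, arc_count=3,
                                  anechoic_fraction=0.10)


@dataclass
class PhantomSpec:
    image_size_px: int = 776
    probe_center: tuple[int, int] | None = None   # default: image center
    probe_radius_mm: float = 2.0
    mm_per_px: float = 0.09
    class_label: int = 0                          # 0 benign, 1 malignant
    texture_params: TextureParams | None = None
    lesion_radius_mm: tuple[float, float] = (9.0, 12.0)   # base radius range
    boundary_wobble: float = 0.08                 # relative star-polygon amplitude
    rng_seed: int = 0

    def __post_init__(self):
        if self.image_size_px < 64:
            raise ValueError("image_size_px must be >= 64")
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")
        if self.probe_center is None:
            c = self.image_size_px // 2
            self.probe_center = (c, c)
        if self.texture_params is None:
            self.texture_params = (MALIGNANT_TEXTURE if self.class_label == 1
                                   else BENIGN_TEXTURE)


def _star_radius(theta: np.ndarray, base_px: float, wobble: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Star-convex boundary radius r(theta): base plus low-order harmonics."""
    r = np.full_like(theta, base_px)
    for k in range(2, 6):
        amp = wobble * base_px * rng.uniform(0.2, 1.0) / (k - 1)
        phase = rng.uniform(0, 2 * np.pi)
        r += amp * np.cos(k * theta + phase)
    return r


def generate_phantom(spec: PhantomSpec) -> tuple[EbusImage, LesionMask]:
    """Render one phantom frame and its ground-truth lesion mask.

    Identical spec (including seed) gives bit-identical output.  Raises
    :class:`GeometryError` if the 2–5 mm annulus cannot host a single 32x32
    window with all four corners inside ring ∩ lesion.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.image_size_px
    cr, cc = spec.probe_center
    tp = spec.texture_params

    rows, cols = np.mgrid[0:n, 0:n]
    dist = np.hypot(rows - cr, cols - cc)
    theta = np.arctan2(rows - cr, cols - cc)

    base_mm = rng.uniform(*spec.lesion_radius_mm)
    base_px = base_mm / spec.mm_per_px
    r_bound = _star_radius(theta, base_px, spec.boundary_wobble, rng)
    lesion = dist <= r_bound
    probe_px = spec.probe_radius_mm / spec.mm_per_px
    probe = dist <= probe_px

    # multiplicative Rayleigh speckle envelope, lightly smoothed
    envelope = rng.rayleigh(scale=tp.speckle_scale, size=(n, n))
    envelope = ndimage.gaussian_filter(envelope, tp.smooth_px)
    envelope /= envelope.mean()

    img = np.zeros((n, n))
    img += 8.0 * envelope * ~lesion                    # faint far-field noise
    img += tp.mean_level * envelope * (lesion & ~probe)

    if tp.anechoic_fraction > 0:
        # dark patches: thresholded smooth noise field inside the lesion
        f = ndimage.gaussian_filter(rng.standard_normal((n, n)), 8.0)
        cut = np.quantile(f[lesion], tp.anechoic_fraction)
        img[(f < cut) & lesion & ~probe] *= 0.15

    if tp.dot_density > 0:
        n_dots = rng.poisson(tp.dot_density * lesion.sum() / 1000.0)
        dots = np.zeros((n, n))
        ys, xs = np.nonzero(lesion & ~probe)
        if len(ys):
            pick = rng.integers(0, len(ys), size=n_dots)
            dots[ys[pick], xs[pick]] = rng.uniform(150, 250, size=n_dots)
            dots = ndimage.gaussian_filter(dots, 1.0)
            img += dots * (lesion & ~probe)

    for _ in range(tp.arc_count):
        r_arc = rng.uniform(probe_px + 8, 0.9 * base_px)
        th0 = rng.uniform(0, 2 * np.pi)
        span = rng.uniform(0.3, 1.2)
        dth = np.mod(theta - th0 + np.pi, 2 * np.pi) - np.pi
        band = (np.abs(dist - r_arc) < 1.5) & (np.abs(dth) < span / 2)
        arc = ndimage.gaussian_filter(band * 120.0, 1.0)
        img += arc * (lesion & ~probe)

    img[probe] = 235.0 + 8.0 * (envelope[probe] - 1.0)
    img = np.clip(img, 0, 255).astype(np.uint8)

    image = EbusImage(pixels=img, probe_center=(cr, cc), mm_per_px=spec.mm_per_px,
                      id=f"phantom-{spec.class_label}-{spec.rng_seed}")
    mask = LesionMask(lesion)

    from .preprocess import RingSpec, select_patches
    try:
        patches = select_patches(image, mask, RingSpec(),
                                 probe_radius_mm=spec.probe_radius_mm)
        n_patches = len(patches)
    except Exception:
        n_patches = 0
    if n_patches == 0:
        raise GeometryError(
            "lesion/annulus geometry admits no 32x32 window; enlarge the lesion "
            "or the image")
    return image, mask


# Published cohort statistics used as generator defaults: per class —
# (n, male count, age mean, age sd, size>=3cm count, smoking non/smoker/ex counts)
COHORT_STATS = {
    1: dict(n=124, male=74, age_mean=64.32, age_sd=13.21, large=75,
            smoking={"non-smoker": 52, "smoker": 35, "ex-smoker": 37}),
    0: dict(n=76, male=29, age_mean=57.63, age_sd=15.51, large=38,
            smoking={"non-smoker": 29, "smoker": 27, "ex-smoker": 20}),
}

AGE_RANGE = (17.0, 86.0)


def _draw_record(label: int, rng: np.random.Generator, id: str) -> PatientRecord:
    s = COHORT_STATS[label]
    gender = "male" if rng.random() < s["male"] / s["n"] else "female"
    age = float(np.clip(rng.normal(s["age_mean"], s["age_sd"]), *AGE_RANGE))
    size = ">=3cm" if rng.random() < s["large"] / s["n"] else "<3cm"
    levels = list(s["smoking"])
    probs = np.array([s["smoking"][k] for k in levels], dtype=float)
    smoking = str(rng.choice(levels, p=probs / probs.sum()))
    return PatientRecord(gender=gender, smoking=smoking, age=age,
                         lesion_size=size, label=label, id=id)


def _stratified_split(labels: np.ndarray, rng: np.random.Generator,
                      test_frac: float = 0.2) -> list[str]:
    split = ["train"] * len(labels)
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        n_test = int(round(test_frac * len(idx)))
        test_idx = rng.choice(idx, size=n_test, replace=False)
        for i in test_idx:
            split[int(i)] = "test"
    return split


def generate_cohort(n_malignant: int, n_benign: int, seed: int = 0,
                    image_size_px: int = 776, mm_per_px: float = 0.09,
                    probe_radius_mm: float = 2.0) -> Cohort:
    """Generate an index-aligned phantom cohort with an 80:20 stratified split.

    Class-conditional metadata follows the published cohort statistics; the
    default class sizes (124 malignant, 76 benign) mirror that cohort.
    """
    if n_malignant < 0 or n_benign < 0:
        raise ValueError("counts must be non-negative")
    master = np.random.default_rng(seed)
    images, masks, records = [], [], []
    labels = [1] * n_malignant + [0] * n_benign
    for i, label in enumerate(labels):
        sub_seed = int(master.integers(0, 2**31 - 1))
        spec = PhantomSpec(image_size_px=image_size_px, mm_per_px=mm_per_px,
                           probe_radius_mm=probe_radius_mm, class_label=label,
                           rng_seed=sub_seed)
        img, mask = generate_phantom(spec)
        img.id = f"case-{i:04d}"
        images.append(img)
        masks.append(mask)
        records.append(_draw_record(label, master, id=img.id))
    split = _stratified_split(np.array(labels, dtype=int), master)
    return Cohort(images=images, masks=masks, records=records, split=split)
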