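"""2-D shape descriptors of the lesion mask."""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

__all__ = ["shape2d_features"]


def _max_diameter(coords: np.ndarray) -> float:
    """Largest pairwise distance between pixel centers (0 for one pixel)."""
    if len(coords) < 2:
        return 0.0
    pts = coords.astype(float)
    try:
        hull = ConvexHull(pts)
        pts = pts[hull.vertices]
    except QhullError:
        pass  # collinear: brute force on the raw points
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=-1)
    return float(np.sqrt(d2.max()))


def shape2d_features(mask: np.ndarray) -> dict[str, float]:
    """Nine named descriptors of a binary mask.

    area (px), perimeter, perimeter/area, major and minor axis lengths,
    elongation (minor/major, 1 for degenerate masks), sphericity
    (2*sqrt(pi*A)/perimeter, the isoperimetric circularity, 1 for degenerate
    masks), maximum diameter (largest pairwise pixel-center distance) and
    equivalent circle diameter sqrt(4A/pi).
    """
    mask = np.asarray(mask, dtype=bool)
    area = float(mask.sum())
    if area == 0:
        raise ValueError("empty mask")
    props = measure.regionprops(mask.astype(np.uint8))[0]
    perimeter = float(props.perimeter)
    major = float(props.axis_major_length)
    minor = float(props.axis_minor_length)
    elongation = minor / major if major > 0 else 1.0
    sphericity = 2.0 * np.sqrt(np.pi * area) / perimeter if perimeter > 0 else 1.0
    coords = np.argwhere(mask)
    return {
        "shape_area": area,
        "shape_perimeter": perimeter,
        "shape_perimeter_area_ratio": perimeter / area,
        "shape_major_axis_length": major,
        "shape_minor_axis_length": minor,
        "shape_elongation": elongation,
        "shape_sphericity": sphericity,
        "shape_maximum_diameter": _max_diameter(coords),
        "shape_equivalent_diameter": float(np.sqrt(4.0 * area / np.pi)),
    }
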