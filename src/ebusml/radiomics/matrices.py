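"""Texture-matrix construction on quantized, masked grids.

All builders take a quantized grid (integer levels 1..Ng, 0 outside the
mask) plus the boolean mask, and return plain numpy arrays.  Conventions:

* GLCM: pixel-pair counts at distance 1 for the four 2-D angles, optionally
  symmetrized (both directions counted); both pixels of a pair must be
  in-mask.
* GLDM: dependence j = 1 + number of in-mask 8-neighbours whose level
  differs from the center by at most ``alpha`` (default 0).
* GLRLM: run lengths of equal levels along a direction; a mask break ends
  the run.
* GLSZM: 8-connected zones of equal level.
* NGTDM: per-level counts n_i and summed absolute deviations s_i from the
  mean of the in-mask 8-neighbourhood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["CooccurrenceMatrix", "GLCM_ANGLES", "glcm", "gldm_matrix",
           "glrlm_matrix", "glszm_matrix", "ngtdm_table"]

# distance-1 offsets (d_row, d_col) for angles 0, 45, 90, 135 degrees
GLCM_ANGLES: dict[int, tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}


@dataclass
class CooccurrenceMatrix:
    counts: np.ndarray            # (Ng, Ng) pair counts
    offset: tuple[int, int]
    symmetric: bool

    @property
    def normalized(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / total


def _pairs(quant: np.ndarray, offset: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Levels of (source, shifted) pixels where both are in-mask."""
    dr, dc = offset
    h, w = quant.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = quant[r0:r1, c0:c1]
    b = quant[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    ok = (a > 0) & (b > 0)
    return a[ok], b[ok]


def glcm(quant: np.ndarray, offset: tuple[int, int], n_levels: int | None = None,
         symmetric: bool = True) -> CooccurrenceMatrix:
    """Gray-level co-occurrence counts for one offset."""
    if (quant > 0).sum() < 2:
        raise ValueError("mask must contain at least 2 pixels")
    ng = int(n_levels or quant.max())
    a, b = _pairs(quant, offset)
    counts = np.bincount((a - 1) * ng + (b - 1), minlength=ng * ng)
    counts = counts.reshape(ng, ng).astype(float)
    if symmetric:
        counts = counts + counts.T
    return CooccurrenceMatrix(counts=counts, offset=offset, symmetric=symmetric)


_NEIGHBOURS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def gldm_matrix(quant: np.ndarray, n_levels: int | None = None,
                alpha: int = 0) -> np.ndarray:
    """Dependence matrix D[i-1, j-1]: pixels of level i with dependence j.

    Dependence j counts the center itself plus every in-mask 8-neighbour
    whose level differs by at most alpha, so j ranges 1..9.
    """
    ng = int(n_levels or quant.max())
    mask = quant > 0
    dep = np.ones(quant.shape, dtype=np.int32)  # center counts itself
    h, w = quant.shape
    for dr, dc in _NEIGHBOURS8:
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        a = quant[r0:r1, c0:c1]
        b = quant[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        ok = (a > 0) & (b > 0) & (np.abs(a - b) <= alpha)
        dep[r0:r1, c0:c1] += ok
    jmax = 9
    out = np.zeros((ng, jmax), dtype=float)
    i = quant[mask] - 1
    j = dep[mask] - 1
    np.add.at(out, (i, j), 1.0)
    return out


GLRLM_DIRECTIONS = [(0, 1), (-1, 1), (-1, 0), (-1, -1)]


def _line_runs(levels: np.ndarray, out: np.ndarray) -> None:
    """Accumulate run-length counts of one line (0 = out of mask) into out."""
    n = len(levels)
    i = 0
    while i < n:
        v = levels[i]
        j = i + 1
        while j < n and levels[j] == v:
            j += 1
        if v > 0:
            out[v - 1, j - i - 1] += 1.0
        i = j


def glrlm_matrix(quant: np.ndarray, direction: tuple[int, int],
                 n_levels: int | None = None) -> np.ndarray:
    """Run-length matrix R[i-1, l-1] along one direction."""
    ng = int(n_levels or quant.max())
    h, w = quant.shape
    lmax = max(h, w)
    out = np.zeros((ng, lmax), dtype=float)
    dr, dc = direction
    if (dr, dc) == (0, 1):
        lines = [quant[r, :] for r in range(h)]
    elif (dr, dc) == (-1, 0):
        lines = [quant[:, c] for c in range(w)]
    elif (dr, dc) == (-1, 1):
        # anti-diagonals: constant r + c
        flipped = np.fliplr(quant)
        lines = [np.diagonal(flipped, k) for k in range(-(h - 1), w)]
    elif (dr, dc) == (-1, -1):
        lines = [np.diagonal(quant, k) for k in range(-(h - 1), w)]
    else:
        raise ValueError(f"unsupported direction {direction}")
    for line in lines:
        _line_runs(np.asarray(line), out)
    # trim trailing all-zero run-length columns
    used = np.nonzero(out.sum(axis=0))[0]
    return out[:, : used[-1] + 1] if len(used) else out[:, :1]


def glszm_matrix(quant: np.ndarray, n_levels: int | None = None) -> np.ndarray:
    """Size-zone matrix Z[i-1, s-1]: 8-connected zones of level i and size s."""
    ng = int(n_levels or quant.max())
    structure = np.ones((3, 3), dtype=int)
    sizes: list[tuple[int, int]] = []
    for level in range(1, ng + 1):
        lab, nlab = ndimage.label(quant == level, structure=structure)
        if nlab == 0:
            continue
        counts = np.bincount(lab.ravel())[1:]
        sizes.extend((level, int(s)) for s in counts)
    if not sizes:
        return np.zeros((ng, 1))
    smax = max(s for _, s in sizes)
    out = np.zeros((ng, smax), dtype=float)
    for level, s in sizes:
        out[level - 1, s - 1] += 1.0
    return out


def ngtdm_table(quant: np.ndarray, n_levels: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-level counts n_i and deviations s_i for the NGTDM features.

    s_i sums |i - Abar| over in-mask pixels of level i, where Abar is the
    mean level of the pixel's in-mask 8-neighbours; pixels with no in-mask
    neighbour are excluded from both n and s.
    """
    ng = int(n_levels or quant.max())
    mask = quant > 0
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0
    nb_sum = ndimage.convolve(quant.astype(float) * mask, kernel, mode="constant")
    nb_cnt = ndimage.convolve(mask.astype(float), kernel, mode="constant")
    valid = mask & (nb_cnt > 0)
    abar = np.zeros(quant.shape)
    abar[valid] = nb_sum[valid] / nb_cnt[valid]
    n = np.zeros(ng)
    s = np.zeros(ng)
    lv = quant[valid]
    dev = np.abs(quant[valid] - abar[valid])
    np.add.at(n, lv - 1, 1.0)
    np.add.at(s, lv - 1, dev)
    return n, s
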