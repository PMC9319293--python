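"""Closed-form texture features computed from the texture matrices.

Entropies use log base 2.  Degenerate-region conventions (documented in
docs/methods.md): GLCM correlation on a zero-variance region is 0, MCC is 1,
NGTDM coarseness on a zero-deviation region is 1e6 and busyness/strength are
0.  Matrix-family features are averaged over the four distance-1 angles
(GLCM, GLRLM); GLSZM, GLDM and NGTDM are direction-free.
"""

from __future__ import annotations

import numpy as np

from .matrices import (GLCM_ANGLES, GLRLM_DIRECTIONS, CooccurrenceMatrix,
                       glcm, gldm_matrix, glrlm_matrix, glszm_matrix,
                       ngtdm_table)

__all__ = ["glcm_features", "gldm_features", "glrlm_features",
           "glszm_features", "ngtdm_features", "aws_feature",
           "texture_features"]

_EPS = np.finfo(float).tiny


def _log2(x: np.ndarray) -> np.ndarray:
    return np.log2(np.maximum(x, _EPS))


def glcm_features(P: np.ndarray) -> dict[str, float]:
    """The 24 co-occurrence features of one normalized (symmetric) GLCM."""
    ng = P.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sig_x = float(np.sqrt((((i - mu_x) ** 2) * px).sum()))
    sig_y = float(np.sqrt((((i - mu_y) ** 2) * py).sum()))

    # difference and sum distributions
    k_diff = np.arange(0, ng)
    p_diff = np.array([P[np.abs(ii - jj) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([P[(ii + jj) == k].sum() for k in k_sum])

    da = float((k_diff * p_diff).sum())
    hxy = float(-(P * _log2(P))[P > 0].sum())
    pxy = np.outer(px, py)
    hxy1 = float(-(P * _log2(pxy))[P > 0].sum())
    hxy2 = float(-(pxy * _log2(pxy))[pxy > 0].sum())
    hx = float(-(px * _log2(px))[px > 0].sum())
    hy = float(-(py * _log2(py))[py > 0].sum())

    if sig_x * sig_y > 0:
        correlation = (float((ii * jj * P).sum()) - mu_x * mu_y) / (sig_x * sig_y)
    else:
        correlation = 0.0

    denom = max(hx, hy)
    imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    off = ii != jj
    feats = {
        "glcm_autocorrelation": float((ii * jj * P).sum()),
        "glcm_joint_average": mu_x,
        "glcm_cluster_prominence": float((((ii + jj - mu_x - mu_y) ** 4) * P).sum()),
        "glcm_cluster_shade": float((((ii + jj - mu_x - mu_y) ** 3) * P).sum()),
        "glcm_cluster_tendency": float((((ii + jj - mu_x - mu_y) ** 2) * P).sum()),
        "glcm_contrast": float((((ii - jj) ** 2) * P).sum()),
        "glcm_correlation": correlation,
        "glcm_difference_average": da,
        "glcm_difference_entropy": float(-(p_diff * _log2(p_diff))[p_diff > 0].sum()),
        "glcm_difference_variance": float((((k_diff - da) ** 2) * p_diff).sum()),
        "glcm_joint_energy": float((P ** 2).sum()),
        "glcm_joint_entropy": hxy,
        "glcm_imc1": imc1,
        "glcm_imc2": imc2,
        "glcm_id": float((P / (1.0 + np.abs(ii - jj))).sum()),
        "glcm_idm": float((P / (1.0 + (ii - jj) ** 2)).sum()),
        "glcm_idmn": float((P / (1.0 + ((ii - jj) ** 2) / ng ** 2)).sum()),
        "glcm_idn": float((P / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "glcm_inverse_variance": float((P[off] / ((ii - jj)[off] ** 2)).sum()),
        "glcm_maximum_probability": float(P.max()),
        "glcm_sum_average": float((k_sum * p_sum).sum()),
        "glcm_sum_entropy": float(-(p_sum * _log2(p_sum))[p_sum > 0].sum()),
        "glcm_sum_squares": float((((ii - mu_x) ** 2) * P).sum()),
        "glcm_mcc": _mcc(P, px, py),
    }
    return feats


def _mcc(P: np.ndarray, px: np.ndarray, py: np.ndarray) -> float:
    """Maximal correlation coefficient: sqrt of the second-largest eigenvalue
    of Q(i,j) = sum_k P(i,k) P(j,k) / (px(i) py(k)), restricted to levels
    with nonzero marginals.  Fewer than two occupied levels gives 1."""
    keep = px > 0
    if keep.sum() < 2:
        return 1.0
    Pk = P[np.ix_(keep, keep)]
    pxk = px[keep]
    pyk = py[keep]
    Q = (Pk / pxk[:, None]) @ (Pk / pyk[None, :]).T
    ev = np.sort(np.real(np.linalg.eigvals(Q)))
    second = ev[-2] if len(ev) >= 2 else 0.0
    return float(np.sqrt(max(0.0, second)))


def aws_feature(matrix: CooccurrenceMatrix | np.ndarray) -> float:
    """Adaptive weighted sum of the upper/lower triangular GLCM.

    On the *unsymmetrized* normalized matrix, S_U = sum_{i<j} p|i-j| and
    S_L = sum_{i>j} p|i-j| measure off-diagonal (heterogeneous) mass above
    and below the diagonal; the adaptive weight w = S_U/(S_U+S_L) (0.5 when
    both vanish) yields AWS = w*S_U + (1-w)*S_L.  Zero iff all co-occurrence
    mass is diagonal.
    """
    P = matrix.normalized if isinstance(matrix, CooccurrenceMatrix) else np.asarray(matrix, float)
    if P.sum() > 0:
        P = P / P.sum()
    ng = P.shape[0]
    ii, jj = np.meshgrid(np.arange(ng), np.arange(ng), indexing="ij")
    d = np.abs(ii - jj)
    s_u = float((P * d)[ii < jj].sum())
    s_l = float((P * d)[ii > jj].sum())
    w = s_u / (s_u + s_l) if (s_u + s_l) > 0 else 0.5
    return w * s_u + (1.0 - w) * s_l


def _weighted_stats(M: np.ndarray):
    """Common helper: normalized matrix p, level index i, column index j."""
    total = M.sum()
    p = M / total if total > 0 else M
    ng, nj = M.shape
    i = np.arange(1, ng + 1, dtype=float)
    j = np.arange(1, nj + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    return p, ii, jj, total


def glrlm_features(R: np.ndarray, n_voxels: int) -> dict[str, float]:
    """The 16 run-length features of one direction's matrix."""
    p, ii, jj, nr = _weighted_stats(R)
    ri = R.sum(axis=1)
    rj = R.sum(axis=0)
    mu_i = float((ii * p).sum())
    mu_j = float((jj * p).sum())
    return {
        "glrlm_short_run_emphasis": float((R / jj ** 2).sum() / nr),
        "glrlm_long_run_emphasis": float((R * jj ** 2).sum() / nr),
        "glrlm_gray_level_nonuniformity": float((ri ** 2).sum() / nr),
        "glrlm_gray_level_nonuniformity_normalized": float((ri ** 2).sum() / nr ** 2),
        "glrlm_run_length_nonuniformity": float((rj ** 2).sum() / nr),
        "glrlm_run_length_nonuniformity_normalized": float((rj ** 2).sum() / nr ** 2),
        "glrlm_run_percentage": float(nr / n_voxels),
        "glrlm_gray_level_variance": float((((ii - mu_i) ** 2) * p).sum()),
        "glrlm_run_variance": float((((jj - mu_j) ** 2) * p).sum()),
        "glrlm_run_entropy": float(-(p * _log2(p))[p > 0].sum()),
        "glrlm_low_gray_level_run_emphasis": float((R / ii ** 2).sum() / nr),
        "glrlm_high_gray_level_run_emphasis": float((R * ii ** 2).sum() / nr),
        "glrlm_short_run_low_gray_level_emphasis": float((R / (ii ** 2 * jj ** 2)).sum() / nr),
        "glrlm_short_run_high_gray_level_emphasis": float((R * ii ** 2 / jj ** 2).sum() / nr),
        "glrlm_long_run_low_gray_level_emphasis": float((R * jj ** 2 / ii ** 2).sum() / nr),
        "glrlm_long_run_high_gray_level_emphasis": float((R * ii ** 2 * jj ** 2).sum() / nr),
    }


def glszm_features(Z: np.ndarray, n_voxels: int) -> dict[str, float]:
    """The 16 size-zone features."""
    p, ii, jj, nz = _weighted_stats(Z)
    zi = Z.sum(axis=1)
    zj = Z.sum(axis=0)
    mu_i = float((ii * p).sum())
    mu_j = float((jj * p).sum())
    return {
        "glszm_small_area_emphasis": float((Z / jj ** 2).sum() / nz),
        "glszm_large_area_emphasis": float((Z * jj ** 2).sum() / nz),
        "glszm_gray_level_nonuniformity": float((zi ** 2).sum() / nz),
        "glszm_gray_level_nonuniformity_normalized": float((zi ** 2).sum() / nz ** 2),
        "glszm_size_zone_nonuniformity": float((zj ** 2).sum() / nz),
        "glszm_size_zone_nonuniformity_normalized": float((zj ** 2).sum() / nz ** 2),
        "glszm_zone_percentage": float(nz / n_voxels),
        "glszm_gray_level_variance": float((((ii - mu_i) ** 2) * p).sum()),
        "glszm_zone_variance": float((((jj - mu_j) ** 2) * p).sum()),
        "glszm_zone_entropy": float(-(p * _log2(p))[p > 0].sum()),
        "glszm_low_gray_level_zone_emphasis": float((Z / ii ** 2).sum() / nz),
        "glszm_high_gray_level_zone_emphasis": float((Z * ii ** 2).sum() / nz),
        "glszm_small_area_low_gray_level_emphasis": float((Z / (ii ** 2 * jj ** 2)).sum() / nz),
        "glszm_small_area_high_gray_level_emphasis": float((Z * ii ** 2 / jj ** 2).sum() / nz),
        "glszm_large_area_low_gray_level_emphasis": float((Z * jj ** 2 / ii ** 2).sum() / nz),
        "glszm_large_area_high_gray_level_emphasis": float((Z * ii ** 2 * jj ** 2).sum() / nz),
    }


def gldm_features(D: np.ndarray) -> dict[str, float]:
    """The 14 dependence-matrix features."""
    p, ii, jj, nz = _weighted_stats(D)
    di = D.sum(axis=1)
    dj = D.sum(axis=0)
    mu_i = float((ii * p).sum())
    mu_j = float((jj * p).sum())
    return {
        "gldm_small_dependence_emphasis": float((D / jj ** 2).sum() / nz),
        "gldm_large_dependence_emphasis": float((D * jj ** 2).sum() / nz),
        "gldm_gray_level_nonuniformity": float((di ** 2).sum() / nz),
        "gldm_dependence_nonuniformity": float((dj ** 2).sum() / nz),
        "gldm_dependence_nonuniformity_normalized": float((dj ** 2).sum() / nz ** 2),
        "gldm_gray_level_variance": float((((ii - mu_i) ** 2) * p).sum()),
        "gldm_dependence_variance": float((((jj - mu_j) ** 2) * p).sum()),
        "gldm_dependence_entropy": float(-(p * _log2(p))[p > 0].sum()),
        "gldm_low_gray_level_emphasis": float((D / ii ** 2).sum() / nz),
        "gldm_high_gray_level_emphasis": float((D * ii ** 2).sum() / nz),
        "gldm_small_dependence_low_gray_level_emphasis": float((D / (ii ** 2 * jj ** 2)).sum() / nz),
        "gldm_small_dependence_high_gray_level_emphasis": float((D * ii ** 2 / jj ** 2).sum() / nz),
        "gldm_large_dependence_low_gray_level_emphasis": float((D * jj ** 2 / ii ** 2).sum() / nz),
        "gldm_large_dependence_high_gray_level_emphasis": float((D * ii ** 2 * jj ** 2).sum() / nz),
    }


def ngtdm_features(n: np.ndarray, s: np.ndarray) -> dict[str, float]:
    """The 5 neighbouring-gray-tone-difference features."""
    nv = n.sum()
    ng_levels = len(n)
    p = n / nv if nv > 0 else n
    present = p > 0
    i = np.arange(1, ng_levels + 1, dtype=float)
    ngp = int(present.sum())

    ps = float((p * s).sum())
    coarseness = 1.0 / ps if ps > 0 else 1e6

    if ngp > 1:
        ip = i[present]
        pp = p[present]
        diff2 = (ip[:, None] - ip[None, :]) ** 2
        contrast = float((pp[:, None] * pp[None, :] * diff2).sum()
                         / (ngp * (ngp - 1)) * s.sum() / nv)
        absdiff = np.abs((ip * pp)[:, None] - (ip * pp)[None, :])
        denom = float(absdiff.sum())
        busyness = ps / denom if denom > 0 else 0.0
        sp = s[present]
        pair_sum = pp[:, None] + pp[None, :]
        complexity = float((np.abs(ip[:, None] - ip[None, :])
                            * (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :])
                            / pair_sum).sum() / nv)
        strength_num = float((pair_sum * diff2).sum())
        ssum = float(s.sum())
        strength = strength_num / ssum if ssum > 0 else 0.0
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0
    return {
        "ngtdm_coarseness": coarseness,
        "ngtdm_contrast": contrast,
        "ngtdm_busyness": busyness,
        "ngtdm_complexity": complexity,
        "ngtdm_strength": strength,
    }


def texture_features(quant: np.ndarray, n_levels: int | None = None) -> dict[str, float]:
    """All 75 matrix-based features of a quantized masked grid.

    GLCM and GLRLM are averaged over the four distance-1 angles; GLDM,
    GLSZM and NGTDM have a single matrix each.
    """
    ng = int(n_levels or quant.max())
    n_voxels = int((quant > 0).sum())

    glcm_acc: dict[str, float] = {}
    for offset in GLCM_ANGLES.values():
        f = glcm_features(glcm(quant, offset, n_levels=ng).normalized)
        for k, v in f.items():
            glcm_acc[k] = glcm_acc.get(k, 0.0) + v / len(GLCM_ANGLES)

    glrlm_acc: dict[str, float] = {}
    for direction in GLRLM_DIRECTIONS:
        f = glrlm_features(glrlm_matrix(quant, direction, n_levels=ng), n_voxels)
        for k, v in f.items():
            glrlm_acc[k] = glrlm_acc.get(k, 0.0) + v / len(GLRLM_DIRECTIONS)

    out: dict[str, float] = {}
    out.update(glcm_acc)
    out.update(gldm_features(gldm_matrix(quant, n_levels=ng)))
    out.update(glrlm_acc)
    out.update(glszm_features(glszm_matrix(quant, n_levels=ng), n_voxels))
    n, s = ngtdm_table(quant, n_levels=ng)
    out.update(ngtdm_features(n, s))
    return out
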