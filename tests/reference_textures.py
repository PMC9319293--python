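"""Independent brute-force texture-feature implementations for cross-checks.

Everything here is written as plain loops straight from the matrix and
feature definitions, with no reuse of the package's vectorized code paths.
Grids use levels 1..Ng with 0 marking out-of-mask pixels.
"""

from __future__ import annotations

import math

import numpy as np

LOG2 = math.log(2.0)


def log2(x: float) -> float:
    return math.log(x) / LOG2


# ---------------------------------------------------------------- GLCM ----

def ref_glcm_counts(q, offset, symmetric=True):
    ng = int(q.max())
    h, w = q.shape
    dr, dc = offset
    m = [[0.0] * ng for _ in range(ng)]
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and q[r, c] > 0 and q[r2, c2] > 0:
                m[q[r, c] - 1][q[r2, c2] - 1] += 1.0
                if symmetric:
                    m[q[r2, c2] - 1][q[r, c] - 1] += 1.0
    return np.array(m)


def ref_glcm_features(P):
    ng = P.shape[0]
    total = P.sum()
    P = P / total if total > 0 else P
    px = [sum(P[i, j] for j in range(ng)) for i in range(ng)]
    py = [sum(P[i, j] for i in range(ng)) for j in range(ng)]
    mu_x = sum((i + 1) * px[i] for i in range(ng))
    mu_y = sum((j + 1) * py[j] for j in range(ng))
    sig_x = math.sqrt(sum((i + 1 - mu_x) ** 2 * px[i] for i in range(ng)))
    sig_y = math.sqrt(sum((j + 1 - mu_y) ** 2 * py[j] for j in range(ng)))

    p_diff = [0.0] * ng
    p_sum = [0.0] * (2 * ng - 1)  # index k-2 for k = 2..2Ng
    for i in range(ng):
        for j in range(ng):
            p_diff[abs(i - j)] += P[i, j]
            p_sum[i + j] += P[i, j]

    out = {}
    out["glcm_autocorrelation"] = sum((i + 1) * (j + 1) * P[i, j]
                                      for i in range(ng) for j in range(ng))
    out["glcm_joint_average"] = mu_x
    for name, power in (("glcm_cluster_prominence", 4), ("glcm_cluster_shade", 3),
                        ("glcm_cluster_tendency", 2)):
        out[name] = sum((i + 1 + j + 1 - mu_x - mu_y) ** power * P[i, j]
                        for i in range(ng) for j in range(ng))
    out["glcm_contrast"] = sum((i - j) ** 2 * P[i, j]
                               for i in range(ng) for j in range(ng))
    if sig_x * sig_y > 0:
        corr = (sum((i + 1) * (j + 1) * P[i, j] for i in range(ng)
                    for j in range(ng)) - mu_x * mu_y) / (sig_x * sig_y)
    else:
        corr = 0.0
    out["glcm_correlation"] = corr
    da = sum(k * p_diff[k] for k in range(ng))
    out["glcm_difference_average"] = da
    out["glcm_difference_entropy"] = -sum(p * log2(p) for p in p_diff if p > 0)
    out["glcm_difference_variance"] = sum((k - da) ** 2 * p_diff[k] for k in range(ng))
    out["glcm_joint_energy"] = sum(P[i, j] ** 2 for i in range(ng) for j in range(ng))
    hxy = -sum(P[i, j] * log2(P[i, j]) for i in range(ng) for j in range(ng)
               if P[i, j] > 0)
    out["glcm_joint_entropy"] = hxy
    hxy1 = -sum(P[i, j] * log2(px[i] * py[j]) for i in range(ng) for j in range(ng)
                if P[i, j] > 0)
    hxy2 = -sum(px[i] * py[j] * log2(px[i] * py[j]) for i in range(ng)
                for j in range(ng) if px[i] * py[j] > 0)
    hx = -sum(p * log2(p) for p in px if p > 0)
    hy = -sum(p * log2(p) for p in py if p > 0)
    denom = max(hx, hy)
    out["glcm_imc1"] = (hxy - hxy1) / denom if denom > 0 else 0.0
    out["glcm_imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    out["glcm_id"] = sum(P[i, j] / (1 + abs(i - j)) for i in range(ng) for j in range(ng))
    out["glcm_idm"] = sum(P[i, j] / (1 + (i - j) ** 2) for i in range(ng) for j in range(ng))
    out["glcm_idmn"] = sum(P[i, j] / (1 + (i - j) ** 2 / ng ** 2)
                           for i in range(ng) for j in range(ng))
    out["glcm_idn"] = sum(P[i, j] / (1 + abs(i - j) / ng)
                          for i in range(ng) for j in range(ng))
    out["glcm_inverse_variance"] = sum(P[i, j] / (i - j) ** 2
                                       for i in range(ng) for j in range(ng) if i != j)
    out["glcm_maximum_probability"] = max(P[i, j] for i in range(ng) for j in range(ng))
    out["glcm_sum_average"] = sum((k + 2) * p_sum[k] for k in range(2 * ng - 1))
    out["glcm_sum_entropy"] = -sum(p * log2(p) for p in p_sum if p > 0)
    out["glcm_sum_squares"] = sum((i + 1 - mu_x) ** 2 * P[i, j]
                                  for i in range(ng) for j in range(ng))
    # MCC via explicitly assembled Q on occupied levels
    keep = [i for i in range(ng) if px[i] > 0]
    if len(keep) < 2:
        out["glcm_mcc"] = 1.0
    else:
        nq = len(keep)
        Q = np.zeros((nq, nq))
        for a, i in enumerate(keep):
            for b, j in enumerate(keep):
                Q[a, b] = sum(P[i, k] * P[j, k] / (px[i] * py[k])
                              for k in keep if py[k] > 0)
        ev = sorted(np.real(np.linalg.eigvals(Q)))
        out["glcm_mcc"] = math.sqrt(max(0.0, ev[-2]))
    return out


def ref_aws(P):
    total = P.sum()
    P = P / total if total > 0 else P
    ng = P.shape[0]
    s_u = sum(P[i, j] * abs(i - j) for i in range(ng) for j in range(ng) if i < j)
    s_l = sum(P[i, j] * abs(i - j) for i in range(ng) for j in range(ng) if i > j)
    w = s_u / (s_u + s_l) if s_u + s_l > 0 else 0.5
    return w * s_u + (1 - w) * s_l


# --------------------------------------------------------------- GLRLM ----

def ref_glrlm(q, direction):
    """Run-length counts by walking each maximal line in the direction."""
    h, w = q.shape
    ng = int(q.max())
    dr, dc = direction
    dr, dc = -dr, -dc  # walk in scan order
    runs = {}
    starts = []
    for r in range(h):
        for c in range(w):
            pr, pc = r - dr, c - dc
            if not (0 <= pr < h and 0 <= pc < w):
                starts.append((r, c))
    for r0, c0 in starts:
        r, c = r0, c0
        cur, length = 0, 0
        while 0 <= r < h and 0 <= c < w:
            v = q[r, c]
            if v == cur:
                length += 1
            else:
                if cur > 0:
                    runs[(cur, length)] = runs.get((cur, length), 0) + 1
                cur, length = v, 1
            r, c = r + dr, c + dc
        if cur > 0:
            runs[(cur, length)] = runs.get((cur, length), 0) + 1
    lmax = max((l for (_, l) in runs), default=1)
    R = np.zeros((ng, lmax))
    for (lev, l), n in runs.items():
        R[lev - 1, l - 1] = n
    return R


def ref_rlm_style_features(M, n_voxels, prefix, names):
    """Shared run-length/size-zone style formulas evaluated by loops.

    names maps formula keys to the package's feature names.
    """
    ng, nj = M.shape
    ns = M.sum()
    out = {}
    out[names["sre"]] = sum(M[i, j] / (j + 1) ** 2 for i in range(ng) for j in range(nj)) / ns
    out[names["lre"]] = sum(M[i, j] * (j + 1) ** 2 for i in range(ng) for j in range(nj)) / ns
    out[names["gln"]] = sum(sum(M[i, :]) ** 2 for i in range(ng)) / ns
    if "glnn" in names:
        out[names["glnn"]] = sum(sum(M[i, :]) ** 2 for i in range(ng)) / ns ** 2
    out[names["rln"]] = sum(sum(M[:, j]) ** 2 for j in range(nj)) / ns
    out[names["rlnn"]] = sum(sum(M[:, j]) ** 2 for j in range(nj)) / ns ** 2
    if "rp" in names:
        out[names["rp"]] = ns / n_voxels
    mu_i = sum((i + 1) * M[i, j] / ns for i in range(ng) for j in range(nj))
    mu_j = sum((j + 1) * M[i, j] / ns for i in range(ng) for j in range(nj))
    out[names["glv"]] = sum((i + 1 - mu_i) ** 2 * M[i, j] / ns
                            for i in range(ng) for j in range(nj))
    out[names["rv"]] = sum((j + 1 - mu_j) ** 2 * M[i, j] / ns
                           for i in range(ng) for j in range(nj))
    out[names["re"]] = -sum((M[i, j] / ns) * log2(M[i, j] / ns)
                            for i in range(ng) for j in range(nj) if M[i, j] > 0)
    out[names["lgl"]] = sum(M[i, j] / (i + 1) ** 2 for i in range(ng) for j in range(nj)) / ns
    out[names["hgl"]] = sum(M[i, j] * (i + 1) ** 2 for i in range(ng) for j in range(nj)) / ns
    out[names["srlgl"]] = sum(M[i, j] / ((i + 1) ** 2 * (j + 1) ** 2)
                              for i in range(ng) for j in range(nj)) / ns
    out[names["srhgl"]] = sum(M[i, j] * (i + 1) ** 2 / (j + 1) ** 2
                              for i in range(ng) for j in range(nj)) / ns
    out[names["lrlgl"]] = sum(M[i, j] * (j + 1) ** 2 / (i + 1) ** 2
                              for i in range(ng) for j in range(nj)) / ns
    out[names["lrhgl"]] = sum(M[i, j] * (i + 1) ** 2 * (j + 1) ** 2
                              for i in range(ng) for j in range(nj)) / ns
    return out


GLRLM_NAMES = dict(
    sre="glrlm_short_run_emphasis", lre="glrlm_long_run_emphasis",
    gln="glrlm_gray_level_nonuniformity",
    glnn="glrlm_gray_level_nonuniformity_normalized",
    rln="glrlm_run_length_nonuniformity",
    rlnn="glrlm_run_length_nonuniformity_normalized",
    rp="glrlm_run_percentage", glv="glrlm_gray_level_variance",
    rv="glrlm_run_variance", re="glrlm_run_entropy",
    lgl="glrlm_low_gray_level_run_emphasis",
    hgl="glrlm_high_gray_level_run_emphasis",
    srlgl="glrlm_short_run_low_gray_level_emphasis",
    srhgl="glrlm_short_run_high_gray_level_emphasis",
    lrlgl="glrlm_long_run_low_gray_level_emphasis",
    lrhgl="glrlm_long_run_high_gray_level_emphasis",
)

GLSZM_NAMES = dict(
    sre="glszm_small_area_emphasis", lre="glszm_large_area_emphasis",
    gln="glszm_gray_level_nonuniformity",
    glnn="glszm_gray_level_nonuniformity_normalized",
    rln="glszm_size_zone_nonuniformity",
    rlnn="glszm_size_zone_nonuniformity_normalized",
    rp="glszm_zone_percentage", glv="glszm_gray_level_variance",
    rv="glszm_zone_variance", re="glszm_zone_entropy",
    lgl="glszm_low_gray_level_zone_emphasis",
    hgl="glszm_high_gray_level_zone_emphasis",
    srlgl="glszm_small_area_low_gray_level_emphasis",
    srhgl="glszm_small_area_high_gray_level_emphasis",
    lrlgl="glszm_large_area_low_gray_level_emphasis",
    lrhgl="glszm_large_area_high_gray_level_emphasis",
)

GLDM_NAMES = dict(
    sre="gldm_small_dependence_emphasis", lre="gldm_large_dependence_emphasis",
    gln="gldm_gray_level_nonuniformity",
    rln="gldm_dependence_nonuniformity",
    rlnn="gldm_dependence_nonuniformity_normalized",
    glv="gldm_gray_level_variance", rv="gldm_dependence_variance",
    re="gldm_dependence_entropy",
    lgl="gldm_low_gray_level_emphasis", hgl="gldm_high_gray_level_emphasis",
    srlgl="gldm_small_dependence_low_gray_level_emphasis",
    srhgl="gldm_small_dependence_high_gray_level_emphasis",
    lrlgl="gldm_large_dependence_low_gray_level_emphasis",
    lrhgl="gldm_large_dependence_high_gray_level_emphasis",
)


# --------------------------------------------------------------- GLSZM ----

def ref_glszm(q):
    ng = int(q.max())
    h, w = q.shape
    seen = np.zeros((h, w), dtype=bool)
    zones = []
    for r in range(h):
        for c in range(w):
            if q[r, c] > 0 and not seen[r, c]:
                level = q[r, c]
                stack = [(r, c)]
                seen[r, c] = True
                size = 0
                while stack:
                    rr, cc = stack.pop()
                    size += 1
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            r2, c2 = rr + dr, cc + dc
                            if (0 <= r2 < h and 0 <= c2 < w and not seen[r2, c2]
                                    and q[r2, c2] == level):
                                seen[r2, c2] = True
                                stack.append((r2, c2))
                zones.append((level, size))
    smax = max((s for _, s in zones), default=1)
    Z = np.zeros((ng, smax))
    for lev, s in zones:
        Z[lev - 1, s - 1] += 1
    return Z


# ---------------------------------------------------------------- GLDM ----

def ref_gldm(q, alpha=0):
    ng = int(q.max())
    h, w = q.shape
    D = np.zeros((ng, 9))
    for r in range(h):
        for c in range(w):
            if q[r, c] == 0:
                continue
            dep = 1
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    r2, c2 = r + dr, c + dc
                    if (0 <= r2 < h and 0 <= c2 < w and q[r2, c2] > 0
                            and abs(int(q[r, c]) - int(q[r2, c2])) <= alpha):
                        dep += 1
            D[q[r, c] - 1, dep - 1] += 1
    return D


# --------------------------------------------------------------- NGTDM ----

def ref_ngtdm_features(q):
    ng = int(q.max())
    h, w = q.shape
    n = [0.0] * ng
    s = [0.0] * ng
    for r in range(h):
        for c in range(w):
            if q[r, c] == 0:
                continue
            neigh = []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < h and 0 <= c2 < w and q[r2, c2] > 0:
                        neigh.append(q[r2, c2])
            if not neigh:
                continue
            abar = sum(neigh) / len(neigh)
            n[q[r, c] - 1] += 1
            s[q[r, c] - 1] += abs(q[r, c] - abar)
    nv = sum(n)
    p = [x / nv for x in n]
    present = [i for i in range(ng) if p[i] > 0]
    ngp = len(present)
    ps = sum(p[i] * s[i] for i in range(ng))
    coarseness = 1.0 / ps if ps > 0 else 1e6
    if ngp > 1:
        contrast = (sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
                    / (ngp * (ngp - 1))) * (sum(s) / nv)
        denom = sum(abs((i + 1) * p[i] - (j + 1) * p[j])
                    for i in present for j in present)
        busyness = ps / denom if denom > 0 else 0.0
        complexity = sum(abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
                         for i in present for j in present) / nv
        ssum = sum(s)
        strength = (sum((p[i] + p[j]) * (i - j) ** 2 for i in present for j in present)
                    / ssum) if ssum > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "ngtdm_coarseness": coarseness,
        "ngtdm_contrast": contrast,
        "ngtdm_busyness": busyness,
        "ngtdm_complexity": complexity,
        "ngtdm_strength": strength,
    }
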