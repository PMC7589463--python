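"""Texture feature families on the discretised ROI (95 features).

Six grey-level matrix families with IBSI-standard member lists and counts:

* GLCM  (co-occurrence, 25) — distance-1 neighbours, 13 unique 3D
  directions, symmetrised; features averaged over directions.
* GLRLM (run length, 16)    — runs per 13 directions, features averaged.
* GLSZM (size zone, 16)     — 26-connected zones of equal grey level.
* GLDZM (distance zone, 16) — zones with city-block distance to the ROI
  edge (border voxels have distance 1).
* NGTDM (neighbourhood grey tone difference, 5) — 26-neighbourhood means.
* NGLDM (neighbouring grey level dependence, 17) — Chebyshev distance 1,
  coarseness parameter a = 0; dependence count includes the voxel itself
  (j = k + 1).

All matrices are computed in 3D on the level grid (0 outside the ROI).
Degenerate single-level or single-voxel ROIs return the documented
limiting values instead of raising.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .histogram import DiscretisedRoi

__all__ = ["TEXTURE_NAMES", "texture_features", "DIRECTIONS_13",
           "glcm_matrix", "glrlm_matrix", "glszm_matrix", "gldzm_matrix",
           "ngtdm_table", "ngldm_matrix"]

log = logging.getLogger(__name__)

# 13 unique 3D directions: first non-zero component positive
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)
assert len(DIRECTIONS_13) == 13

GLCM_NAMES = (
    "glcm_joint_max", "glcm_joint_average", "glcm_joint_variance",
    "glcm_joint_entropy", "glcm_diff_average", "glcm_diff_variance",
    "glcm_diff_entropy", "glcm_sum_average", "glcm_sum_variance",
    "glcm_sum_entropy", "glcm_energy", "glcm_contrast",
    "glcm_dissimilarity", "glcm_inv_diff", "glcm_inv_diff_norm",
    "glcm_inv_diff_moment", "glcm_inv_diff_moment_norm",
    "glcm_inv_variance", "glcm_correlation", "glcm_autocorrelation",
    "glcm_cluster_tendency", "glcm_cluster_shade",
    "glcm_cluster_prominence", "glcm_info_corr1", "glcm_info_corr2",
)
GLRLM_NAMES = (
    "glrlm_sre", "glrlm_lre", "glrlm_lgre", "glrlm_hgre", "glrlm_srlge",
    "glrlm_srhge", "glrlm_lrlge", "glrlm_lrhge", "glrlm_glnu",
    "glrlm_glnu_norm", "glrlm_rlnu", "glrlm_rlnu_norm", "glrlm_run_pct",
    "glrlm_gl_var", "glrlm_rl_var", "glrlm_run_entropy",
)
GLSZM_NAMES = (
    "glszm_sze", "glszm_lze", "glszm_lgze", "glszm_hgze", "glszm_szlge",
    "glszm_szhge", "glszm_lzlge", "glszm_lzhge", "glszm_glnu",
    "glszm_glnu_norm", "glszm_zsnu", "glszm_zsnu_norm", "glszm_zone_pct",
    "glszm_gl_var", "glszm_zs_var", "glszm_zs_entropy",
)
GLDZM_NAMES = (
    "gldzm_sde", "gldzm_lde", "gldzm_lgze", "gldzm_hgze", "gldzm_sdlge",
    "gldzm_sdhge", "gldzm_ldlge", "gldzm_ldhge", "gldzm_glnu",
    "gldzm_glnu_norm", "gldzm_zdnu", "gldzm_zdnu_norm", "gldzm_zone_pct",
    "gldzm_gl_var", "gldzm_zd_var", "gldzm_zd_entropy",
)
NGTDM_NAMES = (
    "ngtdm_coarseness", "ngtdm_contrast", "ngtdm_busyness",
    "ngtdm_complexity", "ngtdm_strength",
)
NGLDM_NAMES = (
    "ngldm_lde", "ngldm_hde", "ngldm_lgce", "ngldm_hgce", "ngldm_ldlge",
    "ngldm_ldhge", "ngldm_hdlge", "ngldm_hdhge", "ngldm_glnu",
    "ngldm_glnu_norm", "ngldm_dcnu", "ngldm_dcnu_norm", "ngldm_dc_pct",
    "ngldm_gl_var", "ngldm_dc_var", "ngldm_dc_entropy", "ngldm_dc_energy",
)
TEXTURE_NAMES = (GLCM_NAMES + GLRLM_NAMES + GLSZM_NAMES + GLDZM_NAMES
                 + NGTDM_NAMES + NGLDM_NAMES)
assert len(TEXTURE_NAMES) == 95

COARSENESS_CAP = 1e6


def _shift_pairs(grid: np.ndarray, d: tuple[int, int, int]
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Aligned views (a, b) with b displaced by d relative to a."""
    sl_a, sl_b = [], []
    for k, n in zip(d, grid.shape):
        if k >= 0:
            sl_a.append(slice(0, n - k))
            sl_b.append(slice(k, n))
        else:
            sl_a.append(slice(-k, n))
            sl_b.append(slice(0, n + k))
    return grid[tuple(sl_a)], grid[tuple(sl_b)]


# --------------------------------------------------------------------- GLCM

def glcm_matrix(level_grid: np.ndarray, ng: int,
                d: tuple[int, int, int]) -> np.ndarray:
    """Symmetric co-occurrence counts for one direction (distance 1)."""
    a, b = _shift_pairs(level_grid, d)
    ok = (a > 0) & (b > 0)
    m = np.zeros((ng, ng), dtype=float)
    np.add.at(m, (a[ok] - 1, b[ok] - 1), 1.0)
    return m + m.T


def _glcm_features(m: np.ndarray) -> dict[str, float]:
    ng = m.shape[0]
    total = m.sum()
    if total == 0:  # single voxel ROI: no neighbour pairs
        return {k: 0.0 for k in GLCM_NAMES} | {"glcm_joint_max": 1.0,
                                               "glcm_energy": 1.0,
                                               "glcm_info_corr2": 0.0}
    p = m / total
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    pi = p.sum(axis=1)

    mu = float(np.sum(ii * p))
    joint_var = float(np.sum((ii - mu) ** 2 * p))

    diff = np.abs(ii - jj)
    k_d = np.arange(0, ng)
    p_dm = np.array([p[diff == k].sum() for k in k_d])
    da = float(np.sum(k_d * p_dm))
    dvar = float(np.sum((k_d - da) ** 2 * p_dm))
    nzd = p_dm > 0
    dent = float(-np.sum(p_dm[nzd] * np.log2(p_dm[nzd])))

    s = ii + jj
    k_s = np.arange(2, 2 * ng + 1)
    p_sm = np.array([p[s == k].sum() for k in k_s])
    sa = float(np.sum(k_s * p_sm))
    svar = float(np.sum((k_s - sa) ** 2 * p_sm))
    nzs = p_sm > 0
    sent = float(-np.sum(p_sm[nzs] * np.log2(p_sm[nzs])))

    nz = p > 0
    hxy = float(-np.sum(p[nz] * np.log2(p[nz])))
    pipj = np.outer(pi, pi)
    okk = nz & (pipj > 0)
    hxy1 = float(-np.sum(p[okk] * np.log2(pipj[okk])))
    ok2 = pipj > 0
    hxy2 = float(-np.sum(pipj[ok2] * np.log2(pipj[ok2])))
    hx = float(-np.sum(pi[pi > 0] * np.log2(pi[pi > 0])))
    icorr1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    arg = 1.0 - np.exp(-2.0 * (hxy2 - hxy))
    icorr2 = float(np.sqrt(max(arg, 0.0)))

    sigma2 = float(np.sum((i - mu) ** 2 * pi))
    if sigma2 > 0:
        corr = (float(np.sum(ii * jj * p)) - mu**2) / sigma2
    else:
        corr = 1.0

    off = diff > 0
    inv_var = float(np.sum(p[off] / diff[off] ** 2)) if off.any() else 0.0

    return {
        "glcm_joint_max": float(p.max()),
        "glcm_joint_average": mu,
        "glcm_joint_variance": joint_var,
        "glcm_joint_entropy": hxy,
        "glcm_diff_average": da,
        "glcm_diff_variance": dvar,
        "glcm_diff_entropy": dent,
        "glcm_sum_average": sa,
        "glcm_sum_variance": svar,
        "glcm_sum_entropy": sent,
        "glcm_energy": float(np.sum(p**2)),
        "glcm_contrast": float(np.sum((ii - jj) ** 2 * p)),
        "glcm_dissimilarity": float(np.sum(diff * p)),
        "glcm_inv_diff": float(np.sum(p / (1.0 + diff))),
        "glcm_inv_diff_norm": float(np.sum(p / (1.0 + diff / ng))),
        "glcm_inv_diff_moment": float(np.sum(p / (1.0 + diff**2))),
        "glcm_inv_diff_moment_norm": float(np.sum(p / (1.0 + diff**2 / ng**2))),
        "glcm_inv_variance": inv_var,
        "glcm_correlation": float(corr),
        "glcm_autocorrelation": float(np.sum(ii * jj * p)),
        "glcm_cluster_tendency": float(np.sum((ii + jj - 2 * mu) ** 2 * p)),
        "glcm_cluster_shade": float(np.sum((ii + jj - 2 * mu) ** 3 * p)),
        "glcm_cluster_prominence": float(np.sum((ii + jj - 2 * mu) ** 4 * p)),
        "glcm_info_corr1": float(icorr1),
        "glcm_info_corr2": icorr2,
    }


# -------------------------------------------------------------------- GLRLM

def glrlm_matrix(level_grid: np.ndarray, ng: int,
                 d: tuple[int, int, int]) -> np.ndarray:
    """Run-length counts R[level-1, length-1] for one direction."""
    shape = level_grid.shape
    inroi = level_grid > 0
    # run starts: in-ROI voxels whose predecessor along d is absent/different
    pred = np.zeros(shape, dtype=bool)
    same = np.zeros(shape, dtype=bool)
    a, b = _shift_pairs(level_grid, d)
    # b is displaced by +d relative to a: predecessor of b-voxels is a
    sl_a, sl_b = [], []
    for k, n in zip(d, shape):
        if k >= 0:
            sl_a.append(slice(0, n - k)); sl_b.append(slice(k, n))
        else:
            sl_a.append(slice(-k, n)); sl_b.append(slice(0, n + k))
    same[tuple(sl_b)] = (a == b) & (a > 0)
    starts = inroi & ~same

    zs, ys, xs = np.nonzero(starts)
    levels = level_grid[zs, ys, xs]
    lengths = np.ones(zs.size, dtype=np.int64)
    active = np.arange(zs.size)
    cz, cy, cx = zs.copy(), ys.copy(), xs.copy()
    max_len = 1
    while active.size:
        cz[active] += d[0]; cy[active] += d[1]; cx[active] += d[2]
        inb = ((cz[active] >= 0) & (cz[active] < shape[0])
               & (cy[active] >= 0) & (cy[active] < shape[1])
               & (cx[active] >= 0) & (cx[active] < shape[2]))
        cand = active[inb]
        cont = level_grid[cz[cand], cy[cand], cx[cand]] == levels[cand]
        cand = cand[cont]
        lengths[cand] += 1
        active = cand
        if active.size:
            max_len = int(lengths[active].max())
    r = np.zeros((ng, max(max_len, 1)), dtype=float)
    np.add.at(r, (levels - 1, lengths - 1), 1.0)
    return r


def _rlm_style_features(m: np.ndarray, n_vox: int,
                        names: tuple[str, ...]) -> dict[str, float]:
    """Shared formula block for GLRLM/GLSZM/GLDZM-style matrices.

    ``m[i-1, j-1]`` counts items with grey level i and size/length/
    distance j.
    """
    ns = m.sum()
    if ns == 0:
        return {k: 0.0 for k in names}
    ng, nj = m.shape
    i = np.arange(1, ng + 1)[:, None].astype(float)
    j = np.arange(1, nj + 1)[None, :].astype(float)
    p = m / ns
    mi = m.sum(axis=1)
    mj = m.sum(axis=0)

    mu_i = float(np.sum(i * p))
    mu_j = float(np.sum(j * p))
    nz = p > 0
    vals = {
        "sre": float(np.sum(m / j**2) / ns),
        "lre": float(np.sum(m * j**2) / ns),
        "lgre": float(np.sum(m / i**2) / ns),
        "hgre": float(np.sum(m * i**2) / ns),
        "srlge": float(np.sum(m / (i**2 * j**2)) / ns),
        "srhge": float(np.sum(m * i**2 / j**2) / ns),
        "lrlge": float(np.sum(m * j**2 / i**2) / ns),
        "lrhge": float(np.sum(m * i**2 * j**2) / ns),
        "glnu": float(np.sum(mi**2) / ns),
        "glnu_norm": float(np.sum(mi**2) / ns**2),
        "jnu": float(np.sum(mj**2) / ns),
        "jnu_norm": float(np.sum(mj**2) / ns**2),
        "pct": float(ns / n_vox),
        "gl_var": float(np.sum((i - mu_i) ** 2 * p)),
        "j_var": float(np.sum((j - mu_j) ** 2 * p)),
        "entropy": float(-np.sum(p[nz] * np.log2(p[nz]))),
    }
    return dict(zip(names, vals.values()))


# ------------------------------------------------------------- GLSZM/GLDZM

_CONN26 = np.ones((3, 3, 3), dtype=int)


def _zones(level_grid: np.ndarray, ng: int):
    """Yield (level, zone_label_array, n_zones) per grey level."""
    for g in range(1, ng + 1):
        sel = level_grid == g
        if not sel.any():
            continue
        lab, n = ndimage.label(sel, structure=_CONN26)
        yield g, lab, n


def glszm_matrix(level_grid: np.ndarray, ng: int) -> np.ndarray:
    """Size-zone counts S[level-1, size-1] (26-connected zones)."""
    entries: list[tuple[int, int]] = []
    for g, lab, n in _zones(level_grid, ng):
        sizes = np.bincount(lab.ravel())[1:]
        entries.extend((g, int(s)) for s in sizes)
    if not entries:
        return np.zeros((ng, 1))
    max_s = max(s for _, s in entries)
    m = np.zeros((ng, max_s), dtype=float)
    for g, s in entries:
        m[g - 1, s - 1] += 1.0
    return m


def gldzm_matrix(level_grid: np.ndarray, ng: int,
                 roi_bool: np.ndarray) -> np.ndarray:
    """Distance-zone counts D[level-1, distance-1].

    Zone distance = min over zone voxels of the city-block distance to the
    ROI edge; voxels adjacent to (or on) the image border count distance 1.
    """
    padded = np.pad(roi_bool, 1)
    dist = ndimage.distance_transform_cdt(padded, metric="taxicab")
    dist = dist[1:-1, 1:-1, 1:-1]
    entries: list[tuple[int, int]] = []
    for g, lab, n in _zones(level_grid, ng):
        mins = ndimage.minimum(dist, labels=lab, index=np.arange(1, n + 1))
        mins = np.atleast_1d(mins)
        entries.extend((g, int(dmin)) for dmin in mins)
    if not entries:
        return np.zeros((ng, 1))
    max_d = max(dmin for _, dmin in entries)
    m = np.zeros((ng, max_d), dtype=float)
    for g, dmin in entries:
        m[g - 1, dmin - 1] += 1.0
    return m


# -------------------------------------------------------------------- NGTDM

def _neighbour_sums(level_grid: np.ndarray):
    """Sum and count of in-ROI 26-neighbour levels at every voxel."""
    s = np.zeros(level_grid.shape, dtype=float)
    c = np.zeros(level_grid.shape, dtype=float)
    inroi = level_grid > 0
    for d in DIRECTIONS_13:
        for dd in (d, tuple(-k for k in d)):
            a_lev, b_lev = _shift_pairs(level_grid, dd)
            a_in, b_in = _shift_pairs(inroi, dd)
            # neighbour of the a-view voxels is the b-view voxel
            sl_a = tuple(slice(0, n - k) if k >= 0 else slice(-k, n)
                         for k, n in zip(dd, level_grid.shape))
            s[sl_a] += np.where(b_in, b_lev, 0)
            c[sl_a] += b_in
    return s, c


def ngtdm_table(level_grid: np.ndarray, ng: int
                ) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-level occurrence counts n_i and absolute-difference sums s_i."""
    inroi = level_grid > 0
    s, c = _neighbour_sums(level_grid)
    valid = inroi & (c > 0)
    nbar = np.zeros(level_grid.shape, dtype=float)
    nbar[valid] = s[valid] / c[valid]
    lev = level_grid[valid]
    diff = np.abs(lev - nbar[valid])
    n_i = np.bincount(lev, minlength=ng + 1)[1:].astype(float)
    s_i = np.zeros(ng)
    np.add.at(s_i, lev - 1, diff)
    return n_i, s_i, int(valid.sum())


def _ngtdm_features(n_i: np.ndarray, s_i: np.ndarray,
                    n_valid: int) -> dict[str, float]:
    if n_valid == 0:
        return {k: 0.0 for k in NGTDM_NAMES}
    ng = n_i.size
    p = n_i / n_valid
    i = np.arange(1, ng + 1, dtype=float)
    nzi = p > 0
    ngp = int(nzi.sum())

    dens = float(np.sum(p * s_i))
    coarseness = 1.0 / dens if dens > 0 else COARSENESS_CAP
    coarseness = min(coarseness, COARSENESS_CAP)

    if ngp > 1:
        pp = np.outer(p, p)
        di = (i[:, None] - i[None, :])
        contrast = (float(np.sum(pp * di**2)) / (ngp * (ngp - 1))
                    * float(s_i.sum()) / n_valid)
        ipi = i * p
        denom_b = float(np.sum(np.abs(ipi[nzi][:, None] - ipi[nzi][None, :])))
        busyness = dens / denom_b if denom_b > 0 else 0.0
        mask2 = np.outer(nzi, nzi)
        ps = p * s_i
        num_c = (np.abs(di) * (ps[:, None] + ps[None, :])
                 / (p[:, None] + p[None, :] + ~mask2))  # guard zero division
        complexity = float(np.sum(num_c[mask2])) / n_valid
        num_s = float(np.sum((p[:, None] + p[None, :]) * di**2
                             * mask2))
        s_sum = float(s_i.sum())
        strength = num_s / s_sum if s_sum > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "ngtdm_coarseness": coarseness,
        "ngtdm_contrast": contrast,
        "ngtdm_busyness": busyness,
        "ngtdm_complexity": complexity,
        "ngtdm_strength": strength,
    }


# -------------------------------------------------------------------- NGLDM

def ngldm_matrix(level_grid: np.ndarray, ng: int,
                 alpha: int = 0) -> np.ndarray:
    """Dependence counts S[level-1, j-1], j = (dependent neighbours) + 1.

    A 26-neighbour is dependent when |level difference| <= alpha.
    """
    inroi = level_grid > 0
    dep = np.zeros(level_grid.shape, dtype=np.int64)
    for d in DIRECTIONS_13:
        for dd in (d, tuple(-k for k in d)):
            a_lev, b_lev = _shift_pairs(level_grid, dd)
            a_in, b_in = _shift_pairs(inroi, dd)
            sl_a = tuple(slice(0, n - k) if k >= 0 else slice(-k, n)
                         for k, n in zip(dd, level_grid.shape))
            dep[sl_a] += (b_in & a_in
                          & (np.abs(a_lev - b_lev) <= alpha)).astype(np.int64)
    lev = level_grid[inroi]
    j = dep[inroi] + 1
    m = np.zeros((ng, int(j.max())), dtype=float)
    np.add.at(m, (lev - 1, j - 1), 1.0)
    return m


NGLDM_MAP = ("lde", "hde", "lgce", "hgce", "ldlge", "ldhge", "hdlge",
             "hdhge", "glnu", "glnu_norm", "dcnu", "dcnu_norm", "dc_pct",
             "gl_var", "dc_var", "dc_entropy")


def _ngldm_features(m: np.ndarray, n_vox: int) -> dict[str, float]:
    base = _rlm_style_features(
        m, n_vox, tuple(f"ngldm_{k}" for k in NGLDM_MAP))
    p = m / m.sum() if m.sum() else m
    base["ngldm_dc_energy"] = float(np.sum(p**2))
    return base


# ----------------------------------------------------------------- frontend

def texture_features(droi: DiscretisedRoi,
                     mask_bool: np.ndarray) -> dict[str, float]:
    """All 95 texture features for one discretised ROI.

    ``mask_bool`` is the 3D ROI indicator aligned with the discretisation
    (the level of the voxel at the k-th True position is
    ``droi.levels[k]``, C order).
    """
    n_vox = int(mask_bool.sum())
    if n_vox < 1:
        raise ValueError("texture features require a non-empty ROI")
    grid = droi.level_grid(mask_bool)
    # crop to the ROI bounding box (plus 1-voxel pad) for speed
    nz = np.nonzero(mask_bool)
    sl = tuple(slice(max(int(a.min()) - 1, 0), int(a.max()) + 2) for a in nz)
    grid = grid[sl]
    roi = mask_bool[sl]
    ng = droi.n_levels

    out: dict[str, float] = {}

    glcm_acc: list[dict[str, float]] = []
    glrlm_acc: list[dict[str, float]] = []
    for d in DIRECTIONS_13:
        glcm_acc.append(_glcm_features(glcm_matrix(grid, ng, d)))
        glrlm_acc.append(_rlm_style_features(glrlm_matrix(grid, ng, d),
                                             n_vox, GLRLM_NAMES))
    for name in GLCM_NAMES:
        out[name] = float(np.mean([f[name] for f in glcm_acc]))
    for name in GLRLM_NAMES:
        out[name] = float(np.mean([f[name] for f in glrlm_acc]))

    out.update(_rlm_style_features(glszm_matrix(grid, ng), n_vox,
                                   GLSZM_NAMES))
    out.update(_rlm_style_features(gldzm_matrix(grid, ng, roi), n_vox,
                                   GLDZM_NAMES))
    out.update(_ngtdm_features(*ngtdm_table(grid, ng)))
    out.update(_ngldm_features(ngldm_matrix(grid, ng), n_vox))

    if n_vox == 1:
        log.debug("single-voxel ROI: texture features at degenerate values")
    return out
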