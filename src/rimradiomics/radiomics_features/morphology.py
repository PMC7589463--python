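"""Morphological family (28 features, base image only).

Mesh-based quantities (volume, surface area, maximum diameter, convex
hull) come from a marching-cubes surface mesh of the *geometric* mask;
intensity-weighted members (integrated intensity, centre-of-mass shift,
Moran's I, Geary's C) use the re-segmented intensities.  Principal-axis
quantities use the eigenvalues of the voxel-centre covariance matrix.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.spatial import ConvexHull
from skimage import measure

__all__ = ["MORPHOLOGY_NAMES", "morphology_features"]

log = logging.getLogger(__name__)

MORPHOLOGY_NAMES = (
    "morph_vol_voxel", "morph_vol_mesh", "morph_surface_area",
    "morph_sv_ratio", "morph_compactness1", "morph_compactness2",
    "morph_spherical_disproportion", "morph_sphericity",
    "morph_asphericity", "morph_com_shift", "morph_max_diameter",
    "morph_major_axis", "morph_minor_axis", "morph_least_axis",
    "morph_elongation", "morph_flatness",
    "morph_vol_density_aabb", "morph_area_density_aabb",
    "morph_vol_density_ombb", "morph_area_density_ombb",
    "morph_vol_density_aee", "morph_area_density_aee",
    "morph_vol_density_mvee", "morph_vol_density_hull",
    "morph_area_density_hull",
    "morph_integrated_intensity", "morph_moran_i", "morph_geary_c",
)
assert len(MORPHOLOGY_NAMES) == 28

#: spatial-autocorrelation features subsample the ROI above this size
AUTOCORR_MAX_VOXELS = 2000


def _mesh(mask_bool: np.ndarray, spacing: float):
    padded = np.pad(mask_bool, 1).astype(float)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5,
                                                spacing=(spacing,) * 3)
    verts = verts - spacing  # undo padding offset
    return verts, faces


def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    a, b, c = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    return float(abs(np.einsum("ij,ij->i", a, np.cross(b, c)).sum()) / 6.0)


def _ellipsoid_area(a: float, b: float, c: float) -> float:
    """Thomsen's approximation of the ellipsoid surface area."""
    p = 1.6075
    t = ((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0
    return float(4.0 * np.pi * t ** (1.0 / p))


def _autocorr(coords: np.ndarray, vals: np.ndarray
              ) -> tuple[float, float]:
    """Moran's I and Geary's C with inverse-distance weights.

    Large ROIs are deterministically subsampled to keep the pairwise sums
    tractable; the estimate is unbiased under random subsampling.
    """
    n = coords.shape[0]
    if n > AUTOCORR_MAX_VOXELS:
        rng = np.random.default_rng(0)  # fixed: reproducible features
        idx = rng.choice(n, AUTOCORR_MAX_VOXELS, replace=False)
        coords, vals = coords[idx], vals[idx]
        n = AUTOCORR_MAX_VOXELS
    if n < 2 or vals.var() == 0:
        return 1.0, 1.0
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    with np.errstate(divide="ignore"):
        w = 1.0 / np.sqrt(d2)
    np.fill_diagonal(w, 0.0)
    wsum = w.sum()
    mu = vals.mean()
    dev = vals - mu
    s2 = float(np.sum(dev**2))
    moran = float(n / wsum * (dev @ w @ dev) / s2)
    diff2 = (vals[:, None] - vals[None, :]) ** 2
    geary = float((n - 1) / (2 * wsum) * np.sum(w * diff2) / s2)
    return moran, geary


def morphology_features(mask_bool: np.ndarray, image_values: np.ndarray,
                        spacing_mm: float,
                        reseg_bool: np.ndarray | None = None
                        ) -> dict[str, float]:
    """The 28 morphological features.

    Parameters
    ----------
    mask_bool : geometric (non-re-segmented) ROI indicator.
    image_values : aligned base-image intensities.
    spacing_mm : isotropic voxel spacing.
    reseg_bool : re-segmented ROI used for the intensity-weighted members;
        defaults to ``mask_bool``.
    """
    n_vox = int(mask_bool.sum())
    if n_vox == 0:
        raise ValueError("morphology requires a non-empty mask")
    if reseg_bool is None:
        reseg_bool = mask_bool
    vv = spacing_mm**3
    vol_vox = n_vox * vv

    coords = np.argwhere(mask_bool).astype(float) * spacing_mm

    degenerate = n_vox < 4 or np.any(coords.max(0) == coords.min(0))
    if degenerate:
        log.info("mask with <4 non-coplanar voxels: mesh features fall "
                 "back to voxel-based values")
        vol_mesh = vol_vox
        area = 6.0 * spacing_mm**2 * n_vox  # upper-bound voxel surface
        verts = coords
        hull = None
    else:
        verts, faces = _mesh(mask_bool, spacing_mm)
        vol_mesh = _mesh_volume(verts, faces)
        area = float(measure.mesh_surface_area(verts, faces))
        try:
            hull = ConvexHull(verts)
        except Exception:  # coplanar fallback
            hull = None

    r_equiv = (3.0 * vol_mesh / (4.0 * np.pi)) ** (1.0 / 3.0)
    sphere_area = 4.0 * np.pi * r_equiv**2
    sphericity = sphere_area / area if area > 0 else 1.0
    compact1 = vol_mesh / (np.pi**0.5 * area**1.5) if area > 0 else 0.0
    compact2 = 36.0 * np.pi * vol_mesh**2 / area**3 if area > 0 else 0.0

    # principal axes from voxel-centre covariance
    cov = np.cov(coords.T) if n_vox > 1 else np.zeros((3, 3))
    evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    evals = np.maximum(evals, 0.0)
    major, minor, least = (4.0 * np.sqrt(evals)).tolist()
    elong = float(np.sqrt(evals[1] / evals[0])) if evals[0] > 0 else 1.0
    flat = float(np.sqrt(evals[2] / evals[0])) if evals[0] > 0 else 1.0

    # maximum 3D diameter over voxel *corners* (exact for axis-aligned
    # boxes; the marching-cubes mesh chamfers corners and undershoots)
    try:
        centre_hull = ConvexHull(coords)
        cpts = coords[centre_hull.vertices]
    except Exception:
        cpts = coords
    h = spacing_mm / 2.0
    offs = np.array(list(np.ndindex(2, 2, 2))) * spacing_mm - h
    corners = (cpts[:, None, :] + offs[None, :, :]).reshape(-1, 3)
    try:
        corners = corners[ConvexHull(corners).vertices]
    except Exception:
        pass
    d2 = np.sum((corners[:, None, :] - corners[None, :, :]) ** 2, axis=-1)
    max_diam = float(np.sqrt(d2.max()))

    # bounding volumes
    ext = verts.max(0) - verts.min(0)
    aabb_vol = float(np.prod(np.maximum(ext, spacing_mm)))
    aabb_area = float(2.0 * (ext[0] * ext[1] + ext[0] * ext[2]
                             + ext[1] * ext[2]))
    # oriented (PCA-rotated) bounding box
    centred = verts - verts.mean(0)
    if n_vox > 3:
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        rot = centred @ vt.T
        exto = rot.max(0) - rot.min(0)
    else:
        exto = ext
    ombb_vol = float(np.prod(np.maximum(exto, spacing_mm)))
    ombb_area = float(2.0 * (exto[0] * exto[1] + exto[0] * exto[2]
                             + exto[1] * exto[2]))

    # approximate enclosing ellipsoid (2*sqrt(eigenvalue) semi-axes)
    sa = np.sqrt(np.maximum(evals, 1e-12)) * 2.0
    aee_vol = float(4.0 / 3.0 * np.pi * np.prod(sa))
    aee_area = _ellipsoid_area(*sa)
    # minimum-volume enclosing ellipsoid approximated by scaling the AEE
    # until it contains every voxel centre
    if evals[2] > 0:
        r_norm = np.sqrt((((coords - coords.mean(0))
                           / sa) ** 2).sum(axis=1)).max()
        mvee_vol = aee_vol * max(r_norm, 1.0) ** 3
    else:
        mvee_vol = aee_vol

    hull_vol = float(hull.volume) if hull is not None else aabb_vol
    hull_area = float(hull.area) if hull is not None else aabb_area

    # intensity-weighted members on the re-segmented ROI
    ivals = image_values[reseg_bool]
    icoords = np.argwhere(reseg_bool).astype(float) * spacing_mm
    com_geom = coords.mean(axis=0)
    wsum = ivals.sum()
    com_int = (icoords * ivals[:, None]).sum(0) / wsum if wsum != 0 else com_geom
    com_shift = float(np.linalg.norm(com_geom - com_int))
    integrated = float(ivals.mean() * vol_mesh)
    moran, geary = _autocorr(icoords, ivals.astype(float))

    return {
        "morph_vol_voxel": vol_vox,
        "morph_vol_mesh": vol_mesh,
        "morph_surface_area": area,
        "morph_sv_ratio": area / vol_mesh if vol_mesh > 0 else 0.0,
        "morph_compactness1": compact1,
        "morph_compactness2": compact2,
        "morph_spherical_disproportion": 1.0 / sphericity if sphericity else 0.0,
        "morph_sphericity": sphericity,
        "morph_asphericity": (1.0 / compact2) ** (1.0 / 3.0) - 1.0
                             if compact2 > 0 else 0.0,
        "morph_com_shift": com_shift,
        "morph_max_diameter": max_diam,
        "morph_major_axis": major,
        "morph_minor_axis": minor,
        "morph_least_axis": least,
        "morph_elongation": elong,
        "morph_flatness": flat,
        "morph_vol_density_aabb": vol_mesh / aabb_vol if aabb_vol > 0 else 0.0,
        "morph_area_density_aabb": area / aabb_area if aabb_area > 0 else 0.0,
        "morph_vol_density_ombb": vol_mesh / ombb_vol if ombb_vol > 0 else 0.0,
        "morph_area_density_ombb": area / ombb_area if ombb_area > 0 else 0.0,
        "morph_vol_density_aee": vol_mesh / aee_vol if aee_vol > 0 else 0.0,
        "morph_area_density_aee": area / aee_area if aee_area > 0 else 0.0,
        "morph_vol_density_mvee": vol_mesh / mvee_vol if mvee_vol > 0 else 0.0,
        "morph_vol_density_hull": vol_mesh / hull_vol if hull_vol > 0 else 0.0,
        "morph_area_density_hull": area / hull_area if hull_area > 0 else 0.0,
        "morph_integrated_intensity": integrated,
        "morph_moran_i": moran,
        "morph_geary_c": geary,
    }
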