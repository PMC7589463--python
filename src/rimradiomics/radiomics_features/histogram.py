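"""Histogram-based family: intensity histogram (23), intensity-volume
histogram (13) and intensity peaks (2) — 38 features in total.

Discretisation uses a fixed bin number (default 32) over the in-ROI
intensity range, which stays well defined on filter-response images where
HU bin-width semantics break down.  The intensity-volume histogram and the
peaks are computed on the continuous (undiscretised) intensities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = ["DiscretisedRoi", "discretise", "histogram_features",
           "HISTOGRAM_NAMES", "intensity_peaks"]

log = logging.getLogger(__name__)

N_BINS_DEFAULT = 32

IH_NAMES = (
    "ih_mean", "ih_variance", "ih_skewness", "ih_kurtosis", "ih_median",
    "ih_minimum", "ih_p10", "ih_p90", "ih_maximum", "ih_mode", "ih_iqr",
    "ih_range", "ih_mad", "ih_rmad", "ih_medad", "ih_cov", "ih_qcod",
    "ih_entropy", "ih_uniformity", "ih_max_gradient",
    "ih_max_gradient_level", "ih_min_gradient", "ih_min_gradient_level",
)
IVH_NAMES = (
    "ivh_v10", "ivh_v25", "ivh_v50", "ivh_v75", "ivh_v90",
    "ivh_i10", "ivh_i25", "ivh_i50", "ivh_i75", "ivh_i90",
    "ivh_diff_v10_v90", "ivh_diff_i10_i90", "ivh_auc",
)
PEAK_NAMES = ("peak_local", "peak_global")
HISTOGRAM_NAMES = IH_NAMES + IVH_NAMES + PEAK_NAMES


@dataclass
class DiscretisedRoi:
    """Grey-level indices (1..n_levels) for every in-ROI voxel."""

    levels: np.ndarray  # 1D in-ROI level per voxel, consecutive ints from 1
    n_levels: int
    bin_edges: np.ndarray

    def level_grid(self, mask_bool: np.ndarray) -> np.ndarray:
        """3D integer grid with levels inside the mask and 0 outside."""
        grid = np.zeros(mask_bool.shape, dtype=np.int32)
        grid[mask_bool] = self.levels
        return grid


def discretise(intensities: np.ndarray,
               n_bins: int = N_BINS_DEFAULT) -> DiscretisedRoi:
    """Fixed-bin-number discretisation over the in-ROI [min, max] range.

    A constant ROI maps every voxel to level 1.
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    x = np.asarray(intensities, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("cannot discretise an empty ROI")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return DiscretisedRoi(np.ones(x.size, dtype=np.int32), n_bins,
                              np.array([lo, hi]))
    lev = np.floor(n_bins * (x - lo) / (hi - lo)).astype(np.int32) + 1
    lev = np.minimum(lev, n_bins)
    edges = np.linspace(lo, hi, n_bins + 1)
    return DiscretisedRoi(lev, n_bins, edges)


def _ih_features(droi: DiscretisedRoi) -> dict[str, float]:
    lev = droi.levels.astype(float)
    ng = droi.n_levels
    n = lev.size
    counts = np.bincount(droi.levels, minlength=ng + 1)[1:]
    p = counts / n

    mu = lev.mean()
    var = lev.var()
    sd = np.sqrt(var)
    p10, q25, med, q75, p90 = np.percentile(lev, [10, 25, 50, 75, 90])
    skew = float(np.mean((lev - mu) ** 3) / sd**3) if sd > 0 else 0.0
    kurt = float(np.mean((lev - mu) ** 4) / sd**4 - 3.0) if sd > 0 else 0.0
    sub = lev[(lev >= p10) & (lev <= p90)]
    nz = p > 0
    entropy = float(-np.sum(p[nz] * np.log2(p[nz])))
    uniformity = float(np.sum(p**2))

    grad = np.gradient(counts.astype(float)) if ng > 1 else np.zeros(1)
    i_max, i_min = int(np.argmax(grad)), int(np.argmin(grad))

    return {
        "ih_mean": float(mu),
        "ih_variance": float(var),
        "ih_skewness": skew,
        "ih_kurtosis": kurt,
        "ih_median": float(med),
        "ih_minimum": float(lev.min()),
        "ih_p10": float(p10),
        "ih_p90": float(p90),
        "ih_maximum": float(lev.max()),
        "ih_mode": float(np.argmax(counts) + 1),
        "ih_iqr": float(q75 - q25),
        "ih_range": float(lev.max() - lev.min()),
        "ih_mad": float(np.mean(np.abs(lev - mu))),
        "ih_rmad": float(np.mean(np.abs(sub - sub.mean()))) if sub.size else 0.0,
        "ih_medad": float(np.mean(np.abs(lev - med))),
        "ih_cov": float(sd / mu) if mu != 0 else 0.0,
        "ih_qcod": float((q75 - q25) / (q75 + q25)) if (q75 + q25) != 0 else 0.0,
        "ih_entropy": entropy,
        "ih_uniformity": uniformity,
        "ih_max_gradient": float(grad[i_max]),
        "ih_max_gradient_level": float(i_max + 1),
        "ih_min_gradient": float(grad[i_min]),
        "ih_min_gradient_level": float(i_min + 1),
    }


def _ivh_features(x: np.ndarray) -> dict[str, float]:
    """Intensity-volume histogram on continuous intensities.

    V(i) = fraction of ROI volume with intensity >= i.  ``vXX`` evaluates
    V at the intensity XX% of the way from min to max; ``iXX`` is the
    largest intensity at which at least XX% of the volume remains.
    """
    lo, hi = float(x.min()), float(x.max())
    n = x.size
    xs = np.sort(x)

    def v_at(frac: float) -> float:
        thr = lo + frac * (hi - lo)
        return float(np.sum(x >= thr) / n)

    def i_at(vfrac: float) -> float:
        # largest intensity i with V(i) >= vfrac; V(xs[k]) = (n-k)/n
        k = int(np.floor(n * (1 - vfrac)))
        k = min(max(k, 0), n - 1)
        # ensure V >= vfrac (ties/rounding)
        while k > 0 and (n - k) / n < vfrac:
            k -= 1
        return float(xs[k])

    fr = [0.10, 0.25, 0.50, 0.75, 0.90]
    v = {f"ivh_v{int(f*100)}": v_at(f) for f in fr}
    i = {f"ivh_i{int(f*100)}": i_at(f) for f in fr}
    # area under V as a function of normalised intensity fraction
    if hi > lo:
        grid = np.linspace(0, 1, 101)
        auc = float(np.trapezoid([np.sum(x >= lo + g * (hi - lo)) / n
                                  for g in grid], grid))
    else:
        auc = 1.0
    out = {**v, **i,
           "ivh_diff_v10_v90": v["ivh_v10"] - v["ivh_v90"],
           "ivh_diff_i10_i90": i["ivh_i10"] - i["ivh_i90"],
           "ivh_auc": auc}
    return out


def _sphere_kernel(radius_mm: float, spacing_mm: float) -> np.ndarray:
    r_vox = int(np.ceil(radius_mm / spacing_mm))
    ax = (np.arange(2 * r_vox + 1) - r_vox) * spacing_mm
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    return (zz**2 + yy**2 + xx**2 <= radius_mm**2).astype(float)


def intensity_peaks(image_values: np.ndarray, mask_bool: np.ndarray,
                    spacing_mm: float) -> dict[str, float]:
    """Local and global intensity peaks (1 cm³ spherical neighbourhood).

    The local peak is the sphere-mean at the brightest in-ROI voxel; the
    global peak is the largest sphere-mean over all in-ROI voxels.  Sphere
    means include out-of-ROI voxels; near image borders the mean is taken
    over the voxels actually inside the grid.
    """
    radius_mm = (3.0 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)  # 1 cm³ sphere
    kern = _sphere_kernel(radius_mm, spacing_mm)
    num = signal.fftconvolve(image_values, kern, mode="same")
    den = signal.fftconvolve(np.ones_like(image_values), kern, mode="same")
    sphere_mean = num / den
    in_roi_mean = sphere_mean[mask_bool]

    vals = image_values[mask_bool]
    peak_idx = np.flatnonzero(vals == vals.max())
    # ties at the maximum intensity: take the largest sphere mean (IBSI)
    local = float(np.max(in_roi_mean[peak_idx]))
    return {"peak_local": local, "peak_global": float(in_roi_mean.max())}


def histogram_features(droi: DiscretisedRoi, intensities: np.ndarray,
                       image_values: np.ndarray | None = None,
                       mask_bool: np.ndarray | None = None,
                       spacing_mm: float = 1.0) -> dict[str, float]:
    """All 38 histogram-based features.

    ``image_values``/``mask_bool`` provide the spatial context needed for
    the two intensity-peak features; when omitted the peaks degrade to the
    ROI maximum and mean (logged), which keeps the feature vector complete
    on purely tabular input.
    """
    x = np.asarray(intensities, dtype=float).ravel()
    out = _ih_features(droi)
    out.update(_ivh_features(x))
    if image_values is not None and mask_bool is not None:
        out.update(intensity_peaks(image_values, mask_bool, spacing_mm))
    else:
        log.debug("no spatial context: intensity peaks fall back to "
                  "ROI max/mean")
        out["peak_local"] = float(x.max())
        out["peak_global"] = float(x.mean())
    return out
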