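"""Spatial filter bank: stationary coiflet-1 wavelets and Laplacian of Gaussian.

Each patient image is expanded into nine additional images that emphasise
edges and blobs at different scales:

* eight single-level *stationary* (undecimated) coiflet-1 wavelet images,
  one per high-/low-pass combination along the three spatial axes
  (LLL, LLH, ..., HHH);
* one Laplacian-of-Gaussian (LoG) image combining five kernel widths
  (1, 2, 3, 5 and 6 mm) by a voxelwise mean of scale-normalised responses.

The stationary wavelet transform at level 1 is separable filtering with
the coiflet-1 decomposition filters and no downsampling; it is implemented
here as direct 1D correlation per axis with mirror (symmetric) boundary
handling, so every output lives on the input grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage

from .core import ImageVolume

__all__ = ["FilterBankOutput", "wavelet_bank", "log_filter", "filter_bank",
           "WAVELET_LABELS", "LOG_SIGMAS_MM"]

#: axis-order convention: label characters apply to axes (z, y, x)
WAVELET_LABELS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")
LOG_SIGMAS_MM = (1.0, 2.0, 3.0, 5.0, 6.0)


@dataclass
class FilterBankOutput:
    """Base image plus the nine filtered companions."""

    base: ImageVolume
    wavelet_images: dict[str, ImageVolume]
    log_image: ImageVolume

    def __post_init__(self) -> None:
        if set(self.wavelet_images) != set(WAVELET_LABELS):
            raise ValueError("expected exactly the 8 wavelet combinations")
        for img in self.images().values():
            if img.shape != self.base.shape:
                raise ValueError("filtered image grid differs from base")

    @property
    def transform_labels(self) -> list[str]:
        return ["base"] + [f"wav_{k}" for k in WAVELET_LABELS] + ["log"]

    def images(self) -> dict[str, ImageVolume]:
        out = {"base": self.base}
        out.update({f"wav_{k}": v for k, v in self.wavelet_images.items()})
        out["log"] = self.log_image
        return out


def _coif1_filters() -> tuple[np.ndarray, np.ndarray]:
    w = pywt.Wavelet("coif1")
    return np.asarray(w.dec_lo, dtype=float), np.asarray(w.dec_hi, dtype=float)


def wavelet_bank(image: ImageVolume) -> dict[str, ImageVolume]:
    """Single-level stationary coiflet-1 decomposition along each axis.

    Returns the 8 high/low combinations keyed LLL...HHH, where the i-th
    label character selects the low- (L) or high-pass (H) filter along the
    i-th array axis (z, y, x).  Mirror boundary handling; output grids
    equal the input grid.
    """
    lo, hi = _coif1_filters()
    if min(image.shape) < lo.size:
        raise ValueError(
            f"image shape {image.shape} smaller than coiflet-1 support "
            f"({lo.size} taps)")
    bank: dict[str, ImageVolume] = {}
    for label in WAVELET_LABELS:
        out = image.values
        for axis, ch in enumerate(label):
            f = lo if ch == "L" else hi
            out = ndimage.correlate1d(out, f, axis=axis, mode="mirror")
        bank[label] = image.with_values(out)
    return bank


def log_filter(image: ImageVolume,
               sigmas_mm: tuple[float, ...] = LOG_SIGMAS_MM) -> ImageVolume:
    """Multi-scale Laplacian of Gaussian combined into one image.

    Each scale contributes the scale-normalised response σ²·(∇²G_σ ∗ I);
    the five responses are combined by a voxelwise mean.  Mirror boundary
    handling.  ``sigmas_mm`` are physical widths converted to voxels via
    the (isotropic) image spacing.
    """
    if len(sigmas_mm) == 0:
        raise ValueError("need at least one LoG kernel width")
    if any(s <= 0 for s in sigmas_mm):
        raise ValueError("LoG kernel widths must be positive")
    if not image.is_isotropic:
        raise ValueError("LoG filter requires an isotropic image")
    spacing = image.spacing_mm[0]
    acc = np.zeros_like(image.values)
    for s_mm in sigmas_mm:
        s_vox = s_mm / spacing
        resp = ndimage.gaussian_laplace(image.values, sigma=s_vox,
                                        mode="mirror", truncate=6.0)
        # sigma_vox^2 * voxel-Laplacian == sigma_mm^2 * mm-Laplacian
        acc += (s_vox ** 2) * resp
    return image.with_values(acc / len(sigmas_mm))


def filter_bank(image: ImageVolume,
                sigmas_mm: tuple[float, ...] = LOG_SIGMAS_MM
                ) -> FilterBankOutput:
    """All ten images (base + 8 wavelet + 1 LoG) for one patient."""
    return FilterBankOutput(base=image,
                            wavelet_images=wavelet_bank(image),
                            log_image=log_filter(image, sigmas_mm))
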