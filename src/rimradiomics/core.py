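"""Core in-memory containers shared by all stages of the pipeline.

Arrays use axis order (z, y, x); coordinates refer to voxel centres.
Intensities are CT-like Hounsfield units (HU).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageVolume", "RoiMask", "SubVolumeSet"]


@dataclass
class ImageVolume:
    """A 3D scalar image on a regular grid.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        Voxel intensities in HU (or filter response units for transformed
        images).
    spacing_mm : tuple of 3 floats
        Voxel spacing along (z, y, x) in millimetres.
    origin_mm : tuple of 3 floats
        Physical position of the centre of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"image must be 3D, got ndim={self.values.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def is_isotropic(self) -> bool:
        s = self.spacing_mm
        return abs(s[0] - s[1]) < 1e-9 and abs(s[1] - s[2]) < 1e-9

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def with_values(self, values: np.ndarray) -> "ImageVolume":
        """New volume on the same grid with different values."""
        return ImageVolume(values, self.spacing_mm, self.origin_mm)


@dataclass
class RoiMask:
    """A binary region-of-interest mask aligned to an :class:`ImageVolume`.

    ``role`` labels the sub-volume the mask represents, e.g. ``"entire"``,
    ``"rim3"``, ``"core5"`` or ``"rim5+ext2"``.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    role: str = "entire"
    margin_mm: float | None = None
    extension_mm: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask must be binary 0/1, got values {uniq[:10]}")
        self.values = arr.astype(np.uint8)
        if self.values.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={self.values.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def bool_array(self) -> np.ndarray:
        return self.values.astype(bool)

    def with_values(self, values: np.ndarray, role: str | None = None,
                    **meta) -> "RoiMask":
        return RoiMask(values, self.spacing_mm, self.origin_mm,
                       role=role if role is not None else self.role,
                       margin_mm=meta.get("margin_mm", self.margin_mm),
                       extension_mm=meta.get("extension_mm", self.extension_mm))

    def check_aligned(self, image: ImageVolume) -> None:
        if self.values.shape != image.values.shape:
            raise ValueError(
                f"mask shape {self.values.shape} != image shape {image.values.shape}")
        if not np.allclose(self.spacing_mm, image.spacing_mm):
            raise ValueError("mask spacing differs from image spacing")


@dataclass
class SubVolumeSet:
    """Entire tumour mask together with its rim/core decomposition.

    Invariants (enforced on construction): rim and core are disjoint and
    their union is the entire mask; the core holds at least
    ``min_fraction`` of the entire volume.
    """

    entire: RoiMask
    rim: RoiMask
    core: RoiMask
    extended_rims: dict[float, RoiMask] = field(default_factory=dict)
    margin_mm: float = 0.0

    def __post_init__(self) -> None:
        e = self.entire.bool_array()
        r = self.rim.bool_array()
        c = self.core.bool_array()
        if np.any(r & c):
            raise ValueError("rim and core overlap")
        if not np.array_equal(r | c, e):
            raise ValueError("rim ∪ core != entire")

    @property
    def core_fraction(self) -> float:
        n = self.entire.voxel_count
        return self.core.voxel_count / n if n else float("nan")

    def roles(self) -> dict[str, RoiMask]:
        out = {"entire": self.entire, self.rim.role: self.rim,
               self.core.role: self.core}
        for ext, m in self.extended_rims.items():
            out[m.role] = m
        return out
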