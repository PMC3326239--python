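"""Volumetric image and mask containers plus NIfTI round-tripping.

:class:`ImageVolume` is the universal carrier for PET-like intensity grids
(raw activity concentration or SUV) with physical voxel spacing in mm;
:class:`BinaryMask` carries segmentations and ground truth on a congruent
grid.  NIfTI files are read and written through nibabel with the voxel
spacing stored in the affine, so spacing round-trips exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "BinaryMask",
    "read_nifti",
    "write_nifti",
    "read_mask",
    "write_mask",
]


def _as_spacing(spacing) -> tuple[float, float, float]:
    s = tuple(float(v) for v in np.atleast_1d(spacing))
    if len(s) == 1:
        s = s * 3
    if len(s) != 3:
        raise ValueError(f"spacing must have 3 components, got {spacing!r}")
    if any(v <= 0 for v in s):
        raise ValueError(f"spacing components must be positive, got {s}")
    return s  # type: ignore[return-value]


@dataclass
class ImageVolume:
    """A 3-D real-valued intensity grid with per-axis voxel size in mm.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel intensities; finite.
    spacing : sequence of 3 floats
        Voxel size along each axis, mm (a scalar is broadcast).
    units_tag : {"raw", "suv"}
        Whether intensities are raw activity concentration (Bq/ml) or
        standardized uptake values.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    units_tag: str = "suv"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("ImageVolume requires a 3-D grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ImageVolume values must be finite")
        self.spacing = _as_spacing(self.spacing)
        if self.units_tag not in ("raw", "suv"):
            raise ValueError(f"unknown units_tag {self.units_tag!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_values(self, values: np.ndarray, units_tag: str | None = None) -> "ImageVolume":
        """New volume on the same grid with replaced intensities."""
        return ImageVolume(values, self.spacing, units_tag or self.units_tag)

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.values.copy(), self.spacing, self.units_tag)


@dataclass
class BinaryMask:
    """A 3-D boolean grid geometrically congruent to an :class:`ImageVolume`."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError("BinaryMask requires a 3-D grid")
        self.spacing = _as_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def volume_cm3(self) -> float:
        """Mask volume: voxel count x voxel volume, in cm^3."""
        return self.n_voxels * self.voxel_volume_mm3 / 1000.0

    def is_empty(self) -> bool:
        return not self.values.any()

    def copy(self) -> "BinaryMask":
        return BinaryMask(self.values.copy(), self.spacing)


def check_congruent(a, b) -> None:
    """Raise if two volumes/masks do not share shape and spacing."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing, b.spacing):
        raise ValueError(f"spacing mismatch: {a.spacing} vs {b.spacing}")


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_nifti(vol: ImageVolume | BinaryMask, path) -> None:
    """Write a volume (float32) or mask (uint8 0/1) as NIfTI-1."""
    if isinstance(vol, BinaryMask):
        data = vol.values.astype(np.uint8)
    else:
        data = vol.values.astype(np.float32)
    img = nib.Nifti1Image(data, _affine(vol.spacing))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_nifti(path, units_tag: str = "suv") -> ImageVolume:
    """Load a NIfTI volume; voxel spacing taken from the header zooms."""
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return ImageVolume(data, spacing, units_tag)


def read_mask(path) -> BinaryMask:
    """Load a NIfTI file as a binary mask (voxels > 0.5 are foreground)."""
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return BinaryMask(data > 0.5, spacing)


def write_mask(mask: BinaryMask, path) -> None:
    write_nifti(mask, path)
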