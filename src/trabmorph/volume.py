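"""Physical-space image containers and volume I/O.

Every 3D grid in this package carries its voxel spacing in millimetres so
that regions of interest can be defined in physical units and mapped onto
whichever grid (fine microCT-like or coarse MR-like) they are measured on.

Axis convention, used consistently throughout the package:

* axis 0 — anterior-posterior (the MR slice direction; coronal slices),
* axis 1 — vertical, superior at row 0 (image-row convention),
* axis 2 — medial-lateral (image columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

__all__ = [
    "ImageVolume",
    "BinaryVolume",
    "GeometryError",
    "load_nifti",
    "save_nifti",
    "load_tiff_stack",
    "save_tiff_stack",
]


class GeometryError(ValueError):
    """A physical region does not fit on the grid it is evaluated on."""


def _check_spacing(spacing: tuple[float, float, float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive lengths in mm, got {spacing}")
    return spacing


@dataclass
class ImageVolume:
    """A 3D scalar image with physical voxel spacing.

    Parameters
    ----------
    voxels:
        3D array of intensities, axes (anterior-posterior, vertical,
        medial-lateral).  Voxel ``(i, j, k)`` occupies the half-open box
        ``[origin + idx*spacing, origin + (idx+1)*spacing)`` and its centre
        sits at ``origin + (idx + 0.5) * spacing``.
    spacing:
        Voxel edge lengths in mm per axis.
    origin:
        Physical position (mm) of the corner of voxel ``(0, 0, 0)``.
    intensity_range:
        Declared (min, max) of the intensity scale, e.g. ``(0, 255)`` for
        8-bit microCT reconstructions.  Informational; not enforced.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    intensity_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("voxels must be a non-empty 3D array")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels must be finite")
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size of the grid in mm per axis."""
        return tuple(n * s for n, s in zip(self.voxels.shape, self.spacing))


@dataclass
class BinaryVolume:
    """A boolean bone (True) / background (False) grid with spacing in mm."""

    mask: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 3 or self.mask.size == 0:
            raise ValueError("mask must be a non-empty 3D array")
        if self.mask.dtype != bool:
            if not np.isin(self.mask, (0, 1)).all():
                raise ValueError("mask must be boolean or 0/1 valued")
            self.mask = self.mask.astype(bool)
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def extent(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.mask.shape, self.spacing))

    def bone_fraction(self) -> float:
        return float(self.mask.mean())


def _affine(spacing: tuple[float, float, float], origin: tuple[float, float, float]) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def save_nifti(volume: ImageVolume | BinaryVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI with the spacing encoded in the affine."""
    path = Path(path)
    data = volume.mask.astype(np.uint8) if isinstance(volume, BinaryVolume) else volume.voxels
    img = nib.Nifti1Image(np.asarray(data), _affine(volume.spacing, volume.origin))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))
    return path


def load_nifti(path: str | Path, binary: bool = False) -> ImageVolume | BinaryVolume:
    """Read a NIfTI volume, taking spacing from the header zooms."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    if binary:
        return BinaryVolume(data.astype(bool), spacing, origin)
    return ImageVolume(data.astype(np.float64), spacing, origin)


def save_tiff_stack(volume: ImageVolume, path: str | Path) -> Path:
    """Write an 8-bit multi-page TIFF, one page per axis-0 slice."""
    path = Path(path)
    data = np.asarray(volume.voxels)
    if data.min() < 0 or data.max() > 255:
        raise ValueError("TIFF stack export requires intensities in [0, 255]")
    tifffile.imwrite(str(path), np.round(data).astype(np.uint8), photometric="minisblack")
    return path


def load_tiff_stack(path: str | Path, spacing: tuple[float, float, float]) -> ImageVolume:
    """Read a multi-page TIFF stack; spacing (mm) must be supplied by the caller."""
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    return ImageVolume(data.astype(np.float64), spacing, intensity_range=(0, 255))
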