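"""Shared image containers and NIfTI I/O.

An :class:`ImageVolume` is an isotropic-or-not 3D scalar grid (Hounsfield
units upstream, 8-bit gray levels after requantization) with per-axis
spacing in millimetres.  A :class:`RoiMask` is a binary grid on the same
geometry delineating the gross tumor volume (GTV).  The third array axis is
the axial (slice) direction throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "RoiMask", "check_same_geometry"]


def _validate_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive floats, got {spacing!r}")
    return spacing


@dataclass(frozen=True)
class ImageVolume:
    """3D scalar image with isotropic-or-anisotropic voxel spacing (mm)."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={values.ndim}")
        if not np.all(np.isfinite(values)):
            raise ValueError("image contains non-finite values")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", _validate_spacing(self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def save(self, path: str | Path) -> None:
        affine = np.diag((*self.spacing, 1.0))
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.values.astype(np.float32), affine), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "ImageVolume":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(o) for o in img.affine[:3, 3])
        return cls(np.asarray(img.dataobj, dtype=float), spacing, origin)


@dataclass(frozen=True)
class RoiMask:
    """Binary region-of-interest grid sharing geometry with an ImageVolume."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={values.ndim}")
        uniq = np.unique(values)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be binary (0/1)")
        values = values.astype(np.uint8)
        if values.sum() == 0:
            raise ValueError("mask has no foreground voxels")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", _validate_spacing(self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def save(self, path: str | Path) -> None:
        affine = np.diag((*self.spacing, 1.0))
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.values.astype(np.uint8), affine), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "RoiMask":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(o) for o in img.affine[:3, 3])
        return cls(np.asarray(img.dataobj), spacing, origin)


def check_same_geometry(image: ImageVolume, mask: RoiMask, *, atol: float = 1e-6) -> None:
    """Raise if image and mask do not share shape and spacing."""
    if image.shape != mask.shape:
        raise ValueError(f"shape mismatch: {image.shape} vs {mask.shape}")
    if not np.allclose(image.spacing, mask.spacing, atol=atol):
        raise ValueError(f"spacing mismatch: {image.spacing} vs {mask.spacing}")
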