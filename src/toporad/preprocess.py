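"""Preprocessing: isotropic resampling, 8-bit requantization, LoG edge
enhancement, and maximum-GTV axial slice selection.

The preprocessing chain mirrors standard thoracic radiomics practice:
planning CT and GTV mask are resampled to an isotropic grid (0.98 mm by
default), intensities are requantized to 256 gray levels through a look-up
table over a Hounsfield-unit window, and a Laplacian-of-Gaussian filter
enhances lesion boundaries before topological mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .images import ImageVolume, RoiMask, check_same_geometry

__all__ = [
    "RequantizationWindow",
    "LoGConfig",
    "resample_isotropic",
    "resample_mask_shape_based",
    "requantize",
    "level_to_hu_offset",
    "log_filter",
    "select_max_gtv_slice",
]

#: default isotropic voxel edge (mm)
DEFAULT_ISO_MM = 0.98

#: default HU window, the "lung range" look-up table
LUNG_WINDOW = None  # set below once the class exists


@dataclass(frozen=True)
class RequantizationWindow:
    """HU window mapped linearly onto 256 gray levels (0..255)."""

    hu_min: float = -1350.0
    hu_max: float = 150.0
    levels: int = 256

    def __post_init__(self) -> None:
        if not self.hu_min < self.hu_max:
            raise ValueError("hu_min must be < hu_max")
        if self.levels != 256:
            raise ValueError("requantization is fixed at 256 levels")

    @property
    def width(self) -> float:
        return self.hu_max - self.hu_min


LUNG_WINDOW = RequantizationWindow(-1350.0, 150.0)


@dataclass(frozen=True)
class LoGConfig:
    """Laplacian-of-Gaussian scale (in voxels) and kernel extent."""

    sigma_vox: float = 1.0
    truncate: float = 4.0

    def __post_init__(self) -> None:
        if self.sigma_vox <= 0:
            raise ValueError("sigma_vox must be positive")


def _iso_grid_coords(shape, spacing, iso_mm):
    """New grid sizes and source-space coordinates for each axis; only grid
    points inside the original extent are produced."""
    sizes, coords = [], []
    for n, sp in zip(shape, spacing):
        extent = (n - 1) * sp
        m = int(np.floor(extent / iso_mm)) + 1
        sizes.append(m)
        coords.append(np.arange(m) * iso_mm / sp)
    return sizes, coords


def resample_isotropic(volume: ImageVolume, iso_mm: float = DEFAULT_ISO_MM) -> ImageVolume:
    """Cubic-spline resampling of an intensity volume to an isotropic grid."""
    if iso_mm <= 0:
        raise ValueError("iso_mm must be positive")
    if min(volume.shape) < 4:
        raise ValueError("volume too thin for cubic resampling (needs >= 4 per axis)")
    if np.allclose(volume.spacing, iso_mm):
        return ImageVolume(volume.values.copy(), (iso_mm,) * 3, volume.origin)
    sizes, coords = _iso_grid_coords(volume.shape, volume.spacing, iso_mm)
    grid = np.meshgrid(*coords, indexing="ij")
    resampled = ndimage.map_coordinates(
        volume.values, np.stack([g.ravel() for g in grid]), order=3, mode="nearest"
    ).reshape(sizes)
    return ImageVolume(resampled, (iso_mm,) * 3, volume.origin)


def resample_mask_shape_based(mask: RoiMask, iso_mm: float = DEFAULT_ISO_MM) -> RoiMask:
    """Shape-based mask resampling through a signed distance field.

    Per axial slice a signed Euclidean distance map (negative inside the
    mask, in mm) is computed; the stacked distance field is linearly
    interpolated to the isotropic grid and re-thresholded at zero.  Output
    is strictly binary and, for convex inputs, stays connected.
    """
    if iso_mm <= 0:
        raise ValueError("iso_mm must be positive")
    m = mask.values.astype(bool)
    if m.sum() == 0:
        raise ValueError("empty mask")
    sd = np.empty(m.shape, dtype=float)
    in_plane = mask.spacing[:2]
    for k in range(m.shape[2]):
        sl = m[:, :, k]
        if sl.any():
            outside = ndimage.distance_transform_edt(~sl, sampling=in_plane)
            inside = ndimage.distance_transform_edt(sl, sampling=in_plane)
            sd[:, :, k] = outside - inside
        else:
            # empty slice: positive distance grows away from populated slices
            sd[:, :, k] = np.inf
    # replace inf with a large finite distance for interpolation stability
    finite_max = np.nanmax(np.where(np.isinf(sd), np.nan, sd))
    sd = np.where(np.isinf(sd), finite_max + max(mask.spacing) * m.shape[2], sd)
    sizes, coords = _iso_grid_coords(m.shape, mask.spacing, iso_mm)
    grid = np.meshgrid(*coords, indexing="ij")
    resampled = ndimage.map_coordinates(
        sd, np.stack([g.ravel() for g in grid]), order=1, mode="nearest"
    ).reshape(sizes)
    out = (resampled <= 0).astype(np.uint8)
    if out.sum() == 0:
        raise ValueError("resampled mask is empty")
    return RoiMask(out, (iso_mm,) * 3, mask.origin)


def requantize(volume: ImageVolume, window: RequantizationWindow) -> ImageVolume:
    """Map HU values onto 8-bit levels through the window look-up table.

    ``v -> clamp(round(255 * (v - hu_min) / width), 0, 255)`` with
    round-half-up, so hu_min maps to 0 and hu_max to 255.
    """
    scaled = (volume.values - window.hu_min) / window.width * 255.0
    levels = np.clip(np.floor(scaled + 0.5), 0, 255)
    return ImageVolume(levels, volume.spacing, volume.origin)


def level_to_hu_offset(level: float, window: RequantizationWindow) -> float:
    """HU offset above the window floor corresponding to a gray level.

    This is the reporting convention for quoting thresholds in HU, e.g.
    level 235 of a 1500-HU-wide window is ~1382 HU above the floor.
    """
    if not 0 <= level <= 255:
        raise ValueError("level must be in [0, 255]")
    return level / 255.0 * window.width


def log_filter(
    volume: ImageVolume,
    cfg: LoGConfig = LoGConfig(),
    *,
    mask: RoiMask | None = None,
    rewindow: bool = True,
) -> ImageVolume:
    """Laplacian-of-Gaussian response of an 8-bit volume.

    With ``rewindow=True`` (default) the response is linearly mapped back
    to 0..255 by min-max.  When a GTV mask is supplied the min-max is taken
    inside the mask's bounding box dilated by 4 voxels, so the lung
    background does not dominate the window; otherwise the whole field is
    used.  ``rewindow=False`` returns the raw response.
    """
    response = ndimage.gaussian_laplace(
        volume.values.astype(float), sigma=cfg.sigma_vox, truncate=cfg.truncate
    )
    if not rewindow:
        return ImageVolume(response, volume.spacing, volume.origin)
    if mask is not None:
        check_same_geometry(volume, mask)
        idx = np.argwhere(mask.values > 0)
        lo = np.maximum(idx.min(axis=0) - 4, 0)
        hi = np.minimum(idx.max(axis=0) + 5, volume.shape)
        region = response[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    else:
        region = response
    mn, mx = float(region.min()), float(region.max())
    if mx == mn:
        levels = np.zeros_like(response)
    else:
        levels = np.clip(np.floor((response - mn) / (mx - mn) * 255.0 + 0.5), 0, 255)
    return ImageVolume(levels, volume.spacing, volume.origin)


def select_max_gtv_slice(
    volume: ImageVolume, mask: RoiMask
) -> tuple[np.ndarray, np.ndarray, int]:
    """Axial slice with the greatest in-mask pixel count (ties: lowest index).

    Returns (2D image slice, 2D mask slice, slice index); axial is the
    third array axis.
    """
    check_same_geometry(volume, mask)
    counts = mask.values.sum(axis=(0, 1))
    if counts.max() == 0:
        raise ValueError("empty mask")
    k = int(np.argmax(counts))  # argmax returns the first (lowest) index on ties
    return volume.values[:, :, k], mask.values[:, :, k], k
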