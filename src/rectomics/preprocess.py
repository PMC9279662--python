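"""Image conditioning: z-score normalization, isotropic resampling,
1-mm mask erosion and 64-level gray quantization.

Fixed pipeline order: subtraction channels are formed on raw phase
intensities (in the generator / reader), then per channel
z-score -> resample to isotropic grid -> erode mask -> quantize.
Quantization is min-max based inside the (eroded) mask, so it is invariant
to affine intensity rescaling a*x+b with a > 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cohort import MultiparametricStudy

__all__ = [
    "QuantizedROI",
    "znormalize",
    "resample_isotropic",
    "erode_mask",
    "quantize",
    "preprocess_study",
]

log = logging.getLogger(__name__)


@dataclass
class QuantizedROI:
    """Gray levels 1..g inside the eroded mask, 0 outside."""

    levels: np.ndarray
    mask: np.ndarray
    g: int
    spacing_mm: float = 1.0

    def __post_init__(self) -> None:
        inside = self.levels[self.mask]
        if inside.size == 0:
            raise ValueError("quantized ROI mask is empty")
        if inside.min() < 1 or inside.max() > self.g:
            raise ValueError("in-mask levels must lie in [1, g]")


def znormalize(volume: np.ndarray, region_mask: np.ndarray | None = None) -> np.ndarray:
    """Standardize intensities to mean 0 / sd 1 over ``region_mask``.

    The transform estimated on the region is applied to the whole volume.
    By default the region is the nonzero support of the volume.
    """
    volume = np.asarray(volume, dtype=float)
    if region_mask is None:
        region_mask = volume != 0
    region = volume[region_mask]
    if region.size < 2:
        raise ValueError("normalization region must contain >= 2 voxels")
    mu = region.mean()
    sd = region.std()
    if sd == 0:
        raise ValueError("normalization region has zero intensity variance")
    return (volume - mu) / sd


def resample_isotropic(
    volume: np.ndarray,
    mask: np.ndarray,
    spacing_mm: tuple[float, float, float],
    target_spacing: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample intensities (trilinear) and mask (nearest) to an isotropic grid.

    Output shape along each axis is ``round(n * spacing / target)``; an input
    already on the target grid is returned voxel-identical.
    """
    if any(s <= 0 for s in spacing_mm) or target_spacing <= 0:
        raise ValueError("spacings must be positive")
    factors = tuple(s / target_spacing for s in spacing_mm)
    if all(abs(f - 1.0) < 1e-12 for f in factors):
        return np.asarray(volume, dtype=float).copy(), np.asarray(mask, bool).copy()
    out_vol = ndimage.zoom(np.asarray(volume, dtype=float), factors, order=1,
                           mode="nearest", grid_mode=True)
    out_mask = ndimage.zoom(np.asarray(mask, dtype=np.uint8), factors, order=0,
                            mode="nearest", grid_mode=True) > 0
    if not out_mask.any():
        raise ValueError("resampling emptied the tumor mask")
    return out_vol, out_mask


def ball_structure(margin_mm: float, spacing_mm: tuple[float, float, float]) -> np.ndarray:
    """Discrete ball: offsets whose center distance (mm) is <= margin_mm."""
    radii = [int(np.floor(margin_mm / s)) for s in spacing_mm]
    grids = np.meshgrid(*[np.arange(-r, r + 1) for r in radii], indexing="ij")
    d2 = sum((g * s) ** 2 for g, s in zip(grids, spacing_mm))
    return d2 <= margin_mm**2 + 1e-9


def erode_mask(
    mask: np.ndarray,
    margin_mm: float = 1.0,
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Morphological erosion by a discrete ball of radius ``margin_mm``."""
    mask = np.asarray(mask).astype(bool)
    if margin_mm < 0:
        raise ValueError("margin must be >= 0")
    if margin_mm == 0:
        return mask.copy()
    structure = ball_structure(margin_mm, spacing_mm)
    eroded = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    if not eroded.any():
        raise ValueError(f"tumor too small for {margin_mm}-mm margin (erosion empties mask)")
    return eroded


def quantize(volume: np.ndarray, mask: np.ndarray, g: int = 64,
             spacing_mm: float = 1.0) -> QuantizedROI:
    """Fixed-bin-count quantization over the in-mask intensity range.

    level = min(g, floor(g*(x-min)/(max-min)) + 1); a constant region maps
    entirely to level 1.
    """
    if g < 2:
        raise ValueError("g must be >= 2")
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    volume = np.asarray(volume, dtype=float)
    inside = volume[mask]
    lo, hi = inside.min(), inside.max()
    levels = np.zeros(volume.shape, dtype=np.int64)
    if hi == lo:
        levels[mask] = 1
    else:
        scaled = np.floor(g * (volume[mask] - lo) / (hi - lo)).astype(np.int64) + 1
        levels[mask] = np.minimum(scaled, g)
    return QuantizedROI(levels=levels, mask=mask, g=g, spacing_mm=spacing_mm)


def preprocess_study(
    study: MultiparametricStudy,
    target_spacing: float = 1.0,
    erosion_mm: float = 1.0,
) -> MultiparametricStudy:
    """Normalize and resample every channel; erode the common mask.

    Returns a new study on the isotropic grid whose mask is the eroded ROI.
    Quantization happens later, per channel and per wavelet sub-band.
    """
    channels: dict[str, np.ndarray] = {}
    mask_iso = None
    for name, vol in study.channels.items():
        norm = znormalize(vol)
        vol_iso, m = resample_isotropic(norm, study.mask, study.spacing_mm, target_spacing)
        channels[name] = vol_iso
        mask_iso = m
    assert mask_iso is not None
    eroded = erode_mask(mask_iso, erosion_mm, (target_spacing,) * 3)
    return MultiparametricStudy(
        patient_id=study.patient_id,
        channels=channels,
        mask=eroded,
        spacing_mm=(target_spacing,) * 3,
    )
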