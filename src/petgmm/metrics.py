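"""Per-lesion ROI biomarkers and spatial agreement metrics.

An ROI (a binary mask) transferred onto the ADC map yields two biomarkers:
the ROI area (voxel count times physical voxel area, reported in cm^2) and
the mean ADC over ROI voxels with a valid fit.  Agreement between two
segmentations is quantified by the Dice similarity coefficient
``2|A∩B| / (|A|+|B|)`` and the center-of-gravity (CoG) displacement — the
Euclidean distance in mm between the unweighted centroids of the two masks,
optionally normalized by the square root of a reference ROI area so that the
displacement is expressed relative to the reference lesion's linear size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .image import BinaryMask
from .maps import ADCFitResult

__all__ = [
    "ROIMetrics",
    "OverlapMetrics",
    "roi_metrics",
    "dice",
    "center_of_gravity",
    "cog_displacement",
]


@dataclass(frozen=True)
class ROIMetrics:
    """Area (cm^2), mean ADC (mm^2/s; NaN when no valid voxel) and voxel count."""

    area_cm2: float
    mean_adc: float
    n_voxels: int
    n_valid_adc: int
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class OverlapMetrics:
    """Dice in [0,1]; CoG displacement in mm and normalized (NaN when empty)."""

    dice: float
    cog_mm: float
    cog_normalized: float
    flags: tuple[str, ...] = ()


def _check_same_grid(a, b) -> None:
    if a.shape != b.shape:
        raise ValueError(f"grid shape mismatch: {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing, b.spacing) or not np.allclose(a.origin, b.origin):
        raise ValueError("grid geometry mismatch (spacing/origin differ)")


def roi_metrics(mask: BinaryMask, adc: ADCFitResult | None = None) -> ROIMetrics:
    """Area and mean ADC of a mask transferred onto an ADC map.

    Area is ``n_voxels * spacing_row * spacing_col`` converted mm^2 -> cm^2.
    The ADC mean is taken over masked voxels with a valid fit only; if none
    are valid (or no ADC map is given), the mean is NaN and flagged.
    """
    n = mask.n_voxels
    area = n * mask.spacing[0] * mask.spacing[1] / 100.0
    flags: tuple[str, ...] = ()
    if n == 0:
        flags += ("empty_mask",)
    if adc is None:
        return ROIMetrics(area, float("nan"), n, 0, flags + ("no_adc",))
    if adc.adc.shape != mask.shape:
        raise ValueError("mask and ADC map must share one grid")
    sel = mask.mask & adc.valid
    n_valid = int(sel.sum())
    if n_valid == 0:
        return ROIMetrics(area, float("nan"), n, 0, flags + ("no_valid_adc",))
    return ROIMetrics(area, float(adc.adc[sel].mean()), n, n_valid, flags)


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient ``2|A∩B| / (|A|+|B|)``.

    Convention for degenerate inputs: both masks empty -> 1.0 (identical),
    exactly one empty -> 0.0.
    """
    _check_same_grid(a, b)
    na, nb = a.n_voxels, b.n_voxels
    if na + nb == 0:
        return 1.0
    inter = int((a.mask & b.mask).sum())
    return 2.0 * inter / (na + nb)


def center_of_gravity(mask: BinaryMask) -> tuple[float, float]:
    """Unweighted centroid of member-voxel centers, in physical mm.

    Raises ``ValueError`` on an empty mask (not applicable).
    """
    idx = np.argwhere(mask.mask)
    if idx.size == 0:
        raise ValueError("center of gravity is not applicable to an empty mask")
    mean_ij = idx.mean(axis=0)
    return (
        mask.origin[0] + mean_ij[0] * mask.spacing[0],
        mask.origin[1] + mean_ij[1] * mask.spacing[1],
    )


def cog_displacement(
    a: BinaryMask, b: BinaryMask, area_ref_cm2: float | None = None
) -> OverlapMetrics:
    """Dice plus CoG displacement between two masks on one grid.

    ``cog_mm`` is the Euclidean distance between centroids.  When a reference
    area (cm^2) is supplied, ``cog_normalized = cog_mm / sqrt(area_ref_mm2)``
    — the displacement in units of the reference lesion's linear size.  CoG
    fields are NaN and flagged not-applicable when either mask is empty.
    """
    _check_same_grid(a, b)
    d = dice(a, b)
    if a.n_voxels == 0 or b.n_voxels == 0:
        return OverlapMetrics(d, float("nan"), float("nan"), ("cog_not_applicable",))
    ca = center_of_gravity(a)
    cb = center_of_gravity(b)
    cog_mm = math.hypot(ca[0] - cb[0], ca[1] - cb[1])
    if area_ref_cm2 is None or not area_ref_cm2 > 0:
        return OverlapMetrics(d, cog_mm, float("nan"), ("no_reference_area",))
    # sqrt of the reference area in mm^2; 1 cm^2 = 100 mm^2
    cog_norm = cog_mm / (10.0 * math.sqrt(area_ref_cm2))
    return OverlapMetrics(d, cog_mm, cog_norm, ())
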