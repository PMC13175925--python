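"""Automatic lung segmentation from CT and mask algebra.

The segmentation mirrors a classic threshold pipeline: median prefilter
(diameter 3 voxels by default), binarize at a lung HU threshold, discard
exterior air (below-threshold components touching the volume border),
keep connected components of at least 50 mL (6-connectivity), and fill
fully enclosed holes (vessels).  The result is deliberately a *coarse*
mask; a higher-quality mask (phantom truth, or a radiologist-verified
mask on real data) is intersected with it downstream for validation.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .volumes_io import BinaryMask, GeometryError, ScalarVolume

__all__ = ["segment_lungs", "union_mask", "intersect_mask", "EmptyMaskWarning"]

MIN_COMPONENT_ML = 50.0

_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


class EmptyMaskWarning(UserWarning):
    """Segmentation produced no lung voxels."""


def segment_lungs(
    ct: ScalarVolume,
    threshold: float,
    prefilter_diameter: int = 3,
    min_component_ml: float = MIN_COMPONENT_ML,
) -> BinaryMask:
    """Threshold-based lung segmentation.

    Parameters
    ----------
    ct : CT volume in HU.
    threshold : lung intensity threshold in HU, within [-1000, 0];
        voxels strictly below it are lung candidates.
    prefilter_diameter : median-filter kernel diameter in voxels
        (0 disables; otherwise odd and >= 3).
    min_component_ml : minimum connected-component volume kept, in mL.
    """
    if not -1000.0 <= threshold <= 0.0:
        raise ValueError(f"threshold must lie in [-1000, 0] HU, got {threshold}")
    if prefilter_diameter != 0 and (prefilter_diameter < 3 or prefilter_diameter % 2 == 0):
        raise ValueError(f"prefilter_diameter must be 0 or odd >= 3, got {prefilter_diameter}")

    values = np.asarray(ct.values, dtype=float)
    if prefilter_diameter:
        values = ndimage.median_filter(values, size=prefilter_diameter, mode="nearest")
    below = values < threshold

    # drop exterior air: any below-threshold component touching the border
    labels, n = ndimage.label(below, structure=_STRUCT6)
    if n:
        border = np.zeros(below.shape, dtype=bool)
        border[0, :, :] = border[-1, :, :] = True
        border[:, 0, :] = border[:, -1, :] = True
        border[:, :, 0] = border[:, :, -1] = True
        touching = np.unique(labels[border & below])
        keep = np.ones(n + 1, dtype=bool)
        keep[0] = False
        keep[touching] = False
        mask = keep[labels]
        # fill enclosed holes (vessels) before the size filter so strict
        # thresholds do not discard lungs hollowed out by excluded vessels
        if mask.any():
            mask = ndimage.binary_fill_holes(mask)
        # component-size filter (6-connectivity)
        labels2, n2 = ndimage.label(mask, structure=_STRUCT6)
        if n2:
            min_vox = min_component_ml * 1000.0 / ct.grid.voxel_volume_mm3
            sizes = np.bincount(labels2.ravel(), minlength=n2 + 1)
            keep2 = sizes >= min_vox
            keep2[0] = False
            mask = keep2[labels2]
    else:
        mask = below

    if not mask.any():
        warnings.warn("lung segmentation produced an empty mask", EmptyMaskWarning, stacklevel=2)

    return BinaryMask(ct.grid, np.ascontiguousarray(mask))


def _check_same_grid(a: BinaryMask, b: BinaryMask) -> None:
    if a.grid != b.grid:
        raise GeometryError(f"mask grids differ: {a.grid} vs {b.grid}")


def union_mask(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    """Voxel-wise OR (e.g. inhale ∪ exhale lung for the DIR cost region)."""
    _check_same_grid(a, b)
    return BinaryMask(a.grid, a.values | b.values)


def intersect_mask(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    """Voxel-wise AND (e.g. verified mask ∩ coarse mask for validation)."""
    _check_same_grid(a, b)
    return BinaryMask(a.grid, a.values & b.values)
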