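"""Ventilation metrics: Jacobian-based and HU-based, plus masked smoothing.

Two standard metrics, both defined on the exhale grid:

* ``CTVI_Jac(x) = Jac(x) - 1`` — fractional volume change of each lung
  voxel from the Jacobian determinant of the exhale-to-inhale motion field.
* ``CTVI_HU(x) = (HU_ex - HU_in*) / (HU_in* + 1000) * rho_scaling(x)``
  with ``rho_scaling(x) = (HU_ex(x) + 1000) / 1000`` — local change in air
  content from the HU difference between the exhale image and the deformed
  inhale image, density-scaled to model radioaerosol deposition.  The
  asterisk denotes a global intensity correction of the deformed inhale
  image compensating lung-mass changes from blood redistribution during
  inspiration, implemented here as a single multiplicative density factor
  that equalizes total masked lung mass sum(HU + 1000).

Under exact tissue-mass conservation (density_in = density_ex / J) the two
metrics coincide up to the density factor: CTVI_HU = (J - 1) * rho_ex.

Smoothing is an edge-preserving masked median filter: for each lung voxel
the median over the d x d x d index-space neighborhood restricted to lung
voxels, leaving non-lung voxels untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .volumes_io import BinaryMask, GeometryError, ScalarVolume

__all__ = [
    "VentilationImage",
    "ctvi_jacobian",
    "global_intensity_correction",
    "ctvi_hu",
    "median_smooth",
]

DENSITY_FLOOR = 1.0  # HU-equivalent clamp of the CTVI_HU denominator


@dataclass
class VentilationImage:
    """A ventilation map on the exhale grid."""

    volume: ScalarVolume
    method: Literal["Jac", "HU"]
    smoothing_diameter: int = 0
    rho_scaling: ScalarVolume | None = None  # stored when method == "HU"
    n_clamped: int = 0  # near-air voxels whose denominator was clamped


def ctvi_jacobian(jac: ScalarVolume) -> VentilationImage:
    """CTVI_Jac = Jac - 1 voxel-wise."""
    values = np.asarray(jac.values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("Jacobian map contains non-finite values")
    return VentilationImage(
        ScalarVolume(jac.grid, values - 1.0, "ventilation", jac.valid), method="Jac"
    )


def global_intensity_correction(
    deformed_inhale: ScalarVolume, exhale: ScalarVolume, mask: BinaryMask
) -> ScalarVolume:
    """Rescale deformed-inhale densities so masked lung mass matches exhale.

    f = sum_mask(HU_ex + 1000) / sum_mask(HU_in* + 1000); corrected
    HU = f * (HU_in* + 1000) - 1000, applied everywhere, meaningful within
    the mask.
    """
    if deformed_inhale.grid != exhale.grid or mask.grid != exhale.grid:
        raise GeometryError("volumes and mask must share one grid")
    if mask.n_true == 0:
        raise ValueError("mask is empty")
    m = mask.values
    dens_in = deformed_inhale.density()
    dens_ex = exhale.density()
    denom = float(dens_in[m].sum())
    if denom <= 0:
        raise ZeroDivisionError("total deformed-inhale lung density is zero")
    f = float(dens_ex[m].sum()) / denom
    return ScalarVolume(exhale.grid, f * dens_in - 1000.0, "HU", deformed_inhale.valid)


def ctvi_hu(
    exhale: ScalarVolume, corrected_inhale: ScalarVolume, mask: BinaryMask
) -> VentilationImage:
    """HU-based ventilation on mask voxels; NaN outside the mask.

    ``corrected_inhale`` must already carry the global intensity
    correction.  Denominators (HU_in* + 1000) below ``DENSITY_FLOOR`` are
    clamped; the clamped-voxel count is reported on the result.
    """
    if exhale.grid != corrected_inhale.grid or mask.grid != exhale.grid:
        raise GeometryError("volumes and mask must share one grid")
    hu_ex = np.asarray(exhale.values, dtype=float)
    hu_in = np.asarray(corrected_inhale.values, dtype=float)
    denom = hu_in + 1000.0
    m = mask.values
    n_clamped = int((denom[m] < DENSITY_FLOOR).sum())
    denom = np.maximum(denom, DENSITY_FLOOR)
    rho = (hu_ex + 1000.0) / 1000.0
    vent = (hu_ex - hu_in) / denom * rho
    out = np.where(m, vent, np.nan)
    valid = m.copy()
    for v in (exhale.valid, corrected_inhale.valid):
        if v is not None:
            valid &= v
    return VentilationImage(
        ScalarVolume(exhale.grid, out, "ventilation", valid),
        method="HU",
        rho_scaling=ScalarVolume(exhale.grid, rho, "dimensionless"),
        n_clamped=n_clamped,
    )


def median_smooth(vent: VentilationImage, mask: BinaryMask, diameter: int) -> VentilationImage:
    """Edge-preserving masked median filter.

    For each mask voxel, the median over the ``diameter``-cubed index-space
    neighborhood restricted to mask voxels; non-mask voxels unchanged.
    ``diameter`` 0 is the unfiltered identity; otherwise it must be odd >= 3.
    """
    if diameter == 0:
        return VentilationImage(
            vent.volume.with_values(np.array(vent.volume.values, copy=True)),
            vent.method,
            0,
            vent.rho_scaling,
            vent.n_clamped,
        )
    if diameter < 3 or diameter % 2 == 0:
        raise ValueError(f"diameter must be 0 or odd >= 3, got {diameter}")
    if mask.grid != vent.volume.grid:
        raise GeometryError("mask grid must match the ventilation grid")

    values = np.asarray(vent.volume.values, dtype=float)
    out = np.array(values, copy=True)
    m = mask.values
    if m.any():
        out[m] = _masked_median(values, m, diameter)
    return VentilationImage(
        ScalarVolume(vent.volume.grid, out, vent.volume.unit, vent.volume.valid),
        vent.method,
        diameter,
        vent.rho_scaling,
        vent.n_clamped,
    )


def _masked_median(values: np.ndarray, mask: np.ndarray, diameter: int) -> np.ndarray:
    """Median of in-mask neighbors for every mask voxel (vectorized).

    Works on the mask bounding box, padding with NaN and taking nanmedian
    over sliding windows; chunked along x to bound memory for large kernels.
    """
    r = diameter // 2
    idx = np.nonzero(mask)
    lo = [max(int(i.min()) - r, 0) for i in idx]
    hi = [min(int(i.max()) + r + 1, s) for i, s in zip(idx, mask.shape)]
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    vals = np.where(mask[box], values[box], np.nan)
    padded = np.pad(vals, r, mode="constant", constant_values=np.nan)

    from numpy.lib.stride_tricks import sliding_window_view

    box_shape = vals.shape
    out_box = np.empty(box_shape)
    # chunk along x to keep the window view's nanmedian workspace bounded
    chunk = max(1, int(2e7 // (diameter**3 * box_shape[1] * box_shape[2] + 1)))
    import warnings

    with warnings.catch_warnings():
        # windows fully outside the mask are all-NaN; they are discarded below
        warnings.filterwarnings("ignore", message="All-NaN slice encountered")
        for x0 in range(0, box_shape[0], chunk):
            x1 = min(x0 + chunk, box_shape[0])
            win = sliding_window_view(
                padded[x0 : x1 + 2 * r], (diameter, diameter, diameter)
            )
            out_box[x0:x1] = np.nanmedian(win.reshape(win.shape[:3] + (-1,)), axis=-1)

    sub_mask = mask[box]
    return out_box[sub_mask]
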