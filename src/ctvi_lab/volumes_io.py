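"""Volumetric data types, grid geometry, resampling, and standard-format I/O.

Conventions used throughout the package:

* arrays are indexed ``values[i, j, k]`` with axes (x, y, z) =
  (left-right, ant-post, sup-inf); indices are 0-based
* the physical coordinate (mm) of voxel ``(i, j, k)`` is
  ``origin + (i * sx, j * sy, k * sz)`` — voxel centers, not corners
* displacement fields map exhale (fixed) points to inhale (moving)
  points: ``deformed_inhale(x) = inhale(x + u(x))``, u in mm
* HU values enter density arithmetic as ``HU + 1000`` clamped to >= 0;
  the clamp is applied inside arithmetic, never to stored data

On-disk formats are NIfTI-1 (``.nii``/``.nii.gz``) and MetaImage
(``.mha``/``.mhd``), read and written through SimpleITK.  SimpleITK arrays
come back in (z, y, x) order; this module transposes so the package only
ever sees (x, y, z).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import SimpleITK as sitk

__all__ = [
    "VolumeGrid",
    "ScalarVolume",
    "BinaryMask",
    "DisplacementField",
    "FormatError",
    "GeometryError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_displacement_field",
    "write_displacement_field",
    "resample_nearest",
    "resample_linear",
]

UnitTag = Literal["HU", "ventilation", "dimensionless"]


class FormatError(ValueError):
    """Unreadable file or unsupported image layout."""


class GeometryError(ValueError):
    """Grids do not match or do not overlap in physical space."""


@dataclass(frozen=True)
class VolumeGrid:
    """Axis-aligned voxel lattice: dimensions, spacing (mm) and origin (mm)."""

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.dims) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("dims, spacing, origin must be length-3")
        if any(int(d) < 1 for d in self.dims):
            raise ValueError(f"all dims must be >= 1, got {self.dims}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacings must be > 0, got {self.spacing}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers along one axis."""
        return self.origin[axis] + np.arange(self.dims[axis]) * self.spacing[axis]

    def coordinate_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (x, y, z) physical-coordinate arrays."""
        cx = self.axis_coords(0)[:, None, None]
        cy = self.axis_coords(1)[None, :, None]
        cz = self.axis_coords(2)[None, None, :]
        return cx, cy, cz

    def extent(self) -> tuple[tuple[float, float], ...]:
        """Physical (lo, hi) of voxel centers per axis."""
        return tuple(
            (self.origin[a], self.origin[a] + (self.dims[a] - 1) * self.spacing[a])
            for a in range(3)
        )

    def physical_to_index(self, coords_mm: Sequence[np.ndarray]) -> list[np.ndarray]:
        """Continuous index coordinates for physical-point arrays (per axis)."""
        return [
            (np.asarray(coords_mm[a], dtype=float) - self.origin[a]) / self.spacing[a]
            for a in range(3)
        ]

    def overlaps(self, other: "VolumeGrid") -> bool:
        for (lo_a, hi_a), (lo_b, hi_b) in zip(self.extent(), other.extent()):
            if hi_a < lo_b or hi_b < lo_a:
                return False
        return True


def _check_values(grid: VolumeGrid, values: np.ndarray, name: str) -> np.ndarray:
    values = np.asarray(values)
    if values.shape != grid.dims:
        raise ValueError(f"{name} shape {values.shape} does not match grid dims {grid.dims}")
    return values


@dataclass
class ScalarVolume:
    """A 3-D scalar image on a :class:`VolumeGrid`.

    ``valid`` marks voxels carrying meaningful values; resampling flags
    target voxels falling outside the source extent as invalid so that
    downstream masks can exclude them.  ``valid is None`` means all valid.
    """

    grid: VolumeGrid
    values: np.ndarray
    unit: UnitTag = "dimensionless"
    valid: np.ndarray | None = None

    def __post_init__(self):
        self.values = _check_values(self.grid, self.values, "values")
        if self.valid is not None:
            self.valid = _check_values(self.grid, self.valid, "valid").astype(bool)

    def valid_mask(self) -> np.ndarray:
        if self.valid is None:
            return np.ones(self.grid.dims, dtype=bool)
        return self.valid

    def density(self) -> np.ndarray:
        """HU + 1000 clamped to >= 0 (only meaningful for HU volumes)."""
        return np.maximum(np.asarray(self.values, dtype=float) + 1000.0, 0.0)

    def with_values(self, values: np.ndarray, unit: UnitTag | None = None) -> "ScalarVolume":
        return ScalarVolume(self.grid, values, unit or self.unit, self.valid)


@dataclass
class BinaryMask:
    """Boolean voxel mask sharing the grid of the volume it annotates."""

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = _check_values(self.grid, self.values, "values").astype(bool)

    @property
    def n_true(self) -> int:
        return int(self.values.sum())

    def volume_liters(self) -> float:
        return self.n_true * self.grid.voxel_volume_mm3 / 1.0e6


@dataclass
class DisplacementField:
    """Per-voxel displacement (mm) on the exhale/fixed grid.

    ``vectors`` has shape ``dims + (3,)``; component a is u_a in mm.
    Convention: ``deformed_inhale(x) = inhale(x + u(x))``.
    """

    grid: VolumeGrid
    vectors: np.ndarray

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape != self.grid.dims + (3,):
            raise ValueError(
                f"vectors shape {self.vectors.shape} != grid dims + (3,) = {self.grid.dims + (3,)}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement components must all be finite")


# ---------------------------------------------------------------------------
# I/O via SimpleITK
# ---------------------------------------------------------------------------

_SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _SUPPORTED_SUFFIXES):
        raise FormatError(f"unsupported file format: {path} (expected one of {_SUPPORTED_SUFFIXES})")


def _read_sitk(path: str | Path) -> sitk.Image:
    path = Path(path)
    _check_suffix(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    try:
        return sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover - sitk error text varies
        raise FormatError(f"unreadable image file {path}: {exc}") from exc


def _grid_from_sitk(img: sitk.Image) -> VolumeGrid:
    return VolumeGrid(
        dims=tuple(img.GetSize()),
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
    )


def read_volume(path: str | Path, unit: UnitTag = "dimensionless") -> ScalarVolume:
    """Read a 3-D scalar volume from NIfTI or MetaImage.

    Grid spacing/origin come from the header; values are unchanged.
    """
    img = _read_sitk(path)
    if img.GetDimension() != 3 or img.GetNumberOfComponentsPerPixel() != 1:
        raise FormatError(
            f"{path}: expected a 3-D scalar image, got dimension "
            f"{img.GetDimension()} with {img.GetNumberOfComponentsPerPixel()} components"
        )
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    return ScalarVolume(_grid_from_sitk(img), np.ascontiguousarray(arr.transpose(2, 1, 0)), unit)


def write_volume(vol: ScalarVolume, path: str | Path, dtype=np.float32) -> None:
    """Write a scalar volume; round-trips bit-compatibly for float32 payloads."""
    path = Path(path)
    _check_suffix(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    arr = np.asarray(vol.values, dtype=dtype).transpose(2, 1, 0)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr))
    img.SetSpacing(vol.grid.spacing)
    img.SetOrigin(vol.grid.origin)
    sitk.WriteImage(img, str(path))


def read_mask(path: str | Path) -> BinaryMask:
    vol = read_volume(path)
    return BinaryMask(vol.grid, vol.values > 0.5)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    write_volume(ScalarVolume(mask.grid, mask.values.astype(np.uint8)), path, dtype=np.uint8)


def read_displacement_field(path: str | Path) -> DisplacementField:
    """Read a 3-component vector volume (mm) as a displacement field."""
    img = _read_sitk(path)
    if img.GetDimension() != 3 or img.GetNumberOfComponentsPerPixel() != 3:
        raise FormatError(f"{path}: expected a 3-D 3-component vector image")
    arr = sitk.GetArrayFromImage(img)  # (z, y, x, 3)
    return DisplacementField(_grid_from_sitk(img), np.ascontiguousarray(arr.transpose(2, 1, 0, 3)))


def write_displacement_field(dvf: DisplacementField, path: str | Path) -> None:
    path = Path(path)
    _check_suffix(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    arr = np.asarray(dvf.vectors, dtype=np.float32).transpose(2, 1, 0, 3)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr), isVector=True)
    img.SetSpacing(dvf.grid.spacing)
    img.SetOrigin(dvf.grid.origin)
    sitk.WriteImage(img, str(path))


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def _target_index_coords(src: ScalarVolume, target: VolumeGrid):
    if not src.grid.overlaps(target):
        raise GeometryError("source and target grids have disjoint physical extents")
    phys = [c for c in np.meshgrid(*(target.axis_coords(a) for a in range(3)), indexing="ij")]
    idx = src.grid.physical_to_index(phys)
    inside = np.ones(target.dims, dtype=bool)
    for a in range(3):
        inside &= (idx[a] >= -0.5) & (idx[a] <= src.grid.dims[a] - 0.5)
    return idx, inside


def resample_nearest(src: ScalarVolume, target: VolumeGrid) -> ScalarVolume:
    """Nearest-neighbor resampling onto ``target``.

    Each target voxel takes the value of the physically nearest source
    voxel; target voxels outside the source extent are flagged invalid.
    """
    if target == src.grid:
        return ScalarVolume(src.grid, src.values.copy(), src.unit, src.valid)
    idx, inside = _target_index_coords(src, target)
    out = np.empty(target.dims, dtype=np.asarray(src.values).dtype)
    nearest = [
        np.clip(np.rint(idx[a]).astype(int), 0, src.grid.dims[a] - 1) for a in range(3)
    ]
    out[...] = np.asarray(src.values)[nearest[0], nearest[1], nearest[2]]
    valid = inside
    if src.valid is not None:
        valid = inside & src.valid[nearest[0], nearest[1], nearest[2]]
    return ScalarVolume(target, out, src.unit, valid)


def resample_linear(src: ScalarVolume, target: VolumeGrid) -> ScalarVolume:
    """Trilinear resampling onto ``target`` (exact for affine fields)."""
    from scipy.ndimage import map_coordinates

    if target == src.grid:
        return ScalarVolume(src.grid, src.values.copy(), src.unit, src.valid)
    idx, inside = _target_index_coords(src, target)
    coords = np.stack([np.clip(idx[a], 0, src.grid.dims[a] - 1) for a in range(3)])
    out = map_coordinates(
        np.asarray(src.values, dtype=float), coords, order=1, mode="nearest"
    )
    valid = inside
    if src.valid is not None:
        src_ok = map_coordinates(src.valid.astype(float), coords, order=1, mode="constant") > 0.999
        valid = inside & src_ok
    return ScalarVolume(target, out, src.unit, valid)
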