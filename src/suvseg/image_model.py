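"""Voxel-grid data model, world/index geometry and NIfTI-1 I/O.

The package operates on 3D scalar PET volumes in body-weight SUV units.  A
:class:`ScalarVolume` is a numpy array plus an explicit grid geometry: the
per-axis voxel edge length in millimetres and the world coordinate of the
*center* of voxel ``(0, 0, 0)``.  Axis order is ``(x, y, z)`` with ``z`` the
axial (slice) direction.

All regions of interest — the ellipsoidal lesion VOI, cubic reference ROIs
(parotid gland, spleen) and the single-slice circular liver ROI — are defined
in world millimetres and rasterized onto a volume's grid by the voxel-center
inclusion rule: a voxel belongs to a region iff its center lies inside the
region's analytic boundary (boundary inclusive).  This rule is deliberately
simple (no partial-volume fractions) so that geometric tests have exact,
enumerable answers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import nibabel as nib
import numpy as np

__all__ = [
    "ScalarVolume",
    "EllipsoidVOI",
    "BoxROI",
    "DiscROI",
    "Geometry",
    "VolumeFormatError",
    "GeometryError",
    "read_volume",
    "write_volume",
    "rasterize",
    "voxel_volume_ml",
]


class VolumeFormatError(ValueError):
    """Raised when a file or array does not describe a valid 3D SUV volume."""


class GeometryError(ValueError):
    """Raised when a region rasterizes to no voxels or does not fit the grid."""


@dataclass(frozen=True, eq=False)
class ScalarVolume:
    """A 3D scalar image of SUV values on a regular grid.

    Parameters
    ----------
    values
        3D array, axis order ``(x, y, z)``; finite, non-negative SUV.
    spacing
        Per-axis voxel edge lengths in mm; all positive.
    origin
        World coordinate (mm) of the center of voxel ``(0, 0, 0)``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise VolumeFormatError(f"expected a 3D array, got ndim={values.ndim}")
        if not np.all(np.isfinite(values)):
            raise VolumeFormatError("SUV values must be finite")
        if np.any(values < 0):
            raise VolumeFormatError("SUV values must be non-negative")
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(spacing) != 3 or len(origin) != 3:
            raise VolumeFormatError("spacing and origin must have 3 components")
        if any(s <= 0 for s in spacing):
            raise VolumeFormatError(f"spacing must be positive, got {spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in ml (spacings are mm; 1000 mm^3 = 1 ml)."""
        return float(np.prod(self.spacing)) / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        n = self.values.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)


@dataclass(frozen=True)
class EllipsoidVOI:
    """Axis-aligned ellipsoid volume of interest surrounding a lesion."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise GeometryError(f"semi_axes must be positive, got {self.semi_axes}")


@dataclass(frozen=True)
class BoxROI:
    """Axis-aligned box, e.g. the cubic 10 or 30 mm background reference ROI."""

    center: tuple[float, float, float]
    edge_lengths: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.edge_lengths):
            raise GeometryError(f"edge_lengths must be positive, got {self.edge_lengths}")

    @classmethod
    def cube(cls, center: tuple[float, float, float], edge: float) -> "BoxROI":
        return cls(center, (edge, edge, edge))


@dataclass(frozen=True)
class DiscROI:
    """Circular ROI in the axial plane, occupying exactly one slice.

    Mirrors the planar circular liver reference region: the disc is placed on
    the axial slice whose z voxel-center is nearest the disc center.
    """

    center: tuple[float, float, float]
    diameter: float

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise GeometryError(f"diameter must be positive, got {self.diameter}")


Geometry = Union[EllipsoidVOI, BoxROI, DiscROI]


def voxel_volume_ml(vol: ScalarVolume) -> float:
    """Volume of one voxel of ``vol`` in ml."""
    return vol.voxel_volume_ml


def rasterize(vol: ScalarVolume, geom: Geometry) -> np.ndarray:
    """Boolean mask of voxels whose centers lie inside ``geom``.

    Raises :class:`GeometryError` if the region contains no voxel center.
    """
    x = vol.axis_coords(0)[:, None, None]
    y = vol.axis_coords(1)[None, :, None]
    z = vol.axis_coords(2)[None, None, :]

    if isinstance(geom, EllipsoidVOI):
        cx, cy, cz = geom.center
        ax, ay, az = geom.semi_axes
        mask = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0
    elif isinstance(geom, BoxROI):
        cx, cy, cz = geom.center
        hx, hy, hz = (e / 2.0 for e in geom.edge_lengths)
        mask = (np.abs(x - cx) <= hx) & (np.abs(y - cy) <= hy) & (np.abs(z - cz) <= hz)
    elif isinstance(geom, DiscROI):
        cx, cy, cz = geom.center
        zc = vol.axis_coords(2)
        k = int(np.argmin(np.abs(zc - cz)))
        r = geom.diameter / 2.0
        in_plane = (x[:, :, 0] - cx) ** 2 + (y[:, :, 0] - cy) ** 2 <= r**2
        mask = np.zeros(vol.shape, dtype=bool)
        mask[:, :, k] = in_plane
    else:  # pragma: no cover - type narrowing
        raise TypeError(f"unsupported geometry type {type(geom).__name__}")

    mask = np.broadcast_to(mask, vol.shape).copy() if mask.shape != vol.shape else mask
    if not mask.any():
        raise GeometryError(f"{type(geom).__name__} contains no voxel center on this grid")
    return mask


def _affine(vol: ScalarVolume) -> np.ndarray:
    aff = np.diag(list(vol.spacing) + [1.0])
    aff[:3, 3] = vol.origin
    return aff


def write_volume(vol: ScalarVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 (.nii or .nii.gz); lossless for values."""
    path = Path(path)
    img = nib.Nifti1Image(vol.values, _affine(vol))
    img.header.set_data_dtype(vol.values.dtype)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_volume(path: str | Path) -> ScalarVolume:
    """Read a 3D NIfTI-1 volume written by :func:`write_volume`.

    Spacing is taken from the header zooms and the origin from the affine
    translation.  Non-3D images and non-positive spacings are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected 3D image, got ndim={data.ndim}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any((not math.isfinite(z)) or z <= 0 for z in zooms):
        raise VolumeFormatError(f"{path}: non-positive voxel spacing {zooms}")
    origin = tuple(float(t) for t in img.affine[:3, 3])
    return ScalarVolume(values=data, spacing=zooms, origin=origin)
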