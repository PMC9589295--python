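"""Core domain types and image I/O.

Volumes are 3D scalar fields on a regular grid with physical spacing.
Arrays are indexed ``(x, y, z)`` with ``z`` the superior-inferior axis; all
millimetre offsets (e.g. the pelvis crop) act on ``z``.  Units are carried as
a tag (``HU``, ``Gy``, ``unitless``, ``probability``) and voxel-wise
arithmetic across different units raises, which catches HU/Gy mix-ups early.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk

#: absolute tolerance (mm) for geometry comparisons — header floats are noisy
GEOMETRY_ATOL = 1e-6

VALID_UNITS = ("HU", "Gy", "unitless", "probability")


class UnitError(ValueError):
    """Arithmetic between volumes with incompatible unit tags."""


class GeometryError(ValueError):
    """Volumes do not share shape/spacing/origin."""


class StructureError(ValueError):
    """A required mask is missing, empty, or inconsistent."""


@dataclass(frozen=True)
class Geometry:
    """Shape, spacing (mm) and origin (mm) of a regular 3D grid."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.shape) != 3:
            raise GeometryError(f"expected 3D shape, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")

    def compatible(self, other: "Geometry") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=GEOMETRY_ATOL, rtol=0)
            and np.allclose(self.origin, other.origin, atol=GEOMETRY_ATOL, rtol=0)
        )

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def coordinate_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates (mm) of voxel centres along each axis."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )


def _check_compatible(a: Geometry, b: Geometry) -> None:
    if not a.compatible(b):
        raise GeometryError(f"incompatible geometries: {a} vs {b}")


@dataclass
class VolumeGrid:
    """3D scalar field on a physical grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar lattice, stored as float32/float64 (or bool for masks that are
        wrapped ad hoc; structure masks normally live in :class:`StructureSet`).
    spacing, origin : mm per axis.
    unit : one of ``HU``, ``Gy``, ``unitless``, ``probability``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    unit: str = "unitless"

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise GeometryError(f"expected 3D array, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")
        if self.unit not in VALID_UNITS:
            raise UnitError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if self.unit == "probability":
            v = self.values[np.isfinite(self.values)]
            if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
                raise UnitError("probability-tagged values must lie in [0, 1]")

    @property
    def geometry(self) -> Geometry:
        return Geometry(tuple(self.values.shape), self.spacing, self.origin)

    def like(self, values: np.ndarray, unit: str | None = None) -> "VolumeGrid":
        """New volume with the same geometry and (by default) unit."""
        return VolumeGrid(values, self.spacing, self.origin, unit or self.unit)

    def copy(self) -> "VolumeGrid":
        return self.like(self.values.copy())

    def check_same_unit(self, other: "VolumeGrid") -> None:
        if self.unit != other.unit:
            raise UnitError(f"unit mismatch: {self.unit} vs {other.unit}")

    def check_compatible(self, other) -> None:
        _check_compatible(self.geometry, other.geometry)


@dataclass
class StructureSet:
    """Named binary masks sharing one grid geometry."""

    geometry: Geometry
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def add(self, name: str, mask: np.ndarray) -> None:
        mask = np.asarray(mask, dtype=bool)
        if tuple(mask.shape) != self.geometry.shape:
            raise GeometryError(
                f"mask {name!r} shape {mask.shape} != geometry {self.geometry.shape}"
            )
        self.masks[name] = mask

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in self.masks:
            raise StructureError(f"missing structure {name!r}")
        return self.masks[name]

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self.masks]
        if missing:
            raise StructureError(f"missing structures: {missing}")

    def volume_cm3(self, name: str) -> float:
        return float(self[name].sum()) * self.geometry.voxel_volume_mm3 / 1000.0


@dataclass
class VectorField:
    """Per-voxel 3D displacement in mm, shape (nx, ny, nz, 3)."""

    displacement: np.ndarray
    geometry: Geometry

    def __post_init__(self):
        self.displacement = np.asarray(self.displacement, dtype=np.float64)
        if self.displacement.shape != self.geometry.shape + (3,):
            raise GeometryError(
                f"displacement shape {self.displacement.shape} does not match "
                f"geometry {self.geometry.shape} + (3,)"
            )

    @classmethod
    def zeros(cls, geometry: Geometry) -> "VectorField":
        return cls(np.zeros(geometry.shape + (3,)), geometry)

    @classmethod
    def constant(cls, geometry: Geometry, translation_mm) -> "VectorField":
        d = np.broadcast_to(
            np.asarray(translation_mm, dtype=float), geometry.shape + (3,)
        ).copy()
        return cls(d, geometry)

    def max_magnitude(self) -> float:
        return float(np.sqrt((self.displacement**2).sum(axis=-1)).max())


@dataclass
class PatientCase:
    """One patient's aligned volumes: MRI, CT, sCTs, doses and structures."""

    id: str
    mri: VolumeGrid
    ct: VolumeGrid
    structures: StructureSet
    scts: dict[str, VolumeGrid] = field(default_factory=dict)
    doses: dict[str, VolumeGrid] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        geo = self.mri.geometry
        for vol in [self.ct, *self.scts.values(), *self.doses.values()]:
            _check_compatible(geo, vol.geometry)
        _check_compatible(geo, self.structures.geometry)

    @property
    def geometry(self) -> Geometry:
        return self.mri.geometry


# ---------------------------------------------------------------------------
# SimpleITK interop

def to_sitk(vol: VolumeGrid) -> sitk.Image:
    """Convert to a SimpleITK image (which indexes arrays (z, y, x))."""
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.values.T))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    return img


def from_sitk(img: sitk.Image, unit: str = "unitless") -> VolumeGrid:
    arr = sitk.GetArrayFromImage(img).T
    return VolumeGrid(arr, tuple(img.GetSpacing()), tuple(img.GetOrigin()), unit)


# ---------------------------------------------------------------------------
# I/O

_KNOWN_EXT = (".nii", ".nii.gz", ".mha", ".mhd")


def read_volume(path: str | os.PathLike, unit: str = "unitless") -> VolumeGrid:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) volume.

    The unit tag is not stored by these formats; it is supplied by the caller
    (sidecar config or CLI flag).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    img = sitk.ReadImage(path)
    if img.GetDimension() != 3:
        raise GeometryError(f"expected a 3D image, got {img.GetDimension()}D: {path}")
    return from_sitk(img, unit)


def write_volume(vol: VolumeGrid, path: str | os.PathLike) -> None:
    """Write as NIfTI or MetaImage (by extension), float32 on disk."""
    path = os.fspath(path)
    parent = os.path.dirname(path) or "."
    if not os.path.isdir(parent):
        raise IOError(f"parent directory does not exist: {parent}")
    out = replace(vol)
    out.values = vol.values.astype(np.float32)
    sitk.WriteImage(to_sitk(out), path)


def write_mask(mask: np.ndarray, geometry: Geometry, path: str | os.PathLike) -> None:
    vol = VolumeGrid(np.asarray(mask, dtype=np.uint8).astype(np.float32),
                     geometry.spacing, geometry.origin, "unitless")
    write_volume(vol, path)


def resample_like(
    vol: VolumeGrid, reference: Geometry, mode: str = "linear",
    background: float = 0.0,
) -> VolumeGrid:
    """Resample onto ``reference`` geometry.

    ``mode='nearest'`` is required for binary masks (preserves binarity).
    """
    if mode not in ("linear", "nearest"):
        raise ValueError(f"mode must be 'linear' or 'nearest', got {mode!r}")
    Geometry(reference.shape, reference.spacing, reference.origin)  # validates
    if vol.geometry.compatible(reference):
        return vol.copy()
    interp = sitk.sitkLinear if mode == "linear" else sitk.sitkNearestNeighbor
    ref_img = sitk.Image(*reference.shape, sitk.sitkFloat64)
    ref_img.SetSpacing(reference.spacing)
    ref_img.SetOrigin(reference.origin)
    out = sitk.Resample(to_sitk(vol), ref_img, sitk.Transform(), interp,
                        background, sitk.sitkFloat64)
    return from_sitk(out, vol.unit)
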