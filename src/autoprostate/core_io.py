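"""Shared domain types and volumetric image I/O.

The central container is :class:`VoxelGrid`, a 3D scalar volume with a fixed
axis convention: axis 0 = x (transverse, left-right), axis 1 = y
(anterior-posterior), axis 2 = z (cranio-caudal, increasing toward the head).
Voxel centers sit at ``origin + index * spacing`` (mm). All physical
measurements in the package use this voxel-center convention.

NIfTI (.nii/.nii.gz) is the interchange format; DICOM series are readable
but never written. Masks are written as unsigned 8-bit NIfTI.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "VoxelGrid",
    "PatientRecord",
    "GeometryRecord",
    "FormatError",
    "MetadataError",
    "read_volume",
    "write_volume",
]


class FormatError(ValueError):
    """The file cannot be parsed under the named standard."""


class MetadataError(ValueError):
    """Required geometric metadata (spacing) is absent or invalid."""


@dataclass(frozen=True)
class VoxelGrid:
    """A 3D scalar volume with physical geometry.

    Parameters
    ----------
    data:
        3D array ``(nx, ny, nz)``; intensity, probability or label values.
    spacing:
        Voxel size ``(sx, sy, sz)`` in mm; all components positive.
    origin:
        Physical coordinate (mm) of the center of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"VoxelGrid data must be 3D, got ndim={data.ndim}")
        if any(n < 1 for n in data.shape):
            raise ValueError(f"all dims must be >= 1, got shape {data.shape}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing components must be > 0, got {spacing}")
        origin = tuple(float(o) for o in self.origin)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def with_data(self, data: np.ndarray) -> "VoxelGrid":
        """New grid sharing this grid's geometry."""
        return replace(self, data=np.asarray(data))

    def same_geometry(self, other: "VoxelGrid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Physical mm coordinates of (possibly fractional) voxel indices."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)


@dataclass(frozen=True)
class PatientRecord:
    """Clinical metadata attached to a case."""

    name: str
    hospital_number: str
    date_of_birth: _dt.date | None = None
    scan_date: _dt.date | None = None
    age: float | None = None
    psa: float | None = None  # ng/mL

    def __post_init__(self) -> None:
        if self.psa is not None and self.psa < 0:
            raise ValueError("psa must be >= 0")
        if self.age is not None and self.age < 0:
            raise ValueError("age must be >= 0")


@dataclass(frozen=True)
class GeometryRecord:
    """Bookkeeping to undo a resample and/or crop-or-pad step.

    ``crop_offsets`` holds the index of the output's first voxel in the
    source frame per axis (negative when the output was padded).
    ``resample_factor`` holds output/input size ratios.
    """

    original_shape: tuple[int, int, int]
    original_spacing: tuple[float, float, float]
    crop_offsets: tuple[int, int, int] = (0, 0, 0)
    resample_factor: tuple[float, float, float] = (1.0, 1.0, 1.0)
    original_origin: tuple[float, float, float] = (0.0, 0.0, 0.0)


# --------------------------------------------------------------------------
# File I/O
# --------------------------------------------------------------------------

def _affine_from_grid(grid: VoxelGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = grid.spacing
    aff[:3, 3] = grid.origin
    return aff


def read_volume(path: str | Path, format: str = "nifti") -> VoxelGrid:
    """Read a 3D volume, remapping to the package axis convention.

    Parameters
    ----------
    path:
        A NIfTI file, or a directory holding a DICOM series.
    format:
        ``"nifti"`` or ``"dicom-series"``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "nifti":
        return _read_nifti(path)
    if format == "dicom-series":
        return _read_dicom_series(path)
    raise ValueError(f"unknown format {format!r}")


def _read_nifti(path: Path) -> VoxelGrid:
    try:
        img = nib.load(str(path))
        # reorient to the closest RAS-like frame so x/y/z semantics hold
        img = nib.as_closest_canonical(img)
        data = np.asarray(img.dataobj)
    except Exception as exc:  # nibabel raises a zoo of types on bad input
        raise FormatError(f"cannot parse {path} as NIfTI: {exc}") from exc
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise MetadataError(f"{path}: invalid voxel spacing {zooms}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return VoxelGrid(data=data, spacing=tuple(float(z) for z in zooms), origin=origin)


def _read_dicom_series(path: Path) -> VoxelGrid:
    import SimpleITK as sitk

    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(str(path))
    if not files:
        raise FormatError(f"no DICOM series found under {path}")
    reader.SetFileNames(files)
    try:
        img = reader.Execute()
    except RuntimeError as exc:
        raise FormatError(f"cannot read DICOM series under {path}: {exc}") from exc
    # SimpleITK arrays are (z, y, x); transpose to (x, y, z)
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return VoxelGrid(
        data=data,
        spacing=tuple(float(s) for s in img.GetSpacing()),
        origin=tuple(float(o) for o in img.GetOrigin()),
    )


def write_volume(grid: VoxelGrid, path: str | Path) -> None:
    """Write a grid as NIfTI-1; label/mask data are stored as uint8."""
    path = Path(path)
    data = grid.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    elif np.issubdtype(data.dtype, np.integer) and data.size and 0 <= data.min() and data.max() <= 255:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, _affine_from_grid(grid))
    img.header.set_zooms(grid.spacing)
    try:
        nib.save(img, str(path))
    except OSError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc
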