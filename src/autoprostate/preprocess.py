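"""Geometric standardization and intensity normalization.

Both segmentation pathways share the same geometric standardization:
in-plane resampling to a common resolution (default 0.4018 mm), then
cropping or zero-padding to a common in-plane shape (320x320 for the zonal
pathway, 256x256 centred on the prostate for the lesion pathway). Each step
returns a :class:`~autoprostate.core_io.GeometryRecord` so probability maps
can be restored to the original frame exactly.

Intensity normalization differs by pathway: the zonal pathway whitens the
T2 volume (zero mean, unit variance over the whole volume), while the
lesion pathway divides T2 and computed high-b DWI intensities by the
interquartile mean of central-gland voxel intensities. ADC maps are never
normalized — they carry a quantitative measurement.

Co-registration of ADC/DWI onto T2 is a pluggable provider; the default
provider is the identity (inputs assumed co-registered). An external
registration tool can be wired in by supplying a provider that returns a
physical-space affine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .core_io import GeometryRecord, VoxelGrid

__all__ = [
    "PreprocessConfig",
    "NormalizationError",
    "RegistrationError",
    "resample_inplane",
    "crop_or_pad_inplane",
    "restore_inplane",
    "whiten",
    "interquartile_mean",
    "normalize_by_cg",
    "align_to_reference",
]


class NormalizationError(ValueError):
    pass


class RegistrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class PreprocessConfig:
    """Experimental-settings defaults for both pathways."""

    target_spacing: float = 0.4018  # mm, in-plane
    zone_crop_shape: tuple[int, int] = (320, 320)
    lesion_crop_shape: tuple[int, int] = (256, 256)
    crop_center_mode: str = "image-center"  # or "prostate-center"

    def __post_init__(self) -> None:
        if self.target_spacing <= 0:
            raise ValueError("target_spacing must be > 0")
        for shp in (self.zone_crop_shape, self.lesion_crop_shape):
            if any(v <= 0 or v % 2 for v in shp):
                raise ValueError(f"crop shapes must be positive and even, got {shp}")


def resample_inplane(
    grid: VoxelGrid, target: float, is_label: bool = False
) -> tuple[VoxelGrid, GeometryRecord]:
    """Resample x/y to ``target`` mm; z is untouched.

    Linear interpolation for intensities, nearest-neighbour for labels.
    A grid already at the target spacing is returned unchanged.
    """
    if target <= 0:
        raise ValueError(f"target spacing must be > 0, got {target}")
    sx, sy, sz = grid.spacing
    nx, ny, nz = grid.shape
    identity = GeometryRecord(
        original_shape=grid.shape,
        original_spacing=grid.spacing,
        original_origin=grid.origin,
    )
    if abs(sx - target) < 1e-9 and abs(sy - target) < 1e-9:
        return grid, identity

    new_nx = max(1, int(round(nx * sx / target)))
    new_ny = max(1, int(round(ny * sy / target)))
    out = resize(
        np.asarray(grid.data, dtype=float),
        (new_nx, new_ny, nz),
        order=0 if is_label else 1,
        preserve_range=True,
        anti_aliasing=False,
        mode="edge",
    )
    if is_label:
        out = out.astype(grid.data.dtype)
    record = GeometryRecord(
        original_shape=grid.shape,
        original_spacing=grid.spacing,
        original_origin=grid.origin,
        resample_factor=(new_nx / nx, new_ny / ny, 1.0),
    )
    new_grid = VoxelGrid(out, spacing=(target, target, sz), origin=grid.origin)
    return new_grid, record


def crop_or_pad_inplane(
    grid: VoxelGrid,
    shape: tuple[int, int],
    center: Optional[tuple[int, int]] = None,
) -> tuple[VoxelGrid, GeometryRecord]:
    """Crop/zero-pad x/y to ``shape`` around ``center`` (voxel coords).

    Regions outside the source are zero-filled; the record stores the
    per-axis offset of the output's first voxel in the source frame
    (negative when padded), which makes the operation exactly invertible.
    """
    w, h = shape
    if w <= 0 or h <= 0:
        raise ValueError(f"crop shape must be positive, got {shape}")
    nx, ny, nz = grid.shape
    cx, cy = (nx // 2, ny // 2) if center is None else (int(round(center[0])), int(round(center[1])))
    ox, oy = cx - w // 2, cy - h // 2

    out = np.zeros((w, h, nz), dtype=grid.data.dtype)
    src_x0, src_x1 = max(ox, 0), min(ox + w, nx)
    src_y0, src_y1 = max(oy, 0), min(oy + h, ny)
    if src_x0 < src_x1 and src_y0 < src_y1:
        out[src_x0 - ox : src_x1 - ox, src_y0 - oy : src_y1 - oy, :] = grid.data[
            src_x0:src_x1, src_y0:src_y1, :
        ]
    record = GeometryRecord(
        original_shape=grid.shape,
        original_spacing=grid.spacing,
        original_origin=grid.origin,
        crop_offsets=(ox, oy, 0),
    )
    new_origin = (
        grid.origin[0] + ox * grid.spacing[0],
        grid.origin[1] + oy * grid.spacing[1],
        grid.origin[2],
    )
    return VoxelGrid(out, spacing=grid.spacing, origin=new_origin), record


def restore_inplane(grid: VoxelGrid, record: GeometryRecord, is_label: bool = False) -> VoxelGrid:
    """Undo one resample or crop-or-pad step described by ``record``.

    Apply restores in reverse order of the forward operations.
    """
    if record.crop_offsets != (0, 0, 0) or (
        record.resample_factor == (1.0, 1.0, 1.0) and grid.shape != record.original_shape
    ):
        ox, oy, _ = record.crop_offsets
        nx, ny, nz = record.original_shape
        w, h = grid.shape[0], grid.shape[1]
        out = np.zeros(record.original_shape, dtype=grid.data.dtype)
        dst_x0, dst_x1 = max(ox, 0), min(ox + w, nx)
        dst_y0, dst_y1 = max(oy, 0), min(oy + h, ny)
        if dst_x0 < dst_x1 and dst_y0 < dst_y1:
            out[dst_x0:dst_x1, dst_y0:dst_y1, :] = grid.data[
                dst_x0 - ox : dst_x1 - ox, dst_y0 - oy : dst_y1 - oy, :
            ]
        return VoxelGrid(out, spacing=record.original_spacing, origin=record.original_origin)

    if record.resample_factor == (1.0, 1.0, 1.0):
        return VoxelGrid(grid.data, spacing=record.original_spacing, origin=record.original_origin)
    out = resize(
        np.asarray(grid.data, dtype=float),
        record.original_shape,
        order=0 if is_label else 1,
        preserve_range=True,
        anti_aliasing=False,
        mode="edge",
    )
    if is_label:
        out = out.astype(grid.data.dtype)
    return VoxelGrid(out, spacing=record.original_spacing, origin=record.original_origin)


def whiten(grid: VoxelGrid) -> VoxelGrid:
    """Zero-mean unit-variance normalization over the whole volume."""
    data = np.asarray(grid.data, dtype=float)
    if data.size < 2:
        raise NormalizationError("whitening needs > 1 voxel")
    std = data.std()
    if std == 0:
        raise NormalizationError("zero intensity variance; cannot whiten")
    return grid.with_data((data - data.mean()) / std)


def interquartile_mean(values) -> float:
    """Mean of the values v with Q1 <= v <= Q3 (quartiles by linear
    interpolation, bounds inclusive)."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 4:
        raise ValueError(f"interquartile mean needs >= 4 values, got {v.size}")
    q1, q3 = np.percentile(v, [25, 75])
    inner = v[(v >= q1) & (v <= q3)]
    return float(inner.mean())


def normalize_by_cg(grid: VoxelGrid, cg_mask: VoxelGrid) -> VoxelGrid:
    """Divide intensities by the interquartile mean of CG voxel values.

    Intended for T2 and computed high-b DWI only; ADC maps are quantitative
    and must bypass this step.
    """
    if not grid.same_geometry(cg_mask):
        raise ValueError("grid and CG mask geometry mismatch")
    mask = np.asarray(cg_mask.data) > 0
    if not mask.any():
        raise NormalizationError("CG mask is empty")
    iqm = interquartile_mean(np.asarray(grid.data, dtype=float)[mask])
    if iqm <= 0:
        raise NormalizationError(f"CG interquartile mean must be > 0, got {iqm}")
    return grid.with_data(np.asarray(grid.data, dtype=float) / iqm)


TransformProvider = Callable[[VoxelGrid, VoxelGrid], Optional[np.ndarray]]


def identity_provider(moving: VoxelGrid, fixed: VoxelGrid):  # noqa: ARG001
    """Default provider: inputs are assumed co-registered."""
    return None


def align_to_reference(
    moving: VoxelGrid,
    fixed: VoxelGrid,
    transform_provider: TransformProvider = identity_provider,
) -> VoxelGrid:
    """Resample ``moving`` onto ``fixed``'s grid.

    The provider returns a 4x4 physical-space affine mapping fixed-space
    points to moving-space points (the resampling transform), or ``None``
    for the identity. Provider exceptions surface as
    :class:`RegistrationError` with the original diagnostics attached.
    """
    try:
        transform = transform_provider(moving, fixed)
    except Exception as exc:
        raise RegistrationError(f"registration provider failed: {exc}") from exc

    if transform is None and moving.same_geometry(fixed):
        return moving
    T = np.eye(4) if transform is None else np.asarray(transform, dtype=float)
    if T.shape != (4, 4):
        raise RegistrationError(f"provider must return a 4x4 affine, got {T.shape}")

    idx = np.indices(fixed.shape, dtype=float)
    pts = idx.reshape(3, -1)
    phys = np.asarray(fixed.origin)[:, None] + pts * np.asarray(fixed.spacing)[:, None]
    phys_h = np.vstack([phys, np.ones((1, phys.shape[1]))])
    mapped = (T @ phys_h)[:3]
    mov_idx = (mapped - np.asarray(moving.origin)[:, None]) / np.asarray(moving.spacing)[:, None]
    out = ndimage.map_coordinates(
        np.asarray(moving.data, dtype=float), mov_idx, order=1, mode="constant", cval=0.0
    ).reshape(fixed.shape)
    return VoxelGrid(out, spacing=fixed.spacing, origin=fixed.origin)
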