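"""Derived clinical quantities for the report.

Prostate lengths are maximum extents of the whole-prostate mask (the union
of PZ and CG) per axis, in cm, under a voxel-footprint convention:
``(max_index - min_index + 1) * spacing``, so a single voxel has nonzero
length. Volumes multiply voxel counts by voxel volume. PSA density is
PSA (ng/mL) divided by whole-prostate volume (cm^3), reported in ng/mL^2.

Lesion centroids are voxel-coordinate means rounded to the nearest voxel.
The centroid region follows the thirds rule on the whole-prostate z-extent
split by physical length: the caudal-most third is the apex, the
cranial-most third the base, the remainder the midgland (z increases
cranially). Boundary centroids are assigned to the more central region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import VoxelGrid
from .postprocess import ComponentCandidate

__all__ = [
    "ProstateMeasurements",
    "LesionCandidate",
    "MeasurementError",
    "whole_prostate_mask",
    "prostate_lengths",
    "mask_volume",
    "psa_density",
    "centroid_region",
    "characterize_lesion",
    "rank_lesions",
]

PZ_LABEL, CG_LABEL = 1, 2


class MeasurementError(ValueError):
    pass


@dataclass(frozen=True)
class ProstateMeasurements:
    transverse_cm: float
    anterior_posterior_cm: float
    cranio_caudal_cm: float
    wp_volume_cm3: float
    pz_volume_cm3: float
    cg_volume_cm3: float
    psa_density: float | None  # ng/mL^2; None when PSA unavailable


@dataclass(frozen=True)
class LesionCandidate:
    """A fully characterized CSPCa lesion candidate."""

    mask: VoxelGrid
    probability: float  # calibrated, in [0, 1]
    volume_cm3: float
    centroid_voxel: tuple[int, int, int]
    centroid_slice: int  # 1-based from the most caudal slice, for display
    centroid_zone: str  # 'PZ' or 'CG'
    centroid_region: str  # 'base' | 'midgland' | 'apex'
    min_adc: float  # mm^2/s
    extracapsular: bool


def whole_prostate_mask(zones: VoxelGrid) -> VoxelGrid:
    """WP = union of the PZ and CG labels."""
    labels = np.asarray(zones.data)
    return zones.with_data(((labels == PZ_LABEL) | (labels == CG_LABEL)).astype(np.uint8))


def prostate_lengths(wp: VoxelGrid) -> tuple[float, float, float]:
    """Maximum extents per axis (transverse, AP, cranio-caudal) in cm."""
    mask = np.asarray(wp.data) > 0
    if not mask.any():
        raise MeasurementError("whole-prostate mask is empty")
    lengths = []
    for axis in range(3):
        proj = mask.any(axis=tuple(a for a in range(3) if a != axis))
        idx = np.flatnonzero(proj)
        lengths.append((idx[-1] - idx[0] + 1) * wp.spacing[axis] / 10.0)
    return tuple(lengths)  # type: ignore[return-value]


def mask_volume(mask: VoxelGrid) -> float:
    """Voxel count times voxel volume, in cm^3."""
    return float((np.asarray(mask.data) > 0).sum() * mask.voxel_volume_mm3 / 1000.0)


def psa_density(psa: float, wp_volume_cm3: float) -> float:
    if wp_volume_cm3 <= 0:
        raise MeasurementError("whole-prostate volume must be > 0 for PSA density")
    return psa / wp_volume_cm3


def centroid_region(centroid_z: int, wp: VoxelGrid) -> str:
    """Thirds rule on the WP z-extent (z increases cranially)."""
    mask = np.asarray(wp.data) > 0
    if not mask.any():
        raise MeasurementError("whole-prostate mask is empty")
    zs = np.flatnonzero(mask.any(axis=(0, 1)))
    z_min, z_max = int(zs[0]), int(zs[-1])
    if not (z_min <= centroid_z <= z_max):
        raise MeasurementError(f"centroid z={centroid_z} outside WP extent [{z_min}, {z_max}]")
    # split by physical length; boundaries go to the more central region
    extent = z_max - z_min + 1
    pos = (centroid_z - z_min + 0.5) / extent  # fractional position, (0, 1)
    if pos < 1.0 / 3.0:
        return "apex"  # caudal-most third
    if pos > 2.0 / 3.0:
        return "base"  # cranial-most third
    return "midgland"


def characterize_lesion(
    component: ComponentCandidate,
    zones: VoxelGrid,
    wp: VoxelGrid,
    adc: VoxelGrid,
) -> LesionCandidate:
    """Derive all reported per-lesion characteristics."""
    mask = np.asarray(component.mask.data) > 0
    if not mask.any():
        raise ValueError("empty lesion component")
    for other in (zones, wp, adc):
        if not component.mask.same_geometry(other):
            raise ValueError("lesion/zone/ADC geometry mismatch")

    coords = np.argwhere(mask)
    centroid = tuple(int(round(v)) for v in coords.mean(axis=0))
    zone_label = int(np.asarray(zones.data)[centroid])
    if zone_label not in (PZ_LABEL, CG_LABEL):
        # C-shaped PZ can place the rounded centroid on background; fall
        # back to the nearest in-prostate zone label by physical distance
        zl = np.asarray(zones.data)
        in_prostate = np.argwhere((zl == PZ_LABEL) | (zl == CG_LABEL))
        if in_prostate.size == 0:
            raise ValueError("zonal map contains no prostate voxels")
        d = ((in_prostate - np.asarray(centroid)) * np.asarray(zones.spacing)) ** 2
        nearest = in_prostate[np.argmin(d.sum(axis=1))]
        zone_label = int(zl[tuple(nearest)])
    wp_mask = np.asarray(wp.data) > 0
    return LesionCandidate(
        mask=component.mask,
        probability=component.score,
        volume_cm3=mask_volume(component.mask),
        centroid_voxel=centroid,
        centroid_slice=centroid[2] + 1,  # display is 1-based from the caudal end
        centroid_zone="PZ" if zone_label == PZ_LABEL else "CG",
        centroid_region=centroid_region(centroid[2], wp),
        min_adc=float(np.asarray(adc.data, dtype=float)[mask].min()),
        extracapsular=bool((mask & ~wp_mask).any()),
    )


def rank_lesions(candidates: list[LesionCandidate]) -> list[LesionCandidate]:
    """Stable sort, descending probability; ties keep extraction order."""
    return sorted(candidates, key=lambda c: -c.probability)
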