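"""Synthetic prostate bpMRI phantoms with exact ground truth.

A phantom is a pair of nested ellipsoids — whole prostate (WP) and central
gland (CG), with the peripheral zone (PZ) as their difference — plus
ellipsoidal lesions with depressed ADC, embedded in a 3D grid. Multi-b DWI
is generated from the monoexponential signal model
``s(b) = s0 * exp(-b * ADC)`` with additive zero-mean Gaussian noise
(clipped at 0). Analytic volumes ``(4/3) * pi * a * b * c`` and diameters
are recorded so every downstream measurement can be checked against a
closed form.

Every draw is seeded; the same spec and seed reproduce a bit-identical
case. A voxel belongs to an ellipsoid iff its *center* satisfies the
ellipsoid inequality, matching the voxel-center convention in
:mod:`autoprostate.core_io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_io import PatientRecord, VoxelGrid

__all__ = [
    "LesionSpec",
    "PhantomSpec",
    "PhantomCase",
    "PhantomSpecError",
    "generate_phantom",
    "perturb_mask",
]


class PhantomSpecError(ValueError):
    """The phantom spec violates a geometric or signal-model invariant."""


@dataclass(frozen=True)
class LesionSpec:
    """One ellipsoidal lesion.

    ``center_mm`` is the offset of the lesion center from the prostate
    center, in mm.
    """

    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    adc: float = 0.8e-3  # mm^2/s; must undercut the surrounding tissue
    is_cspca: bool = True


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (128, 128, 28)
    spacing: tuple[float, float, float] = (0.4018, 0.4018, 2.0)
    wp_semi_axes: tuple[float, float, float] = (20.0, 15.0, 25.0)  # mm
    cg_semi_axes: tuple[float, float, float] = (12.0, 9.0, 15.0)  # mm
    lesions: tuple[LesionSpec, ...] = ()
    tissue_adc: dict = field(
        default_factory=lambda: {"pz": 1.6e-3, "cg": 1.3e-3, "background": 2.0e-3}
    )
    tissue_t2: dict = field(
        default_factory=lambda: {"pz": 600.0, "cg": 400.0, "background": 150.0}
    )
    dwi_s0: dict = field(
        default_factory=lambda: {"pz": 500.0, "cg": 400.0, "background": 100.0}
    )
    b_values: tuple[float, ...] = (0.0, 150.0, 500.0, 1000.0)
    noise_sigma: float = 0.0  # DWI noise, signal-intensity units
    t2_noise_sigma: float = 20.0
    psa: float = 10.0  # ng/mL
    seed: int = 0

    def validate(self) -> None:
        if any(c >= w for c, w in zip(self.cg_semi_axes, self.wp_semi_axes)):
            raise PhantomSpecError("CG ellipsoid must lie strictly inside WP")
        bvals = sorted(set(self.b_values))
        if len(bvals) < 2 or bvals[0] >= 100:
            raise PhantomSpecError("need >= 2 distinct b-values including one < 100")
        tissue_floor = min(self.tissue_adc["pz"], self.tissue_adc["cg"])
        for les in self.lesions:
            if les.adc >= tissue_floor:
                raise PhantomSpecError(
                    f"lesion ADC {les.adc} must be below tissue ADC {tissue_floor}"
                )


@dataclass(frozen=True)
class PhantomCase:
    t2: VoxelGrid
    dwi: dict  # b-value -> VoxelGrid
    adc_gt: VoxelGrid  # mm^2/s
    s0_gt: VoxelGrid
    zones_gt: VoxelGrid  # labels {0 bg, 1 PZ, 2 CG}
    lesions_gt: list  # [(mask VoxelGrid, is_cspca)]
    patient: PatientRecord
    analytic: dict  # wp/cg/pz volumes cm^3, lengths cm
    spec: PhantomSpec


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    center_mm: np.ndarray,
    semi_axes_mm: tuple[float, float, float],
) -> np.ndarray:
    coords = [np.arange(n) * s for n, s in zip(shape, spacing)]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    a, b, c = semi_axes_mm
    return (
        ((xx - center_mm[0]) / a) ** 2
        + ((yy - center_mm[1]) / b) ** 2
        + ((zz - center_mm[2]) / c) ** 2
    ) <= 1.0


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Rasterize a phantom case; deterministic given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape, spacing = spec.grid_shape, spec.spacing
    center = (np.array(shape) - 1) / 2.0 * np.array(spacing)  # grid center, mm

    wp = _ellipsoid_mask(shape, spacing, center, spec.wp_semi_axes)
    if not wp.any():
        raise PhantomSpecError("WP ellipsoid rasterizes to an empty mask")
    cg = _ellipsoid_mask(shape, spacing, center, spec.cg_semi_axes)
    cg &= wp
    pz = wp & ~cg
    zones = np.zeros(shape, dtype=np.uint8)
    zones[pz] = 1
    zones[cg] = 2

    adc = np.full(shape, spec.tissue_adc["background"], dtype=float)
    adc[pz] = spec.tissue_adc["pz"]
    adc[cg] = spec.tissue_adc["cg"]
    t2 = np.full(shape, spec.tissue_t2["background"], dtype=float)
    t2[pz] = spec.tissue_t2["pz"]
    t2[cg] = spec.tissue_t2["cg"]
    s0 = np.full(shape, spec.dwi_s0["background"], dtype=float)
    s0[pz] = spec.dwi_s0["pz"]
    s0[cg] = spec.dwi_s0["cg"]

    lesions_gt = []
    for les in spec.lesions:
        mask = _ellipsoid_mask(
            shape, spacing, center + np.asarray(les.center_mm), les.semi_axes_mm
        )
        if not mask.any():
            raise PhantomSpecError(f"lesion at {les.center_mm} rasterizes empty")
        adc[mask] = les.adc
        t2[mask] = 0.7 * t2[mask]  # mildly hypointense on T2, like real CSPCa
        geom = VoxelGrid(mask.astype(np.uint8), spacing=spacing)
        lesions_gt.append((geom, les.is_cspca))

    if spec.t2_noise_sigma > 0:
        t2 = np.clip(t2 + rng.normal(0.0, spec.t2_noise_sigma, shape), 0.0, None)

    dwi = {}
    for b in spec.b_values:
        sig = s0 * np.exp(-b * adc)
        if spec.noise_sigma > 0:
            sig = np.clip(sig + rng.normal(0.0, spec.noise_sigma, shape), 0.0, None)
        dwi[float(b)] = VoxelGrid(sig, spacing=spacing)

    a, b_, c = spec.wp_semi_axes
    ac, bc_, cc = spec.cg_semi_axes
    wp_vol = 4.0 / 3.0 * np.pi * a * b_ * c / 1000.0  # cm^3
    cg_vol = 4.0 / 3.0 * np.pi * ac * bc_ * cc / 1000.0
    analytic = {
        "wp_volume_cm3": wp_vol,
        "cg_volume_cm3": cg_vol,
        "pz_volume_cm3": wp_vol - cg_vol,
        "lengths_cm": (2 * a / 10.0, 2 * b_ / 10.0, 2 * c / 10.0),
        "lesion_volumes_cm3": [
            4.0 / 3.0 * np.pi * np.prod(l.semi_axes_mm) / 1000.0 for l in spec.lesions
        ],
    }
    patient = PatientRecord(
        name=f"Phantom {spec.seed}",
        hospital_number=f"PH{spec.seed:06d}",
        age=65.0,
        psa=spec.psa,
    )
    return PhantomCase(
        t2=VoxelGrid(t2, spacing=spacing),
        dwi=dwi,
        adc_gt=VoxelGrid(adc, spacing=spacing),
        s0_gt=VoxelGrid(s0, spacing=spacing),
        zones_gt=VoxelGrid(zones, spacing=spacing),
        lesions_gt=lesions_gt,
        patient=patient,
        analytic=analytic,
        spec=spec,
    )


def perturb_mask(mask: VoxelGrid, dice_target: float, seed: int) -> VoxelGrid:
    """Degrade a binary mask to a prescribed Dice against the original.

    Removes ``r = round(n * (1 - dice_target))`` voxels from the mask
    boundary and adds the same number just outside it, so the output keeps
    the input's size and its Dice with the input is ``1 - r/n`` — within
    rounding of ``dice_target``. Boundary voxels are chosen
    nearest-the-surface first with seeded random tie-breaking, which keeps
    the perturbed mask a plausible contour rather than salt-and-pepper.
    """
    if not (0.0 < dice_target <= 1.0):
        raise ValueError(f"dice_target must be in (0, 1], got {dice_target}")
    m = np.asarray(mask.data) > 0
    n = int(m.sum())
    if n == 0:
        raise ValueError("mask is empty")
    r = int(round(n * (1.0 - dice_target)))
    if r == 0:
        return mask.with_data(m.astype(np.uint8))

    rng = np.random.default_rng(seed)
    # rank inside voxels by depth (shallowest first), outside by proximity
    inside_depth = ndimage.distance_transform_edt(m, sampling=mask.spacing)
    outside_dist = ndimage.distance_transform_edt(~m, sampling=mask.spacing)

    inner_idx = np.flatnonzero(m.ravel())
    inner_key = inside_depth.ravel()[inner_idx] + rng.uniform(0, 1e-3, inner_idx.size)
    remove = inner_idx[np.argsort(inner_key)[:r]]

    outer_idx = np.flatnonzero(~m.ravel())
    outer_key = outside_dist.ravel()[outer_idx] + rng.uniform(0, 1e-3, outer_idx.size)
    add = outer_idx[np.argsort(outer_key)[:r]]

    out = m.ravel().copy()
    out[remove] = False
    out[add] = True
    return mask.with_data(out.reshape(m.shape).astype(np.uint8))
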