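"""End-to-end case processing: zonal pathway, lesion pathway, report.

The flow mirrors the clinical framework. The zonal pathway resamples T2 to
a common in-plane resolution, crops/pads to 320x320, whitens, predicts
background/PZ/CG probabilities slice-wise, restores them to the original
frame and takes a per-voxel argmax. The lesion pathway builds the
computed high b-value image (bc = 2000 s/mm^2 by default), standardizes
T2 / ADC / computed DWI / zone probability channels to 256x256 centred on
the prostate (whole-prostate centroid from the zonal output), normalizes
T2 and computed DWI by the CG interquartile mean (ADC and probability
channels pass through unchanged), predicts a CSPCa probability volume,
restores it, calibrates it, and extracts thresholded, size-filtered
candidates. Measurements and the structured report close the loop.

Backends are either ready :class:`~autoprostate.seg_backend.SlicePredictor`
objects or factories ``factory(transform) -> predictor``, where
``transform(grid, is_label=False)`` maps a native-frame volume into the
pathway's preprocessed frame — this is how the ground-truth oracle
backends are instantiated at the correct geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .core_io import PatientRecord, VoxelGrid
from .dwi_model import compute_high_b_from_adc, fit_monoexp_volume
from .measurements import (
    LesionCandidate,
    ProstateMeasurements,
    characterize_lesion,
    mask_volume,
    prostate_lengths,
    psa_density,
    rank_lesions,
    whole_prostate_mask,
)
from .phantom import PhantomCase, PhantomSpec, LesionSpec, generate_phantom
from .postprocess import (
    Calibrator,
    ComponentCandidate,
    PostprocessConfig,
    apply_calibrator,
    extract_candidates,
    zones_argmax,
)
from .preprocess import (
    PreprocessConfig,
    crop_or_pad_inplane,
    normalize_by_cg,
    resample_inplane,
    restore_inplane,
    whiten,
)
from .report import ReportDocument, build_report
from .seg_backend import (
    BackendConfig,
    OracleLesionPredictor,
    OracleZonePredictor,
    predict_volume,
)

__all__ = [
    "PipelineConfig",
    "CaseResult",
    "run_case",
    "run_phantom_case",
    "make_phantom_cohort",
]


@dataclass(frozen=True)
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)
    backend: BackendConfig = field(default_factory=BackendConfig)
    bc: float = 2000.0  # s/mm^2, computed high b-value
    calibrator: Optional[Calibrator] = None  # None -> identity
    use_supplied_adc: bool = True  # extrapolate from supplied ADC when given


@dataclass(frozen=True)
class CaseResult:
    zones: VoxelGrid  # label map {0, 1 PZ, 2 CG} in the native frame
    zone_probs: dict  # class name -> probability VoxelGrid, native frame
    wp: VoxelGrid
    adc_map: VoxelGrid
    computed_high_b: VoxelGrid
    lesion_prob_raw: VoxelGrid
    lesion_prob_calibrated: VoxelGrid
    candidates: list  # ComponentCandidate, extraction order
    lesions: list  # LesionCandidate, descending probability
    measurements: ProstateMeasurements
    report: ReportDocument


def _resolve_backend(backend, transform):
    if hasattr(backend, "predict"):
        return backend
    if callable(backend):
        return backend(transform)
    raise TypeError(f"backend must be a SlicePredictor or factory, got {type(backend)!r}")


def run_case(
    t2: VoxelGrid,
    dwi: dict,
    patient: PatientRecord,
    zone_backend,
    lesion_backend,
    config: PipelineConfig = PipelineConfig(),
    adc: Optional[VoxelGrid] = None,
    seed: int = 0,
) -> CaseResult:
    """Process one case end to end."""
    pre = config.preprocess

    # ---- zonal pathway -------------------------------------------------
    t2_rs, rec_rs = resample_inplane(t2, pre.target_spacing)
    t2_crop, rec_crop = crop_or_pad_inplane(t2_rs, pre.zone_crop_shape)

    def zone_transform(grid: VoxelGrid, is_label: bool = False) -> VoxelGrid:
        g, _ = resample_inplane(grid, pre.target_spacing, is_label=is_label)
        g, _ = crop_or_pad_inplane(g, pre.zone_crop_shape)
        return g

    zone_predictor = _resolve_backend(zone_backend, zone_transform)
    zone_probs_pre = predict_volume(
        zone_predictor, [whiten(t2_crop)], config.backend, seed=seed
    )
    zone_probs = {}
    for name, prob in zip(zone_predictor.classes, zone_probs_pre):
        restored = restore_inplane(prob, rec_crop)
        zone_probs[name] = restore_inplane(restored, rec_rs)
    zones = zones_argmax(zone_probs)
    wp = whole_prostate_mask(zones)

    # ---- lesion pathway ------------------------------------------------
    if adc is not None and config.use_supplied_adc:
        adc_map = adc
        b_low = min(float(b) for b in dwi)
        cb = compute_high_b_from_adc(dwi[b_low], b_low, adc_map, config.bc)
    else:
        s0_map, adc_map = fit_monoexp_volume(dwi)
        cb = s0_map.with_data(
            np.asarray(s0_map.data) * np.exp(-config.bc * np.asarray(adc_map.data))
        )

    wp_vox = np.argwhere(np.asarray(wp.data) > 0)
    if wp_vox.size == 0:
        raise ValueError("zonal pathway produced an empty prostate; cannot centre crop")
    centroid_native = wp_vox.mean(axis=0)
    # centre in the resampled frame: native index scaled by spacing ratio
    scale = np.asarray(t2.spacing[:2]) / pre.target_spacing
    if abs(t2.spacing[0] - pre.target_spacing) < 1e-9 and abs(t2.spacing[1] - pre.target_spacing) < 1e-9:
        scale = np.ones(2)
    center = (centroid_native[0] * scale[0], centroid_native[1] * scale[1])

    def lesion_transform(grid: VoxelGrid, is_label: bool = False) -> VoxelGrid:
        g, _ = resample_inplane(grid, pre.target_spacing, is_label=is_label)
        g, _ = crop_or_pad_inplane(g, pre.lesion_crop_shape, center=center)
        return g

    zones_lesion_frame = lesion_transform(zones, is_label=True)
    cg_mask = zones_lesion_frame.with_data(
        (np.asarray(zones_lesion_frame.data) == 2).astype(np.uint8)
    )

    channels = []
    records = None
    for grid, normalize in (
        (t2, True),
        (adc_map, False),  # quantitative: never normalized
        (cb, True),
        (zone_probs["PZ"], False),
        (zone_probs["CG"], False),
    ):
        g_rs, r_rs = resample_inplane(grid, pre.target_spacing)
        g_crop, r_crop = crop_or_pad_inplane(g_rs, pre.lesion_crop_shape, center=center)
        if normalize:
            g_crop = normalize_by_cg(g_crop, cg_mask)
        channels.append(g_crop)
        records = (r_rs, r_crop)

    lesion_predictor = _resolve_backend(lesion_backend, lesion_transform)
    lesion_prob_pre = predict_volume(lesion_predictor, channels, config.backend, seed=seed + 1)[0]
    r_rs, r_crop = records
    lesion_prob = restore_inplane(restore_inplane(lesion_prob_pre, r_crop), r_rs)

    calibrator = config.calibrator or Calibrator.identity()
    calibrated = apply_calibrator(calibrator, lesion_prob)
    candidates = extract_candidates(calibrated, config.postprocess)
    lesions = rank_lesions(
        [characterize_lesion(c, zones, wp, adc_map) for c in candidates]
    )

    # ---- measurements and report --------------------------------------
    wp_volume = mask_volume(wp)
    pz_volume = mask_volume(zones.with_data((np.asarray(zones.data) == 1).astype(np.uint8)))
    cg_volume = mask_volume(zones.with_data((np.asarray(zones.data) == 2).astype(np.uint8)))
    lengths = prostate_lengths(wp)
    psad = None if patient.psa is None else psa_density(patient.psa, wp_volume)
    measurements = ProstateMeasurements(
        transverse_cm=lengths[0],
        anterior_posterior_cm=lengths[1],
        cranio_caudal_cm=lengths[2],
        wp_volume_cm3=wp_volume,
        pz_volume_cm3=pz_volume,
        cg_volume_cm3=cg_volume,
        psa_density=psad,
    )
    report = build_report(patient, measurements, lesions)
    return CaseResult(
        zones=zones,
        zone_probs=zone_probs,
        wp=wp,
        adc_map=adc_map,
        computed_high_b=cb,
        lesion_prob_raw=lesion_prob,
        lesion_prob_calibrated=calibrated,
        candidates=candidates,
        lesions=lesions,
        measurements=measurements,
        report=report,
    )


def run_phantom_case(
    case: PhantomCase,
    config: PipelineConfig = PipelineConfig(),
    dice_target: float = 1.0,
    seed: int = 0,
) -> CaseResult:
    """Run the full pipeline on a phantom with ground-truth oracle backends.

    The oracle predictors are built in each pathway's preprocessed frame
    via the factory mechanism, optionally degraded to ``dice_target``.
    """

    def zone_factory(transform):
        zones_pre = transform(case.zones_gt, is_label=True)
        return OracleZonePredictor(zones_pre, dice_target=dice_target, seed=seed)

    def lesion_factory(transform):
        if not case.lesions_gt:
            return OracleLesionPredictor.empty_like(transform(case.t2))
        masks = [(transform(m, is_label=True), is_cs) for m, is_cs in case.lesions_gt]
        return OracleLesionPredictor(masks, dice_target=dice_target, seed=seed + 1)

    return run_case(
        case.t2,
        case.dwi,
        case.patient,
        zone_backend=zone_factory,
        lesion_backend=lesion_factory,
        config=config,
        adc=None,
        seed=seed,
    )


def make_phantom_cohort(
    n_cases: int,
    seed: int = 0,
    negative_fraction: float = 0.3,
    noise_sigma: float = 0.0,
) -> list[PhantomCase]:
    """A seeded cohort of varied phantoms for cohort-level evaluation.

    Roughly ``negative_fraction`` of cases are biopsy-negative (no
    lesions); positive cases carry 1-3 lesions, each clinically
    significant with probability 0.7. Gland semi-axes are jittered so no
    two cases share a geometry.
    """
    rng = np.random.default_rng(seed)
    specs: list[PhantomSpec] = []
    for i in range(n_cases):
        wp = tuple(rng.uniform(0.85, 1.1) * np.array([20.0, 15.0, 20.0]))
        cg = tuple(rng.uniform(0.5, 0.62) * np.array(wp))
        lesions = []
        if rng.uniform() >= negative_fraction:
            for _ in range(rng.integers(1, 4)):
                semi = tuple(rng.uniform(3.0, 5.5, size=3))
                # keep the lesion inside the gland: offset bounded by the
                # per-axis room left after the lesion's own extent
                room = 0.6 * (np.array(wp) - np.array(semi))
                center = tuple(rng.uniform(-1, 1, size=3) * room)
                is_cspca = bool(rng.uniform() < 0.7)
                lesions.append(
                    LesionSpec(
                        center_mm=center,
                        semi_axes_mm=semi,
                        adc=0.8e-3 if is_cspca else 1.05e-3,
                        is_cspca=is_cspca,
                    )
                )
        specs.append(
            PhantomSpec(
                wp_semi_axes=wp,
                cg_semi_axes=cg,
                lesions=tuple(lesions),
                noise_sigma=noise_sigma,
                psa=float(rng.uniform(4.0, 20.0)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    # cohort-level metrics need every stratum populated: guarantee at least
    # one biopsy-negative case and at least one nCSPCa lesion
    if n_cases >= 3:
        if all(s.lesions for s in specs):
            specs[-1] = PhantomSpec(
                **{**specs[-1].__dict__, "lesions": ()}
            )
        for want_cspca, adc in ((False, 1.05e-3), (True, 0.8e-3)):
            if any(l.is_cspca == want_cspca for s in specs for l in s.lesions):
                continue
            for i in range(n_cases - 1, -1, -1):
                if specs[i].lesions:
                    flipped = list(specs[i].lesions)
                    flipped[-1] = LesionSpec(
                        center_mm=flipped[-1].center_mm,
                        semi_axes_mm=flipped[-1].semi_axes_mm,
                        adc=adc,
                        is_cspca=want_cspca,
                    )
                    specs[i] = PhantomSpec(**{**specs[i].__dict__, "lesions": tuple(flipped)})
                    break
    return [generate_phantom(s) for s in specs]
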