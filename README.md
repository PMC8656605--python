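# autoprostate

Automated assessment of biparametric prostate MRI (bpMRI): zonal
segmentation post-processing, computed high b-value diffusion imaging,
calibrated clinically-significant prostate cancer (CSPCa) lesion
candidates, derived clinical measurements, and a structured case report —
plus the lesion-level evaluation and paired-statistics suite needed to
benchmark the pipeline against a human reader.

## Who this is for

Researchers building or validating prostate-MRI computer-aided detection
systems. The deep segmentation networks themselves are deliberately **not**
part of this package: any slice-wise predictor can be plugged in behind a
small contract, and a ground-truth *oracle* backend (optionally degraded to
a target Dice) makes every downstream stage testable on synthetic phantoms
with exact analytic ground truth — no patient data or trained weights
required.

## What it computes

**Zonal pathway.** T2-weighted volumes are resampled to a common in-plane
resolution (0.4018 mm), cropped/padded to 320×320, whitened (zero mean,
unit variance), segmented slice-wise into background / peripheral zone
(PZ) / central gland (CG) probabilities, restored to the native frame and
converted to labels by per-voxel argmax.

**Computed high b-value DWI.** The diffusion signal is modeled per voxel
as

    s(b) = s(0) · exp(−b · ADC)

Non-linear least squares over the acquired low-b images yields estimates
s\*(0) and ADC\*, from which a high b-value image is extrapolated:

    s(b_c) = s*(0) · exp(−b_c · ADC*),   b_c = 2000 s/mm²

**Lesion pathway.** T2, ADC, computed b2000, and the PZ/CG probability
maps are standardized to 256×256 centred on the prostate; T2 and computed
DWI are normalized by the interquartile mean of CG intensities (ADC is
quantitative and passes through untouched). The backend's CSPCa
probability volume is calibrated with isotonic regression, thresholded at
a cut-off C = 4.5 %, and connected components smaller than 40 mm³
(20 % of the 200 mm³ guideline minimum for significant lesions) are
removed.

**Report.** Each case yields prostate lengths (maximum extents, cm),
PZ/CG/whole-prostate volumes (voxel count × voxel volume, cm³), PSA
density (PSA / volume, ng/mL²), and per-lesion characteristics (volume,
centroid slice/zone/region by the thirds rule, minimum ADC,
extra-capsular flag), rendered as canonical JSON and static HTML.

**Evaluation.** Dice (volume-wise and on contoured slices), absolute
percentage error, ellipsoid-formula volume, lesion-level matching with
sensitivity / specificity / precision / false positives per
biopsy-negative patient, ROC and PR AUC, and paired comparisons:
Wilcoxon signed-rank, DeLong's paired-AUC test, exact McNemar, and a
generalized-score test on paired precisions.

## Worked example

```python
import autoprostate as ap

case = ap.generate_phantom(ap.PhantomSpec(
    lesions=(ap.LesionSpec(center_mm=(4, 2, 3), semi_axes_mm=(5, 4, 4)),),
    psa=10.5, seed=7))
result = ap.run_phantom_case(case, seed=1)

m = result.measurements
print(f"volume {m.wp_volume_cm3:.1f} cm3 (analytic {case.analytic['wp_volume_cm3']:.1f})")
print(f"PSAd {m.psa_density:.3f}")
print(result.report.findings_summary)
```

prints

```
volume 31.4 cm3 (analytic 31.4)
PSAd 0.335
1 clinically significant lesion candidate(s) identified: LESION 1 in the
CG at the midgland (slice 16) with probability of CSPCa 78%, volume
0.3 cm³, minimum ADC 8.00e-04 mm²/s. Prostate volume 31.4 cm³, PSA
density 0.335 ng/mL².
```

The phantom's nested-ellipsoid gland has analytic volume
(4/3)π·a·b·c = 31.4 cm³; the voxel-counting measurement agrees to well
under a percent at this resolution. The single synthetic lesion (depressed
ADC of 0.8 × 10⁻³ mm²/s inside the central gland) is recovered by the
oracle backend, scored, sized, and localized by the thirds rule.

From the shell:

```bash
autoprostate phantom --out case0 --seed 3
autoprostate cbdwi --dwi case0/dwi_b0.nii.gz --dwi case0/dwi_b1000.nii.gz \
    --bvals 0,1000 --bc 2000 --out case0/cb2000.nii.gz
autoprostate run --t2 case0/t2.nii.gz --dwi case0/dwi_b0.nii.gz \
    --dwi case0/dwi_b1000.nii.gz --bvals 0,1000 \
    --zones-gt case0/zones_gt.nii.gz --psa 8.2 --out case0/out --seed 3
```

## Layout

- `src/autoprostate/core_io.py` — `VoxelGrid` container, NIfTI/DICOM I/O
- `src/autoprostate/phantom.py` — synthetic bpMRI cases with analytic ground truth
- `src/autoprostate/dwi_model.py` — monoexponential fitting, computed high-b DWI
- `src/autoprostate/preprocess.py` — resampling, cropping, whitening, CG normalization, registration hook
- `src/autoprostate/seg_backend.py` — predictor contract, ensembling, test-time augmentation/dropout, oracle backends
- `src/autoprostate/postprocess.py` — argmax labeling, isotonic calibration, candidate extraction
- `src/autoprostate/measurements.py` — lengths, volumes, PSA density, lesion characterization
- `src/autoprostate/report.py` — JSON/HTML report
- `src/autoprostate/evaluation.py` — metrics and paired statistics
- `src/autoprostate/pipeline.py` — end-to-end orchestration
- `docs/methods.md` — models, conventions, and design decisions
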