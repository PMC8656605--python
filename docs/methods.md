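# Methods

## Scope and model of the pipeline

The package implements the computational framework around a prostate-MRI
CAD system: everything from raw volumes to a structured report *except*
the segmentation networks. A network is abstracted as a `SlicePredictor`
— a function from a channel-first 2D slice to per-class probability maps
— so the pipeline's contracts (preprocessing, aggregation, restoration,
calibration, thresholding, measurement, reporting, evaluation) can be
specified and tested independently of any trained weights. A ground-truth
oracle backend, optionally degraded to a prescribed Dice, closes the loop
on synthetic phantoms.

## Coordinate conventions

Volumes are `(nx, ny, nz)` arrays with axis 0 = transverse (left–right),
axis 1 = anterior–posterior, axis 2 = cranio-caudal with z increasing
toward the head. Voxel centers sit at `origin + index·spacing` (mm); a
voxel belongs to a rasterized ellipsoid iff its center satisfies the
ellipsoid inequality. Indices are 0-based internally; reported slice
numbers are 1-based counting from the most caudal slice. NIfTI files in
other orientations are reoriented to the closest canonical frame on read.

## Synthetic phantoms

A phantom is a whole-prostate (WP) ellipsoid containing a central-gland
(CG) ellipsoid, with the peripheral zone (PZ) as the difference, plus
ellipsoidal lesions with depressed ADC. Defaults:

| parameter | default | rationale |
|---|---|---|
| grid | 128×128×28 at 0.4018 × 0.4018 × 2.0 mm | in-plane matches the pipeline's standard resolution; z covers a 50 mm gland |
| WP semi-axes | (20, 15, 25) mm → 31.4 cm³ | typical gland size |
| CG semi-axes | (12, 9, 15) mm | CG ≈ 22 % of WP |
| ADC (PZ / CG / lesion) | 1.6 / 1.3 / 0.8 ×10⁻³ mm²/s | plausible tissue values; only the ordering lesion < tissue is load-bearing |
| b-values | 0, 150, 500, 1000 s/mm² | a standard multi-b low-b protocol |
| DWI noise | additive zero-mean Gaussian, clipped at 0 | simplest model that exercises the NLS fitter; Rician noise is a possible extension |
| T2 intensities (PZ/CG/bg) | 600 / 400 / 150 ± σ=20 | bright PZ, intermediate CG; lesions 30 % hypointense |

Analytic volumes `(4/3)πabc` and diameters are stored with each case, so
voxel-counting measurements have closed-form references. Rasterized
volumes converge to the analytic value as spacing shrinks (verified at
2 → 1 → 0.5 mm); at 0.5 mm isotropic the WP error is ≈ 0.05 %.

What the phantoms deliberately do **not** emulate: realistic anatomy
beyond nested ellipsoids, bias fields, susceptibility artifacts, motion
between sequences, or Rician noise floors. Green tests on phantoms
therefore demonstrate the correctness of the computational contracts, not
clinical segmentation performance — the latter depends entirely on the
plugged-in backend.

`perturb_mask` degrades a mask to a target Dice by removing
`r = round(n(1−d))` voxels from the shallowest interior and adding the
same number just outside the surface (seeded tie-breaks), so the output
keeps size `n` and has Dice exactly `1 − r/n` with the original — a
controlled stand-in for imperfect segmentation.

## Monoexponential DWI model

`s(b) = s0·exp(−b·ADC)` is fitted per voxel by bounded
Levenberg–Marquardt on `(s0, ADC)` with both parameters constrained
non-negative, initialized from the ordinary-least-squares fit of `ln s`
on `b` (non-positive signals excluded). The ADC coordinate is rescaled by
10⁻³ inside the normal equations to keep them well-conditioned against
the ~10⁵ dynamic-range gap between s0 and ADC. Voxels whose signals all
fall below 10⁻⁶ short-circuit to `(0, 0)` — this keeps air from producing
NaNs. On noiseless monoexponential input the initializer is already the
exact optimum and the iteration terminates at machine precision, which is
what makes the phantom closure (`|ADC* − ADC| < 10⁻⁹`) meaningful. When a
scanner-supplied ADC map is available the computed image can instead be
extrapolated directly from the lowest-b acquisition,
`s(b_c) = s(b_low)·exp(−(b_c−b_low)·ADC)`; both paths are exposed and the
pipeline defaults to the supplied-ADC path when a map is given.

## Preprocessing

- **Resampling** changes only the in-plane spacing (linear for
  intensities, nearest-neighbour for labels); a grid already at the
  target spacing is passed through bit-exactly.
- **Crop-or-pad** records per-axis offsets so the operation is exactly
  invertible; zero-padding covers crops beyond the source.
- **Whitening** (zonal pathway) uses whole-volume statistics — per-slice
  or organ-restricted variants were considered and rejected as
  under-specified; whole-volume is the simplest reproducible choice.
- **CG normalization** (lesion pathway) divides by the interquartile mean
  of CG voxel intensities: quartiles by linear interpolation, the
  interquartile set inclusive of its bounds (stated explicitly so tests
  are exact). It is scale-invariant by construction. ADC maps are never
  normalized — they carry a quantitative measurement.
- **Registration** is a pluggable provider returning a physical-space
  affine; the default is the identity (inputs assumed co-registered).
  Re-implementing block-matching/FFD registration is out of scope; an
  external tool can be wired in through the provider interface.
- The lesion-pathway crop is centred on the whole-prostate centroid from
  the zonal output, rounded to the nearest voxel.

## Aggregation around the backend

Ensembling is per-voxel arithmetic averaging; inputs are sorted per voxel
before summation so the result is bit-identical under input permutation
(float addition is not associative). Test-time augmentation applies an
invertible transform to the input, predicts, inverse-transforms the
probabilities, and averages with the plain prediction; the default
transform family (horizontal flip, ±10° rotation, ±10 % scale) is a fixed
discretization of typical training augmentation ranges. Test-time dropout
averages seeded stochastic forward passes (default 10). When both are
active, a single pooled average is taken over all passes. Oracle-backend
pipelines default to no TTA and a single pass, which keeps the
ground-truth closure exact.

## Post-processing

Zonal labels come from per-voxel argmax with ties resolved by the fixed
priority background < PZ < CG (the more specific tissue class wins — the
tie-break must be documented for bit-exact tests).

Lesion probabilities are calibrated by isotonic regression
(pool-adjacent-violators least squares), applied pointwise through a
piecewise-linear map over the fitted knots. Because PAV produces flat
segments that would collapse distinct raw scores into ties — perturbing
ranking metrics such as ROC AUC that calibration should leave invariant —
the applied map blends in a strictly increasing component of the raw
score with weight 10⁻⁹: calibrated values change by less than 10⁻⁹ while
the ranking of distinct scores stays strict. The calibrator is fitted on
pooled voxel-level (score, label) pairs; lesion-level fitting is a
reasonable alternative the package does not implement.

Thresholding uses `p ≥ C` (voxels exactly at the cut-off are positive;
default C = 0.045). Connected components are labeled under 26-neighbour
connectivity by default (6/18 configurable), and components with physical
volume strictly below 40 mm³ are removed — a component exactly at the
minimum is kept. Each candidate is scored by the maximum calibrated
probability inside the component, consistent with per-lesion likelihoods
near 100 % that a mean would rarely attain.

## Measurements

Lengths use the voxel-footprint convention `(max − min + 1)·spacing`, so
a single-voxel object has nonzero extent. Volumes are voxel count ×
voxel volume. PSA density is PSA / WP volume (ng/mL²; unavailable when no
PSA is recorded, in which case the report says so rather than failing).
The centroid region splits the WP z-extent into thirds by physical
length — apex caudal, base cranial, midgland between — with boundaries
assigned to the more central region; splitting by physical length rather
than slice count is robust to anisotropic z spacing. A lesion centroid
that rounds onto background (possible for C-shaped PZ) falls back to the
nearest in-prostate zone label by physical distance. Lesions are listed
in descending calibrated probability with a stable sort.

## Evaluation suite

Detection matching: a candidate matches a ground-truth lesion iff their
masks share at least one voxel — the most permissive standard criterion,
chosen because stricter variants (centroid-inside, Dice > 0.1) are
equally defensible and this one is simplest to reason about; it is
documented rather than configurable-by-default. Each candidate goes to
the lesion of greatest overlap (ties to the larger lesion). A lesion's
score is the maximum probability over matching candidates, falling back
to the maximum calibrated voxel probability under its contour; unmatched
candidates are false positives, and the per-patient FP mean is restricted
to biopsy-negative patients, where ground truth permits FP
determination. Specificity is computed over annotated non-significant
lesions only.

Statistics: Wilcoxon signed-rank discards zero differences and uses the
exact distribution for n ≤ 25 without ties (normal approximation with
continuity correction otherwise); McNemar is the exact two-sided binomial
on discordant pairs (p = 1 when there are none); DeLong's test forms the
paired-AUC covariance from per-case placement values (structural
components) and reports a two-sided z-test; the precision comparison is a
generalized-score-style z-test on the difference of two ratio-of-means
estimators with the paired covariance retained via per-lesion influence
contributions. All four are validated against enumeration, bootstrap, or
Monte-Carlo oracles in the test suite; empirical type-I error of the
McNemar, Wilcoxon and precision tests is checked to lie in
[0.03, 0.07] at nominal α = 0.05 over 2000 null simulations.

## Problem sizes

Cohort-level tests use 20-case phantom cohorts at the default grid
(128×128×28), processed at oracle Dice 1.0 / 0.8 / 0.6; the acceptance
script uses 12 cases plus one 0.5 mm phantom for volume accuracy. These
sizes give stable cohort metrics (≈ 30 lesions, ≈ 5 negative patients)
while keeping a full run in minutes on one CPU.

## Known limitations

- The identity registration default assumes co-registered inputs; real
  multi-sequence data needs an external registration provider.
- Whitening and CG-normalization conventions (whole-volume statistics,
  inclusive interquartile bounds) are one defensible reading of
  under-specified steps; alternatives would change intensities fed to a
  real backend but not the contracts tested here.
- The oracle lesion backend assigns per-lesion probabilities from fixed
  ranges (CSPCa 0.7–1.0, non-significant 0.05–0.4); real backends produce
  far noisier maps, so end-to-end phantom metrics are upper bounds.
- DICOM is read-only; no DICOM-SR export.
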