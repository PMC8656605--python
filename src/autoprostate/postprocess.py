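"""Probability-volume post-processing for both pathways.

Zonal pathway: background/PZ/CG probability volumes become a label map by
per-voxel argmax (ties resolved by the fixed priority background < PZ <
CG, so the most specific tissue class wins).

Lesion pathway: raw CSPCa probabilities are calibrated with isotonic
regression (pool-adjacent-violators), thresholded at a cut-off C
(voxels exactly at the cut-off are positive), connected components are
labeled under configurable 3D connectivity, and components with physical
volume strictly below MinSize mm^3 are removed as false-positive
reduction. Each surviving component is scored by its maximum calibrated
voxel probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.isotonic import IsotonicRegression

from .core_io import VoxelGrid

__all__ = [
    "Calibrator",
    "PostprocessConfig",
    "ComponentCandidate",
    "zones_argmax",
    "fit_calibrator",
    "apply_calibrator",
    "extract_candidates",
]

ZONE_LABELS = {"background": 0, "PZ": 1, "CG": 2}


@dataclass(frozen=True)
class Calibrator:
    """Piecewise-linear monotone map from raw to calibrated probability.

    ``breakpoints`` are increasing raw-score knots; ``values`` are the
    non-decreasing calibrated probabilities at those knots. Scores outside
    the knot range clamp to the end values.
    """

    breakpoints: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if bp.ndim != 1 or bp.shape != vals.shape:
            raise ValueError("breakpoints and values must be 1D of equal length")
        if (np.diff(bp) < 0).any() or (np.diff(vals) < -1e-12).any():
            raise ValueError("breakpoints must be increasing and values non-decreasing")
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "values", vals)

    #: weight of the strictly increasing tie-break component (see __call__)
    _EPS = 1e-9

    def __call__(self, scores: np.ndarray) -> np.ndarray:
        """Calibrated probabilities.

        The isotonic fit contains flat segments where pooled scores map to
        one value; a pure lookup would turn distinct raw scores into ties
        and perturb ranking metrics. The output therefore blends in an
        infinitesimal strictly increasing component of the raw score
        (weight 1e-9), which keeps the ranking of distinct scores strict
        while changing calibrated values by less than 1e-9.
        """
        s = np.asarray(scores, dtype=float)
        cal = np.interp(s, self.breakpoints, self.values)
        return (1.0 - self._EPS) * cal + self._EPS * np.clip(s, 0.0, 1.0)

    @classmethod
    def identity(cls) -> "Calibrator":
        return cls(np.array([0.0, 1.0]), np.array([0.0, 1.0]))


@dataclass(frozen=True)
class PostprocessConfig:
    cutoff_C: float = 0.045  # probability cut-off (4.5%)
    min_size_mm3: float = 40.0  # 20% of the 200 mm^3 guideline minimum
    connectivity: int = 26  # 6 / 18 / 26-neighbour

    def __post_init__(self) -> None:
        if not (0 < self.cutoff_C < 1):
            raise ValueError("cutoff_C must be in (0, 1)")
        if self.min_size_mm3 < 0:
            raise ValueError("min_size_mm3 must be >= 0")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclass(frozen=True)
class ComponentCandidate:
    """One connected component above the cut-off, with its score."""

    mask: VoxelGrid  # binary, single connected component
    score: float  # max calibrated probability inside the component

    @property
    def volume_cm3(self) -> float:
        return float((np.asarray(self.mask.data) > 0).sum() * self.mask.voxel_volume_mm3 / 1000.0)


def zones_argmax(channels: dict) -> VoxelGrid:
    """Label map from per-class probability volumes.

    ``channels`` maps class name ('background', 'PZ', 'CG') to a
    probability :class:`VoxelGrid`. On exact ties the higher-priority
    class (background < PZ < CG) wins.
    """
    missing = set(ZONE_LABELS) - set(channels)
    if missing:
        raise ValueError(f"missing zone channels: {sorted(missing)}")
    ref = channels["background"]
    for name in ("PZ", "CG"):
        if not ref.same_geometry(channels[name]):
            raise ValueError(f"geometry mismatch on channel {name}")
    stack = np.stack(
        [np.asarray(channels[name].data, dtype=float) for name in ("background", "PZ", "CG")]
    )
    # np.argmax picks the first max; reverse so the highest-priority class wins ties
    labels = (2 - np.argmax(stack[::-1], axis=0)).astype(np.uint8)
    return ref.with_data(labels)


def fit_calibrator(raw_scores, labels) -> Calibrator:
    """Isotonic (pool-adjacent-violators) least-squares calibration fit.

    Fits the non-decreasing function minimizing the squared error between
    calibrated scores and binary outcome labels; both classes must be
    present.
    """
    scores = np.asarray(raw_scores, dtype=float).ravel()
    y = np.asarray(labels, dtype=float).ravel()
    if scores.size != y.size or scores.size < 2:
        raise ValueError("need >= 2 paired (score, label) samples")
    if np.unique(y).size < 2:
        raise ValueError("labels must contain both classes")
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
    iso.fit(scores, y)
    bp = np.asarray(iso.X_thresholds_, dtype=float)
    vals = np.asarray(iso.y_thresholds_, dtype=float)
    if bp.size == 1:  # degenerate single-knot fit
        bp = np.array([bp[0], bp[0] + 1e-12])
        vals = np.array([vals[0], vals[0]])
    return Calibrator(bp, vals)


def apply_calibrator(cal: Calibrator, prob: VoxelGrid) -> VoxelGrid:
    """Pointwise monotone recalibration; preserves the voxel ranking."""
    return prob.with_data(np.clip(cal(prob.data), 0.0, 1.0))


_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def extract_candidates(
    prob: VoxelGrid, config: PostprocessConfig = PostprocessConfig()
) -> list[ComponentCandidate]:
    """Threshold, label connected components, drop the small ones.

    Voxels with probability >= ``cutoff_C`` are foreground; components
    with volume strictly below ``min_size_mm3`` are removed (a component
    exactly at the minimum size is kept). An empty result is valid.
    """
    data = np.asarray(prob.data, dtype=float)
    fg = data >= config.cutoff_C
    labeled, ncomp = ndimage.label(fg, structure=_STRUCTS[config.connectivity])
    voxvol = prob.voxel_volume_mm3
    out: list[ComponentCandidate] = []
    for comp_id in range(1, ncomp + 1):
        comp = labeled == comp_id
        if comp.sum() * voxvol < config.min_size_mm3:
            continue
        out.append(
            ComponentCandidate(
                mask=prob.with_data(comp.astype(np.uint8)),
                score=float(data[comp].max()),
            )
        )
    return out
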