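"""Pluggable slice-wise segmentation backends and aggregation machinery.

The segmentation networks themselves are deliberately not part of this
package: a backend is anything implementing the :class:`SlicePredictor`
contract (multi-channel 2D slice in, per-class 2D probability maps out).
What the package owns is everything around the network — per-voxel ensemble
averaging, test-time augmentation (aleatoric uncertainty), test-time
dropout (epistemic uncertainty), and slice-wise prediction with restacking
into probability volumes.

Two oracle backends built on ground truth (optionally degraded to a target
Dice via :func:`autoprostate.phantom.perturb_mask`) make the full pipeline
testable end to end without any trained weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence, runtime_checkable

import numpy as np
from scipy import ndimage

from .core_io import VoxelGrid
from .phantom import perturb_mask

__all__ = [
    "SlicePredictor",
    "BackendConfig",
    "HorizontalFlip",
    "Rotate",
    "Scale",
    "default_tta_transforms",
    "ensemble_average",
    "tta_predict",
    "ttd_predict",
    "predict_volume",
    "OracleZonePredictor",
    "OracleLesionPredictor",
]


@runtime_checkable
class SlicePredictor(Protocol):
    """Contract for slice-wise predictors.

    ``predict`` maps a channel-first 2D slice ``(C, H, W)`` to per-class
    probability maps ``(K, H, W)``. Zone predictors must emit class
    probabilities summing to 1 per pixel; lesion predictors emit a single
    foreground probability channel in [0, 1].
    """

    classes: Sequence[str]
    stochastic: bool

    def predict(
        self,
        x: np.ndarray,
        slice_index: Optional[int] = None,
        rng: Optional[np.random.Generator] = None,
    ) -> np.ndarray: ...


# --------------------------------------------------------------------------
# Invertible test-time augmentation transforms
# --------------------------------------------------------------------------

class HorizontalFlip:
    """Left-right flip (transverse axis); self-inverse and exact."""

    def forward(self, arr: np.ndarray) -> np.ndarray:
        return arr[::-1, :].copy()

    def inverse(self, arr: np.ndarray) -> np.ndarray:
        return arr[::-1, :].copy()


class Rotate:
    """In-plane rotation by a fixed angle (degrees), linear interpolation."""

    def __init__(self, degrees: float):
        self.degrees = float(degrees)

    def _rot(self, arr: np.ndarray, deg: float) -> np.ndarray:
        return ndimage.rotate(arr, deg, axes=(0, 1), reshape=False, order=1, mode="nearest")

    def forward(self, arr: np.ndarray) -> np.ndarray:
        return self._rot(arr, self.degrees)

    def inverse(self, arr: np.ndarray) -> np.ndarray:
        return self._rot(arr, -self.degrees)


class Scale:
    """Isotropic in-plane scaling about the slice center."""

    def __init__(self, factor: float):
        if factor <= 0:
            raise ValueError("scale factor must be > 0")
        self.factor = float(factor)

    def _scale(self, arr: np.ndarray, factor: float) -> np.ndarray:
        center = (np.array(arr.shape) - 1) / 2.0
        matrix = np.eye(2) / factor
        offset = center - matrix @ center
        return ndimage.affine_transform(arr, matrix, offset=offset, order=1, mode="nearest")

    def forward(self, arr: np.ndarray) -> np.ndarray:
        return self._scale(arr, self.factor)

    def inverse(self, arr: np.ndarray) -> np.ndarray:
        return self._scale(arr, 1.0 / self.factor)


def default_tta_transforms() -> list:
    """Discretization of the training-time augmentation family:
    horizontal flip, +/-10 degree rotation, +/-10% scale."""
    return [HorizontalFlip(), Rotate(10.0), Rotate(-10.0), Scale(1.1), Scale(0.9)]


@dataclass(frozen=True)
class BackendConfig:
    """Aggregation settings applied around any backend."""

    tta_transforms: tuple = ()
    ttd_passes: int = 10
    dropout_p: float = 0.2
    ensemble_members: int = 1

    def __post_init__(self) -> None:
        if self.ttd_passes < 1:
            raise ValueError("ttd_passes must be >= 1")
        for t in self.tta_transforms:
            if not (hasattr(t, "forward") and hasattr(t, "inverse")):
                raise ValueError(f"TTA transform {t!r} must define forward and inverse")


# --------------------------------------------------------------------------
# Aggregation operations
# --------------------------------------------------------------------------

def ensemble_average(maps: Sequence[np.ndarray]) -> np.ndarray:
    """Per-voxel arithmetic mean of probability maps; order-invariant."""
    if len(maps) == 0:
        raise ValueError("need >= 1 probability map")
    arrs = [np.asarray(m, dtype=float) for m in maps]
    shape = arrs[0].shape
    for a in arrs[1:]:
        if a.shape != shape:
            raise ValueError(f"geometry mismatch: {a.shape} vs {shape}")
    # sort per voxel before summing so the result is bit-identical under
    # any permutation of the inputs (float addition is not associative)
    stack = np.sort(np.stack(arrs), axis=0)
    return stack.mean(axis=0)


def _apply_channelwise(transform_fn, arr: np.ndarray) -> np.ndarray:
    return np.stack([transform_fn(arr[c]) for c in range(arr.shape[0])])


def tta_predict(
    predictor: SlicePredictor,
    x: np.ndarray,
    transforms: Sequence,
    slice_index: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Average the plain prediction with inverse-mapped predictions on
    transformed inputs."""
    for t in transforms:
        if not (hasattr(t, "forward") and hasattr(t, "inverse")):
            raise ValueError(f"transform {t!r} is not invertible")
    preds = [predictor.predict(x, slice_index=slice_index, rng=rng)]
    for t in transforms:
        x_t = _apply_channelwise(t.forward, x)
        p_t = predictor.predict(x_t, slice_index=slice_index, rng=rng)
        preds.append(_apply_channelwise(t.inverse, p_t))
    return np.clip(ensemble_average(preds), 0.0, 1.0)


def ttd_predict(
    predictor: SlicePredictor,
    x: np.ndarray,
    passes: int,
    seed: int,
    slice_index: Optional[int] = None,
) -> np.ndarray:
    """Mean over seeded stochastic forward passes."""
    if passes < 1:
        raise ValueError("passes must be >= 1")
    if passes > 1 and not predictor.stochastic:
        raise ValueError("predictor is deterministic; ttd requires stochastic=True")
    rng = np.random.default_rng(seed)
    preds = [predictor.predict(x, slice_index=slice_index, rng=rng) for _ in range(passes)]
    return ensemble_average(preds)


def predict_volume(
    predictor: SlicePredictor,
    channels: Sequence[VoxelGrid],
    config: BackendConfig = BackendConfig(),
    seed: int = 0,
) -> list[VoxelGrid]:
    """Slice-wise prediction with pooled TTA/TTD averaging, restacked
    along z.

    Returns one probability :class:`VoxelGrid` per predictor class,
    sharing the input geometry.
    """
    if len(channels) == 0:
        raise ValueError("need >= 1 input channel")
    ref = channels[0]
    for ch in channels[1:]:
        if not ref.same_geometry(ch):
            raise ValueError("channel geometry mismatch")
    nz = ref.shape[2]
    passes = config.ttd_passes if predictor.stochastic else 1
    rng = np.random.default_rng(seed)

    k = len(predictor.classes)
    out = np.zeros((k,) + ref.shape, dtype=float)
    for z in range(nz):
        x = np.stack([np.asarray(ch.data, dtype=float)[:, :, z] for ch in channels])
        pooled = []
        for _ in range(passes):
            pooled.append(
                tta_predict(predictor, x, config.tta_transforms, slice_index=z, rng=rng)
            )
        out[:, :, :, z] = ensemble_average(pooled)
    return [ref.with_data(out[c]) for c in range(k)]


# --------------------------------------------------------------------------
# Oracle backends
# --------------------------------------------------------------------------

class OracleZonePredictor:
    """Ground-truth zonal predictor, optionally degraded to a target Dice.

    Emits one-hot background/PZ/CG probabilities from a (possibly
    perturbed) zonal label volume; ``predict`` reads slices by index and
    ignores the image channels.
    """

    classes = ("background", "PZ", "CG")
    stochastic = False

    def __init__(self, zones_gt: VoxelGrid, dice_target: float = 1.0, seed: int = 0):
        labels = np.asarray(zones_gt.data)
        pz = zones_gt.with_data((labels == 1).astype(np.uint8))
        cg = zones_gt.with_data((labels == 2).astype(np.uint8))
        if dice_target < 1.0:
            pz = perturb_mask(pz, dice_target, seed)
            cg = perturb_mask(cg, dice_target, seed + 1)
        pz_a = np.asarray(pz.data) > 0
        cg_a = np.asarray(cg.data) > 0
        pz_a = pz_a & ~cg_a  # CG wins where perturbed masks collide
        self._probs = np.stack([(~(pz_a | cg_a)), pz_a, cg_a]).astype(float)

    def predict(self, x, slice_index=None, rng=None):
        if slice_index is None:
            raise ValueError("oracle predictor requires a slice index")
        return self._probs[:, :, :, slice_index]


class OracleLesionPredictor:
    """Ground-truth lesion predictor with per-lesion probabilities.

    Each lesion mask (optionally perturbed to a target Dice) is filled
    with a seeded per-lesion probability — high for CSPCa lesions, low for
    non-significant ones — so downstream thresholding, calibration and
    ROC analysis see realistic score separation.
    """

    classes = ("lesion",)
    stochastic = False

    def __init__(
        self,
        lesions_gt: Sequence[tuple[VoxelGrid, bool]],
        dice_target: float = 1.0,
        seed: int = 0,
        p_range_cspca: tuple[float, float] = (0.7, 1.0),
        p_range_ncspca: tuple[float, float] = (0.05, 0.4),
    ):
        rng = np.random.default_rng(seed)
        prob = None
        for i, (mask, is_cspca) in enumerate(lesions_gt):
            lo, hi = p_range_cspca if is_cspca else p_range_ncspca
            p = rng.uniform(lo, hi)
            m = mask if dice_target >= 1.0 else perturb_mask(mask, dice_target, seed + 17 * i)
            arr = (np.asarray(m.data) > 0) * p
            prob = arr if prob is None else np.maximum(prob, arr)
            self._shape = m.data.shape
        if prob is None:
            raise ValueError("oracle lesion predictor needs the volume shape; pass lesions or use empty_like")
        self._prob = prob

    @classmethod
    def empty_like(cls, grid: VoxelGrid) -> "OracleLesionPredictor":
        """Predictor for a case with no lesions (biopsy-negative phantom)."""
        obj = cls.__new__(cls)
        obj._prob = np.zeros(grid.shape, dtype=float)
        obj._shape = grid.shape
        return obj

    def predict(self, x, slice_index=None, rng=None):
        if slice_index is None:
            raise ValueError("oracle predictor requires a slice index")
        return self._prob[None, :, :, slice_index]
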