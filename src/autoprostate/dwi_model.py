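"""Per-voxel monoexponential DWI fitting and computed high b-value DWI.

The observed diffusion signal is modeled as ``s(b) = s(0) * exp(-b * ADC)``.
Non-linear least squares recovers estimates ``s*(0)`` and ``ADC*`` from two
or more low-b acquisitions; a computed high b-value image is then
extrapolated as ``s(bc) = s*(0) * exp(-bc * ADC*)``. Both quantities are
constrained non-negative, so the extrapolated signal is always in
``[0, s*(0)]`` for ``bc >= 0``.

Fitting is a bounded Levenberg–Marquardt iteration initialized from the
log-linear ordinary-least-squares fit of ``ln s`` against ``b`` (zeros
excluded). For noiseless monoexponential input the initializer is already
exact and the iteration terminates immediately. Voxels whose signals all
fall below a small floor short-circuit to ``(0, 0)``, which keeps air
outside the body from producing NaNs.

When a scanner-provided ADC map is available, an alternative path
extrapolates directly from the lowest-b image:
``s(bc) = s(b_low) * exp(-(bc - b_low) * ADC)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import VoxelGrid

__all__ = [
    "MonoexpFit",
    "fit_monoexp",
    "compute_high_b",
    "compute_high_b_volume",
    "compute_high_b_from_adc",
]

SIGNAL_FLOOR = 1e-6
_MAX_ITER = 100


@dataclass(frozen=True)
class MonoexpFit:
    s0_est: float  # signal intensity, >= 0
    adc_est: float  # mm^2/s, >= 0
    residual_norm: float  # sum of squared residuals
    converged: bool


def _loglinear_init(b: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized OLS of ln(s) on b per voxel, positive signals only.

    Rows with < 2 usable points fall back to (max signal, 0).
    """
    pos = s > SIGNAL_FLOOR
    npos = pos.sum(axis=1)
    logs = np.where(pos, np.log(np.where(pos, s, 1.0)), 0.0)
    bm = np.where(pos, b, 0.0)

    sum_b = bm.sum(axis=1)
    sum_b2 = (bm**2).sum(axis=1)
    sum_y = logs.sum(axis=1)
    sum_by = (bm * logs).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = npos * sum_b2 - sum_b**2
        slope = np.where(denom > 0, (npos * sum_by - sum_b * sum_y) / np.where(denom > 0, denom, 1.0), 0.0)
        intercept = np.where(npos > 0, (sum_y - slope * sum_b) / np.maximum(npos, 1), 0.0)

    adc0 = np.clip(-slope, 0.0, None)
    s00 = np.exp(intercept)
    fallback = npos < 2
    s00 = np.where(fallback, s.max(axis=1), s00)
    adc0 = np.where(fallback, 0.0, adc0)
    return s00, adc0


def _fit_stack(b: np.ndarray, signals: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Bounded LM fit of (s0, adc) for each row of ``signals``.

    Returns (s0, adc, sse, converged) arrays.
    """
    s = np.asarray(signals, dtype=float)
    nvox = s.shape[0]
    b_row = np.asarray(b, dtype=float)[None, :]

    dead = (s <= SIGNAL_FLOOR).all(axis=1)
    s0, adc = _loglinear_init(b_row * np.ones((nvox, 1)), s)
    s0 = np.where(dead, 0.0, s0)
    adc = np.where(dead, 0.0, adc)

    def sse_of(s0v: np.ndarray, adcv: np.ndarray, rows: np.ndarray | None = None) -> np.ndarray:
        obs = s if rows is None else s[rows]
        model = s0v[:, None] * np.exp(-b_row * adcv[:, None])
        return ((obs - model) ** 2).sum(axis=1)

    sse = sse_of(s0, adc)
    converged = dead.copy()
    lam = np.full(nvox, 1e-3)
    # ADC is ~1e-3 while s0 is ~1e2: scale the adc coordinate so the 2x2
    # normal equations stay well-conditioned
    adc_scale = 1e-3

    active = ~converged
    for _ in range(_MAX_ITER):
        if not active.any():
            break
        ia = np.flatnonzero(active)
        e = np.exp(-b_row * adc[ia, None])
        model = s0[ia, None] * e
        r = s[ia] - model
        j0 = e  # d model / d s0
        j1 = -s0[ia, None] * b_row * e * adc_scale  # d model / d (adc/scale)
        g0 = (j0 * r).sum(axis=1)
        g1 = (j1 * r).sum(axis=1)
        h00 = (j0 * j0).sum(axis=1)
        h01 = (j0 * j1).sum(axis=1)
        h11 = (j1 * j1).sum(axis=1)

        grad_small = np.hypot(g0, g1) < 1e-12 * (1.0 + sse[ia])
        a00 = h00 * (1 + lam[ia])
        a11 = h11 * (1 + lam[ia])
        det = a00 * a11 - h01**2
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        d_s0 = (a11 * g0 - h01 * g1) / det
        d_adc = (a00 * g1 - h01 * g0) / det * adc_scale

        s0_new = np.clip(s0[ia] + d_s0, 0.0, None)
        adc_new = np.clip(adc[ia] + d_adc, 0.0, None)
        sse_new = sse_of(s0_new, adc_new, rows=ia)
        better = sse_new <= sse[ia]

        step = np.hypot(s0_new - s0[ia], (adc_new - adc[ia]) / adc_scale)
        done = grad_small | (better & (step < 1e-12 * (1.0 + np.hypot(s0[ia], adc[ia] / adc_scale))))

        s0[ia] = np.where(better, s0_new, s0[ia])
        adc[ia] = np.where(better, adc_new, adc[ia])
        sse[ia] = np.where(better, sse_new, sse[ia])
        lam[ia] = np.where(better, lam[ia] * 0.3, lam[ia] * 10.0)
        converged[ia] |= done
        active = ~converged & (lam < 1e12)

    return s0, adc, sse, converged


def fit_monoexp(b_values, signals) -> MonoexpFit:
    """Fit ``s(b) = s0 * exp(-b * adc)`` to one voxel's signals.

    Requires at least two distinct b-values; signals must be non-negative.
    All-zero signals return the degenerate exact fit (0, 0).
    """
    b = np.asarray(b_values, dtype=float)
    s = np.asarray(signals, dtype=float)
    if b.shape != s.shape or b.ndim != 1:
        raise ValueError("b_values and signals must be 1D of equal length")
    if np.unique(b).size < 2:
        raise ValueError("need >= 2 distinct b-values")
    if (s < 0).any():
        raise ValueError("signals must be non-negative")
    s0, adc, sse, conv = _fit_stack(b, s[None, :])
    return MonoexpFit(
        s0_est=float(s0[0]),
        adc_est=float(adc[0]),
        residual_norm=float(sse[0]),
        converged=bool(conv[0]),
    )


def compute_high_b(fit: MonoexpFit, bc: float) -> float:
    """Extrapolated signal ``s*(0) * exp(-bc * ADC*)`` at b-value ``bc``."""
    if bc < 0:
        raise ValueError(f"bc must be >= 0, got {bc}")
    return float(fit.s0_est * np.exp(-bc * fit.adc_est))


def compute_high_b_volume(dwi: dict, bc: float) -> VoxelGrid:
    """Voxelwise monoexponential fit of a DWI stack, extrapolated to ``bc``.

    Parameters
    ----------
    dwi:
        Mapping b-value (s/mm^2) -> :class:`VoxelGrid`; all grids must
        share geometry and at least two distinct b-values are required.
    """
    if bc < 0:
        raise ValueError(f"bc must be >= 0, got {bc}")
    bvals = sorted(float(b) for b in dwi)
    if len(bvals) < 2:
        raise ValueError("need >= 2 b-values")
    ref = dwi[bvals[0]]
    for b in bvals[1:]:
        if not ref.same_geometry(dwi[b]):
            raise ValueError(f"geometry mismatch between b={bvals[0]} and b={b}")
    stack = np.stack([np.asarray(dwi[b].data, dtype=float).ravel() for b in bvals], axis=1)
    s0, adc, _, _ = _fit_stack(np.asarray(bvals), stack)
    out = (s0 * np.exp(-bc * adc)).reshape(ref.shape)
    return ref.with_data(out)


def fit_monoexp_volume(dwi: dict) -> tuple[VoxelGrid, VoxelGrid]:
    """Voxelwise fit of a DWI stack; returns (s0, adc) volumes."""
    bvals = sorted(float(b) for b in dwi)
    if len(bvals) < 2:
        raise ValueError("need >= 2 b-values")
    ref = dwi[bvals[0]]
    for b in bvals[1:]:
        if not ref.same_geometry(dwi[b]):
            raise ValueError("geometry mismatch in DWI stack")
    stack = np.stack([np.asarray(dwi[b].data, dtype=float).ravel() for b in bvals], axis=1)
    s0, adc, _, _ = _fit_stack(np.asarray(bvals), stack)
    return ref.with_data(s0.reshape(ref.shape)), ref.with_data(adc.reshape(ref.shape))


def compute_high_b_from_adc(dwi_low: VoxelGrid, b_low: float, adc_map: VoxelGrid, bc: float) -> VoxelGrid:
    """Extrapolate from a single low-b image and a supplied ADC map."""
    if bc < b_low:
        raise ValueError("bc must be >= the acquired low b-value")
    if not dwi_low.same_geometry(adc_map):
        raise ValueError("DWI and ADC map geometry mismatch")
    out = np.asarray(dwi_low.data, dtype=float) * np.exp(
        -(bc - b_low) * np.asarray(adc_map.data, dtype=float)
    )
    return dwi_low.with_data(out)
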