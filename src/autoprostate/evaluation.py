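"""Segmentation, volume and lesion-level detection metrics, plus the
paired statistical comparisons used to benchmark the pipeline against a
human reader.

Detection bookkeeping: a predicted component matches a ground-truth lesion
iff their masks share at least one voxel; each component is assigned to
the single lesion of greatest overlap (ties to the larger lesion). A
lesion's score is the maximum probability over its matching components,
falling back to the maximum calibrated voxel probability under its contour
when nothing matched. Unmatched components are false positives, and the
per-patient false-positive mean is restricted to biopsy-negative patients,
where the ground truth permits false-positive determination.

Statistics: Wilcoxon signed-rank (paired volume/PSAd estimates), DeLong's
paired-AUC z-test with the structural-components covariance estimator,
McNemar's exact binomial test on discordant pairs (paired
sensitivity/specificity), and a weighted generalized-score style z-test on
paired positive predictive fractions (precision).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .core_io import VoxelGrid
from .postprocess import ComponentCandidate

__all__ = [
    "DetectionOutcome",
    "dice",
    "lesion_dice_contoured_slices",
    "abs_pct_err",
    "ellipsoid_volume",
    "match_detections",
    "detection_metrics",
    "roc_auc",
    "pr_auc",
    "select_cutoff",
    "wilcoxon_signed_rank",
    "mcnemar",
    "delong",
    "wgs_precision_test",
    "concordance",
]


# --------------------------------------------------------------------------
# Segmentation / volume metrics
# --------------------------------------------------------------------------

def dice(a: VoxelGrid, b: VoxelGrid) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); two empty masks score 1."""
    if a.shape != b.shape:
        raise ValueError(f"geometry mismatch: {a.shape} vs {b.shape}")
    am = np.asarray(a.data) > 0
    bm = np.asarray(b.data) > 0
    denom = am.sum() + bm.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (am & bm).sum() / denom)


def lesion_dice_contoured_slices(pred: VoxelGrid, gt: VoxelGrid) -> float:
    """Dice restricted to z-slices where the ground truth has a contour."""
    if pred.shape != gt.shape:
        raise ValueError("geometry mismatch")
    gm = np.asarray(gt.data) > 0
    if not gm.any():
        raise ValueError("ground-truth mask is empty")
    zs = gm.any(axis=(0, 1))
    pm = np.asarray(pred.data) > 0
    pm, gm = pm[:, :, zs], gm[:, :, zs]
    return float(2.0 * (pm & gm).sum() / (pm.sum() + gm.sum()))


def abs_pct_err(est: float, truth: float) -> float:
    if truth == 0:
        raise ValueError("truth must be nonzero for Abs%Err")
    return 100.0 * abs(est - truth) / truth


def ellipsoid_volume(l1: float, l2: float, l3: float) -> float:
    """Ellipsoid-formula volume from three diameters (the radiologist's
    manual estimate): l1*l2*l3*pi/6."""
    if min(l1, l2, l3) <= 0:
        raise ValueError("lengths must be > 0")
    return l1 * l2 * l3 * np.pi / 6.0


# --------------------------------------------------------------------------
# Detection bookkeeping
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectionOutcome:
    """Per-patient lesion-level TP/FP/FN bookkeeping."""

    lesion_matched: tuple  # per GT lesion
    lesion_score: tuple  # per GT lesion
    lesion_is_cspca: tuple  # per GT lesion
    fp_count: int  # unmatched predicted components
    biopsy_negative: bool = False


def match_detections(
    candidates: list,
    gt_lesions: list,
    calibrated_prob: VoxelGrid | None = None,
    biopsy_negative: bool = False,
) -> DetectionOutcome:
    """Assign predicted components to ground-truth lesions.

    ``candidates``: list of :class:`ComponentCandidate` (or (mask, score)
    pairs); ``gt_lesions``: list of (mask, is_cspca).
    """
    cand = [
        c if isinstance(c, ComponentCandidate) else ComponentCandidate(mask=c[0], score=float(c[1]))
        for c in candidates
    ]
    gt_masks = [np.asarray(m.data) > 0 for m, _ in gt_lesions]
    gt_sizes = [int(m.sum()) for m in gt_masks]
    for c in cand:
        for gm, _ in gt_lesions:
            if c.mask.shape != gm.shape:
                raise ValueError("candidate/ground-truth geometry mismatch")

    assigned: list[int | None] = []
    for c in cand:
        cm = np.asarray(c.mask.data) > 0
        overlaps = [int((cm & gm).sum()) for gm in gt_masks]
        best = None
        if overlaps and max(overlaps) > 0:
            top = max(overlaps)
            tied = [i for i, o in enumerate(overlaps) if o == top]
            best = max(tied, key=lambda i: gt_sizes[i])  # ties -> larger GT lesion
        assigned.append(best)

    matched, scores = [], []
    for i, (gm, _) in enumerate(gt_lesions):
        matching = [c.score for c, a in zip(cand, assigned) if a == i]
        if matching:
            matched.append(True)
            scores.append(max(matching))
        else:
            matched.append(False)
            if calibrated_prob is not None:
                scores.append(float(np.asarray(calibrated_prob.data, dtype=float)[gt_masks[i]].max()))
            else:
                scores.append(0.0)
    fp_count = sum(1 for a in assigned if a is None)
    return DetectionOutcome(
        lesion_matched=tuple(matched),
        lesion_score=tuple(scores),
        lesion_is_cspca=tuple(bool(l) for _, l in gt_lesions),
        fp_count=fp_count,
        biopsy_negative=biopsy_negative,
    )


def detection_metrics(outcomes: list[DetectionOutcome], cutoff: float) -> dict:
    """Cohort lesion-level metrics at a score cut-off, in percent.

    Sensitivity over CSPCa lesions, specificity over nCSPCa lesions,
    precision over all lesions scored at/above the cut-off, and the
    false-positive mean over biopsy-negative patients.
    """
    scores = np.array([s for o in outcomes for s in o.lesion_score])
    is_cs = np.array([c for o in outcomes for c in o.lesion_is_cspca], dtype=bool)
    if is_cs.sum() == 0 or (~is_cs).sum() == 0:
        raise ValueError("cohort must contain both CSPCa and nCSPCa lesions")
    pos = scores >= cutoff
    tp = int((pos & is_cs).sum())
    fp_lesion = int((pos & ~is_cs).sum())
    sensitivity = 100.0 * tp / is_cs.sum()
    specificity = 100.0 * int((~pos & ~is_cs).sum()) / (~is_cs).sum()
    precision = 100.0 * tp / (tp + fp_lesion) if (tp + fp_lesion) else float("nan")
    negatives = [o.fp_count for o in outcomes if o.biopsy_negative]
    fp_per_neg = float(np.mean(negatives)) if negatives else float("nan")
    return {
        "sensitivity_pct": sensitivity,
        "specificity_pct": specificity,
        "precision_pct": precision,
        "fp_per_negative_patient": fp_per_neg,
    }


# --------------------------------------------------------------------------
# Score-based metrics
# --------------------------------------------------------------------------

def _check_two_classes(labels: np.ndarray) -> None:
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present")


def roc_auc(scores, labels) -> float:
    """ROC AUC; equals the normalized Mann–Whitney U with ties counted ½."""
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def pr_auc(scores, labels) -> float:
    """Average precision: the interpolation-free step integral over recall."""
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def select_cutoff(scores, labels, target_sensitivity: float, target_specificity: float) -> float:
    """Threshold (at an observed score) best matching a target operating
    point; sensitivity targeted first, specificity breaks ties. Targets in
    percent."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    _check_two_classes(y)
    best_t, best_key = None, None
    for t in np.unique(s):
        sens = 100.0 * (s[y] >= t).mean()
        spec = 100.0 * (s[~y] < t).mean()
        key = (abs(sens - target_sensitivity), abs(spec - target_specificity))
        if best_key is None or key < best_key:
            best_t, best_key = float(t), key
    return best_t


# --------------------------------------------------------------------------
# Paired statistical tests
# --------------------------------------------------------------------------

def wilcoxon_signed_rank(paired_a, paired_b) -> float:
    """Two-sided Wilcoxon signed-rank p on paired measurements.

    Zero differences are discarded; the exact null distribution is used
    for n <= 25 without ties, otherwise the normal approximation with
    continuity correction.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    ranks_tied = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not ranks_tied) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", correction=(method == "approx"), method=method)
    return float(res.pvalue)


def mcnemar(b01: int, b10: int) -> float:
    """Exact binomial two-sided McNemar p on discordant counts."""
    if b01 < 0 or b10 < 0:
        raise ValueError("discordant counts must be >= 0")
    n = b01 + b10
    if n == 0:
        return 1.0
    k = min(b01, b10)
    return float(min(1.0, 2.0 * stats.binom.cdf(k, n, 0.5)))


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong(scores_1, scores_2, labels) -> tuple[float, float, float]:
    """DeLong's paired test for two ROC AUCs over the same cases.

    Returns ``(auc_1, auc_2, p_value)``. The covariance of the paired AUC
    estimates is formed from the per-case structural components (placement
    values), giving the usual z-test on the AUC difference.
    """
    y = np.asarray(labels, dtype=bool)
    _check_two_classes(y)
    s = np.stack([np.asarray(scores_1, dtype=float), np.asarray(scores_2, dtype=float)])
    m, n = int(y.sum()), int((~y).sum())

    aucs = np.empty(2)
    v_pos = np.empty((2, m))  # V10: per-positive placement values
    v_neg = np.empty((2, n))  # V01: per-negative placement values
    for k in range(2):
        pos, neg = s[k][y], s[k][~y]
        all_r = _midrank(np.concatenate([pos, neg]))
        pos_r, neg_r = _midrank(pos), _midrank(neg)
        aucs[k] = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        v_pos[k] = (all_r[:m] - pos_r) / n
        v_neg[k] = 1.0 - (all_r[m:] - neg_r) / m

    s10 = np.cov(v_pos)
    s01 = np.cov(v_neg)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = aucs[0] - aucs[1]
    if var_diff <= 0:
        if diff == 0:
            return float(aucs[0]), float(aucs[1]), 1.0
        raise ValueError("degenerate variance in DeLong test")
    z = diff / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(aucs[0]), float(aucs[1]), float(p)


def wgs_precision_test(calls_a, calls_b, truth) -> float:
    """Paired comparison of two raters' precision (positive predictive
    fraction) over the same lesions.

    A generalized-score style z-test: each rater's precision is a ratio of
    means over the shared lesion list, its sampling variability estimated
    from per-lesion influence contributions, with the paired covariance
    retained. Returns the two-sided p-value.
    """
    ca = np.asarray(calls_a, dtype=float)
    cb = np.asarray(calls_b, dtype=float)
    y = np.asarray(truth, dtype=float)
    if not (ca.shape == cb.shape == y.shape):
        raise ValueError("calls and truth must have equal length")
    n = ca.size
    if ca.sum() == 0 and cb.sum() == 0:
        raise ValueError("neither rater made a positive call")
    if ca.sum() == 0 or cb.sum() == 0:
        raise ValueError("a rater with no positive calls has undefined precision")

    ppv_a = (ca * y).sum() / ca.sum()
    ppv_b = (cb * y).sum() / cb.sum()
    # influence function of a ratio-of-means estimator
    psi_a = ca * (y - ppv_a) / ca.mean()
    psi_b = cb * (y - ppv_b) / cb.mean()
    diff = ppv_a - ppv_b
    var = np.var(psi_a - psi_b, ddof=1) / n
    if var <= 0:
        return 1.0 if diff == 0 else 0.0
    z = diff / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def concordance(binary_calls_a, binary_calls_b) -> tuple[int, int, int]:
    """Percent agreement (rounded to integer) with raw counts."""
    a = np.asarray(binary_calls_a)
    b = np.asarray(binary_calls_b)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("call vectors must be non-empty and equal length")
    agree = int((a == b).sum())
    return int(round(100.0 * agree / a.size)), agree, int(a.size)
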