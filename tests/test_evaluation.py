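"""Metrics and paired statistics, validated against enumeration,
brute-force and simulation oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy import stats

from autoprostate.core_io import VoxelGrid
from autoprostate.evaluation import (
    abs_pct_err,
    concordance,
    delong,
    detection_metrics,
    dice,
    ellipsoid_volume,
    lesion_dice_contoured_slices,
    match_detections,
    mcnemar,
    pr_auc,
    roc_auc,
    select_cutoff,
    wgs_precision_test,
    wilcoxon_signed_rank,
)
from autoprostate.postprocess import ComponentCandidate


def _mask(arr, spacing=(1.0, 1.0, 1.0)):
    return VoxelGrid(np.asarray(arr, dtype=np.uint8), spacing=spacing)


class TestDice:
    def test_identical_and_disjoint(self):
        a = np.zeros((8, 8, 4), np.uint8)
        a[2:5, 2:5, 1:3] = 1
        b = np.zeros_like(a)
        b[5:8, 5:8, 1:3] = 1
        assert dice(_mask(a), _mask(a)) == 1.0
        assert dice(_mask(a), _mask(b)) == 0.0

    def test_half_overlap(self):
        a = np.zeros((20, 10, 1), np.uint8)
        b = np.zeros_like(a)
        a[0:10, 0:10, 0] = 1  # 100 voxels
        b[5:15, 0:10, 0] = 1  # 100 voxels, 50 shared
        assert dice(_mask(a), _mask(b)) == pytest.approx(0.5)

    def test_both_empty_is_one(self):
        z = np.zeros((4, 4, 2), np.uint8)
        assert dice(_mask(z), _mask(z)) == 1.0

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(_mask(np.zeros((4, 4, 2))), _mask(np.zeros((4, 4, 3))))


class TestContouredSliceDice:
    def test_exact_match(self):
        g = np.zeros((6, 6, 4), np.uint8)
        g[2:4, 2:4, 1:3] = 1
        assert lesion_dice_contoured_slices(_mask(g), _mask(g)) == 1.0

    def test_extra_voxels_off_contoured_slices_ignored(self):
        g = np.zeros((6, 6, 4), np.uint8)
        g[2:4, 2:4, 1] = 1
        p = g.copy()
        p[0:3, 0:3, 3] = 1  # slice 3 has no ground-truth contour
        assert lesion_dice_contoured_slices(_mask(p), _mask(g)) == 1.0

    def test_two_slice_hand_computation(self):
        g = np.zeros((4, 4, 3), np.uint8)
        p = np.zeros_like(g)
        g[0:2, 0:2, 0] = 1  # 4 voxels
        p[0:2, 0:1, 0] = 1  # 2 voxels, both inside g
        g[0:2, 0:2, 1] = 1  # 4 voxels
        p[0:2, 0:2, 1] = 1  # full overlap
        # dice = 2*(2+4) / (6 + 8) = 12/14
        assert lesion_dice_contoured_slices(_mask(p), _mask(g)) == pytest.approx(12 / 14)

    def test_empty_gt_rejected(self):
        with pytest.raises(ValueError):
            lesion_dice_contoured_slices(_mask(np.zeros((4, 4, 2))), _mask(np.zeros((4, 4, 2))))


class TestScalarMetrics:
    @pytest.mark.parametrize("est,truth,expected", [(50, 50, 0.0), (45, 50, 10.0), (100, 50, 100.0)])
    def test_abs_pct_err(self, est, truth, expected):
        assert abs_pct_err(est, truth) == pytest.approx(expected)

    def test_abs_pct_err_zero_truth_rejected(self):
        with pytest.raises(ValueError):
            abs_pct_err(1.0, 0.0)

    def test_ellipsoid_formula(self):
        assert ellipsoid_volume(4, 3, 5) == pytest.approx(10 * np.pi)
        assert ellipsoid_volume(1, 1, 1) == pytest.approx(np.pi / 6)

    def test_ellipsoid_matches_phantom_analytic(self, plain_phantom):
        d = [2 * s / 10 for s in plain_phantom.spec.wp_semi_axes]  # diameters, cm
        assert ellipsoid_volume(*d) == pytest.approx(plain_phantom.analytic["wp_volume_cm3"])

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            ellipsoid_volume(0.0, 1.0, 1.0)


class TestMatchDetections:
    def _scene(self):
        gt1 = np.zeros((20, 20, 6), np.uint8)
        gt1[2:8, 2:8, 1:4] = 1
        gt2 = np.zeros_like(gt1)
        gt2[12:18, 12:18, 2:5] = 1
        return gt1, gt2

    def test_single_tp_no_fp(self):
        gt1, gt2 = self._scene()
        cand = ComponentCandidate(mask=_mask(gt1), score=0.9)
        out = match_detections([cand], [(_mask(gt1), True)])
        assert out.lesion_matched == (True,)
        assert out.lesion_score == (0.9,)
        assert out.fp_count == 0

    def test_two_candidates_one_lesion(self):
        gt1, _ = self._scene()
        c1 = np.zeros_like(gt1)
        c1[2:5, 2:5, 1:3] = 1
        c2 = np.zeros_like(gt1)
        c2[5:8, 5:8, 2:4] = 1
        out = match_detections(
            [ComponentCandidate(_mask(c1), 0.6), ComponentCandidate(_mask(c2), 0.8)],
            [(_mask(gt1), True)],
        )
        assert out.lesion_matched == (True,)
        assert out.lesion_score == (0.8,)  # max over matching candidates
        assert out.fp_count == 0

    def test_candidate_assigned_to_greatest_overlap(self):
        gt1, gt2 = self._scene()
        cand = np.zeros_like(gt1)
        cand[5:14, 5:14, 2:4] = 1  # overlaps gt1 on 3x3, gt2 on 2x2 per slice
        out = match_detections(
            [ComponentCandidate(_mask(cand), 0.7)],
            [(_mask(gt1), True), (_mask(gt2), False)],
        )
        assert out.lesion_matched == (True, False)

    def test_unmatched_candidate_is_fp_and_negative_restriction(self):
        gt1, gt2 = self._scene()
        stray = np.zeros_like(gt1)
        stray[0:3, 15:18, 0:2] = 1
        cand = ComponentCandidate(_mask(stray), 0.5)
        neg = match_detections([cand], [], biopsy_negative=True)
        pos = match_detections([cand], [(_mask(gt1), True)], biopsy_negative=False)
        assert neg.fp_count == 1 and neg.biopsy_negative
        assert pos.fp_count == 1 and not pos.biopsy_negative
        m = detection_metrics(
            [neg, pos, match_detections([], [(_mask(gt2), False)])], cutoff=0.045
        )
        assert m["fp_per_negative_patient"] == 1.0  # positive patient excluded

    def test_unmatched_gt_scored_from_probability_map(self):
        gt1, _ = self._scene()
        prob = VoxelGrid(np.zeros(gt1.shape))
        arr = prob.data.copy()
        arr[gt1 > 0] = 0.33
        out = match_detections([], [(_mask(gt1), True)], calibrated_prob=prob.with_data(arr))
        assert out.lesion_score == (0.33,)
        out_no_prob = match_detections([], [(_mask(gt1), True)])
        assert out_no_prob.lesion_score == (0.0,)

    def test_matching_equals_brute_force_on_toy_set(self, rng):
        """Greedy per-candidate greatest-overlap assignment equals direct
        enumeration of overlaps on random toy scenes."""
        for trial in range(5):
            shape = (16, 16, 4)
            gts = []
            for _ in range(3):
                m = np.zeros(shape, np.uint8)
                x, y = rng.integers(0, 10, 2)
                m[x : x + 6, y : y + 6, 1:3] = 1
                gts.append(m)
            cands = []
            for _ in range(3):
                m = np.zeros(shape, np.uint8)
                x, y = rng.integers(0, 10, 2)
                m[x : x + 5, y : y + 5, 1:3] = 1
                cands.append(m)
            out = match_detections(
                [ComponentCandidate(_mask(c), 0.5) for c in cands],
                [(_mask(g), True) for g in gts],
            )
            # brute force: each GT is matched iff some candidate's argmax-overlap GT is it
            sizes = [g.sum() for g in gts]
            matched = set()
            fp = 0
            for c in cands:
                ovl = [int((c & g).sum()) for g in gts]
                if max(ovl) == 0:
                    fp += 1
                    continue
                top = max(ovl)
                tied = [i for i, o in enumerate(ovl) if o == top]
                matched.add(max(tied, key=lambda i: sizes[i]))
            assert out.fp_count == fp
            assert tuple(i in matched for i in range(3)) == out.lesion_matched


class TestDetectionMetrics:
    def _outcome(self, scores, labels, fp=0, neg=False):
        from autoprostate.evaluation import DetectionOutcome

        return DetectionOutcome(
            lesion_matched=tuple(s > 0 for s in scores),
            lesion_score=tuple(scores),
            lesion_is_cspca=tuple(labels),
            fp_count=fp,
            biopsy_negative=neg,
        )

    def test_perfect_separation(self):
        o = self._outcome([1.0, 1.0, 0.0, 0.0], [True, True, False, False])
        m = detection_metrics([o], cutoff=0.5)
        assert m["sensitivity_pct"] == 100.0
        assert m["specificity_pct"] == 100.0
        assert m["precision_pct"] == 100.0

    def test_cutoff_boundaries(self):
        o = self._outcome([0.9, 0.2, 0.8, 0.1], [True, True, False, False])
        assert detection_metrics([o], cutoff=0.0)["sensitivity_pct"] == 100.0
        assert detection_metrics([o], cutoff=0.0)["specificity_pct"] == 0.0
        assert detection_metrics([o], cutoff=1.1)["sensitivity_pct"] == 0.0

    def test_toy_cohort_equals_exhaustive_count(self, rng):
        scores = rng.uniform(0, 1, 10)
        labels = rng.uniform(size=10) < 0.5
        labels[0], labels[1] = True, False  # both strata non-empty
        o = self._outcome(scores, labels)
        cutoff = 0.5
        m = detection_metrics([o], cutoff=cutoff)
        tp = sum(1 for s, l in zip(scores, labels) if l and s >= cutoff)
        fn = sum(1 for s, l in zip(scores, labels) if l and s < cutoff)
        fp = sum(1 for s, l in zip(scores, labels) if not l and s >= cutoff)
        tn = sum(1 for s, l in zip(scores, labels) if not l and s < cutoff)
        assert m["sensitivity_pct"] == pytest.approx(100 * tp / (tp + fn))
        assert m["specificity_pct"] == pytest.approx(100 * tn / (tn + fp))
        if tp + fp:
            assert m["precision_pct"] == pytest.approx(100 * tp / (tp + fp))

    def test_single_stratum_rejected(self):
        o = self._outcome([0.9, 0.8], [True, True])
        with pytest.raises(ValueError):
            detection_metrics([o], cutoff=0.5)


class TestRankingMetrics:
    def test_perfect_and_tied_auc(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_auc_equals_pairwise_enumeration(self, rng):
        scores = rng.uniform(0, 1, 6)
        labels = np.array([1, 1, 0, 0, 0, 1])
        wins = ties = 0
        for i in np.flatnonzero(labels == 1):
            for j in np.flatnonzero(labels == 0):
                wins += scores[i] > scores[j]
                ties += scores[i] == scores[j]
        expected = (wins + 0.5 * ties) / (labels.sum() * (1 - labels).sum())
        assert roc_auc(scores, labels) == pytest.approx(expected)

    def test_auc_invariant_under_monotone_transform(self, rng):
        scores = rng.uniform(0, 1, 50)
        labels = rng.uniform(size=50) < 0.4
        labels[:2] = [True, False]
        a = roc_auc(scores, labels)
        b = roc_auc(np.exp(3 * scores) - 1, labels)
        assert a == pytest.approx(b, abs=1e-12)

    def test_pr_auc_step_integral(self):
        scores = [0.9, 0.7, 0.5, 0.3]
        labels = [1, 0, 1, 0]
        # recall steps at the two positives: P=1 at recall 1/2, P=2/3 at recall 1
        expected = 0.5 * 1.0 + 0.5 * (2 / 3)
        assert pr_auc(scores, labels) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])
        with pytest.raises(ValueError):
            pr_auc([0.1, 0.2], [0, 0])


class TestSelectCutoff:
    def test_exact_operating_point_returned(self):
        scores = [0.9, 0.8, 0.7, 0.3, 0.2, 0.1]
        labels = [1, 1, 1, 0, 0, 0]
        t = select_cutoff(scores, labels, target_sensitivity=100.0, target_specificity=100.0)
        assert t == pytest.approx(0.7)

    def test_monotone_scores_hit_target_within_resolution(self, rng):
        n = 40
        scores = np.sort(rng.uniform(0, 1, n))
        labels = np.zeros(n, bool)
        labels[n // 2 :] = True  # perfectly monotone relation
        t = select_cutoff(scores, labels, target_sensitivity=93.0, target_specificity=37.0)
        sens = 100.0 * (scores[labels] >= t).mean()
        assert abs(sens - 93.0) <= 100.0 / labels.sum()

    def test_degenerate_equal_scores_boundary(self):
        t = select_cutoff([0.5] * 6, [1, 1, 1, 0, 0, 0], 93.0, 37.0)
        assert t == 0.5  # only observable threshold


def _exact_wilcoxon_enumeration(d):
    """Two-sided p by enumerating all sign assignments of |d| ranks."""
    d = np.asarray(d, float)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws)
    p_low = (ws <= w_obs).mean()
    p_high = (ws >= w_obs).mean()
    return min(1.0, 2 * min(p_low, p_high))


class TestWilcoxon:
    def test_constant_shift_strongly_significant(self, rng):
        a = rng.normal(0, 1, 20)
        assert wilcoxon_signed_rank(a + 2.0, a) < 0.001

    def test_symmetric_in_arguments(self, rng):
        a, b = rng.normal(0, 1, 15), rng.normal(0.3, 1, 15)
        assert wilcoxon_signed_rank(a, b) == pytest.approx(wilcoxon_signed_rank(b, a))

    def test_n6_exact_equals_enumeration(self):
        d = np.array([1.3, -0.4, 2.2, 0.7, -1.8, 0.2])
        p = wilcoxon_signed_rank(d, np.zeros(6))
        assert p == pytest.approx(_exact_wilcoxon_enumeration(d), abs=1e-12)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])


class TestMcNemar:
    def test_symmetric_discordance_is_one(self):
        assert mcnemar(7, 7) == 1.0
        assert mcnemar(0, 0) == 1.0

    def test_hand_computed_binomial_sum(self):
        # 2 * sum_{k<=2} C(12,k) / 2^12 = 158/4096
        assert mcnemar(10, 2) == pytest.approx(158 / 4096, abs=1e-12)

    @pytest.mark.parametrize("b01,b10", [(5, 1), (8, 3), (12, 0), (6, 6)])
    def test_matches_exhaustive_enumeration(self, b01, b10):
        n = b01 + b10
        outcomes = np.array([bin(i).count("1") for i in range(2**n)])
        k_obs = min(b01, b10)
        p_enum = min(1.0, 2 * (outcomes <= k_obs).mean())
        assert mcnemar(b01, b10) == pytest.approx(p_enum, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            mcnemar(-1, 2)


def _bootstrap_auc_diff_p(s1, s2, labels, reps, seed):
    """Stratified-bootstrap z-test on the AUC difference (oracle)."""
    rng = np.random.default_rng(seed)
    y = np.asarray(labels, bool)
    pos, neg = np.flatnonzero(y), np.flatnonzero(~y)
    s = np.stack([s1, s2])

    def auc(scores, pi, ni):
        p = scores[pi][:, None]
        n = scores[ni][None, :]
        return ((p > n).mean() + 0.5 * (p == n).mean())

    obs = auc(s[0], pos, neg) - auc(s[1], pos, neg)
    diffs = np.empty(reps)
    for r in range(reps):
        pi = rng.choice(pos, size=pos.size, replace=True)
        ni = rng.choice(neg, size=neg.size, replace=True)
        diffs[r] = auc(s[0], pi, ni) - auc(s[1], pi, ni)
    z = obs / diffs.std(ddof=1)
    return 2 * stats.norm.sf(abs(z))


class TestDeLong:
    def _paired_scores(self, seed=0, n_pos=20, n_neg=30):
        rng = np.random.default_rng(seed)
        labels = np.r_[np.ones(n_pos, bool), np.zeros(n_neg, bool)]
        latent = rng.normal(0, 1, labels.size) + 1.1 * labels
        s1 = latent + rng.normal(0, 0.6, labels.size)
        s2 = 0.8 * latent + rng.normal(0, 0.9, labels.size)
        return s1, s2, labels

    def test_identical_scores_p_one(self):
        s1, _, labels = self._paired_scores()
        a1, a2, p = delong(s1, s1, labels)
        assert a1 == a2 and p == 1.0

    def test_monotone_transform_same_auc(self):
        s1, _, labels = self._paired_scores()
        a1, a2, p = delong(s1, np.exp(s1), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)
        assert p == 1.0

    def test_auc_matches_mann_whitney(self):
        s1, s2, labels = self._paired_scores()
        a1, _, _ = delong(s1, s2, labels)
        assert a1 == pytest.approx(roc_auc(s1, labels), abs=1e-12)

    def test_p_close_to_bootstrap_oracle(self):
        s1, s2, labels = self._paired_scores(seed=0, n_pos=20, n_neg=30)
        _, _, p = delong(s1, s2, labels)
        p_boot = _bootstrap_auc_diff_p(s1, s2, labels, reps=10_000, seed=1)
        assert abs(p - p_boot) <= 0.02


class TestWgsPrecision:
    def test_identical_decisions_p_one(self, rng):
        truth = rng.uniform(size=60) < 0.5
        calls = rng.uniform(size=60) < 0.6
        calls[0] = True
        assert wgs_precision_test(calls, calls, truth) == 1.0

    def test_no_positive_calls_rejected(self):
        with pytest.raises(ValueError):
            wgs_precision_test([0, 0], [0, 0], [1, 0])

    def test_power_when_one_rater_strictly_better(self):
        """A rater with clearly higher precision is flagged in >= 80% of
        replicates at n=200 lesions."""
        rng = np.random.default_rng(99)
        hits = 0
        reps = 100
        for _ in range(reps):
            truth = rng.uniform(size=200) < 0.6
            calls_a = np.where(truth, rng.uniform(size=200) < 0.8, rng.uniform(size=200) < 0.2)
            calls_b = rng.uniform(size=200) < 0.5
            if wgs_precision_test(calls_a, calls_b, truth) < 0.05:
                hits += 1
        assert hits / reps >= 0.8


class TestConcordance:
    def test_published_style_fractions(self):
        a = np.zeros(147, int)
        b = np.zeros(147, int)
        b[:33] = 1  # 33 disagreements -> 114/147 agree
        pct, num, den = concordance(a, b)
        assert (pct, num, den) == (78, 114, 147)

        a = np.zeros(63, int)
        b = np.zeros(63, int)
        b[:24] = 1  # 39/63 agree
        assert concordance(a, b) == (62, 39, 63)

    def test_identical_vectors(self):
        assert concordance([1, 0, 1], [1, 0, 1]) == (100, 3, 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            concordance([1, 0], [1])
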