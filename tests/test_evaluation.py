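"""OKS, AP, mAP, precision/recall, and prediction-to-truth matching."""

import itertools
import math

import numpy as np
import pytest

from bovimetry.evaluation import (
    OKSConfig,
    UndefinedOKSError,
    ap_at_threshold,
    ap_improvement_pp,
    evaluate,
    exhaustive_best_matching,
    match_predictions,
    mean_ap,
    oks,
    precision_recall,
)
from bovimetry.phantom import calibrated_jitter, perturb_keypoints

from .conftest import make_keypoint_set

CFG = OKSConfig()


class TestOKS:
    def test_exact_prediction_scores_one(self, square_keypoints):
        assert oks(square_keypoints, square_keypoints, CFG) == pytest.approx(1.0)

    def test_single_keypoint_at_calibrated_distance_scores_exp_minus_one(self):
        s = math.sqrt(10000.0)
        sigma = 0.05
        d = math.sqrt(2.0) * s * sigma
        gt = make_keypoint_set([[50, 50]] * 6, visibility=[2, 0, 0, 0, 0, 0])
        pred = make_keypoint_set([[50 + d, 50]] * 6, visibility=[2, 0, 0, 0, 0, 0])
        assert oks(pred, gt, CFG) == pytest.approx(math.exp(-1), abs=1e-12)

    def test_one_exact_one_infinitely_far_averages_to_half(self):
        gt = make_keypoint_set([[50, 50], [80, 80]] + [[0, 0]] * 4,
                               visibility=[2, 2, 0, 0, 0, 0])
        pred = make_keypoint_set([[50, 50], [1e9, 1e9]] + [[0, 0]] * 4,
                                 visibility=[2, 2, 0, 0, 0, 0])
        assert oks(pred, gt, CFG) == pytest.approx(0.5)

    def test_no_visible_ground_truth_is_undefined(self, square_keypoints):
        gt = make_keypoint_set(square_keypoints.as_array(), bbox_area=0.0,
                               visibility=[0] * 6)
        with pytest.raises(UndefinedOKSError):
            oks(square_keypoints, gt, CFG)

    def test_translation_of_both_sets_leaves_oks_unchanged(self, square_keypoints):
        pred = perturb_keypoints(square_keypoints, sd_px=3.0, seed=4)
        base = oks(pred, square_keypoints, CFG)
        shifted = oks(pred.translated(17.0, -9.0), square_keypoints.translated(17.0, -9.0), CFG)
        assert shifted == pytest.approx(base, abs=1e-12)

    def test_scaling_coordinates_and_area_leaves_oks_unchanged(self, square_keypoints):
        pred = perturb_keypoints(square_keypoints, sd_px=3.0, seed=4)
        base = oks(pred, square_keypoints, CFG)
        k = 2.5
        gt_s = make_keypoint_set(square_keypoints.as_array() * k,
                                 bbox_area=square_keypoints.bbox_area * k**2)
        pred_s = make_keypoint_set(pred.as_array() * k,
                                   bbox_area=pred.bbox_area * k**2)
        assert oks(pred_s, gt_s, CFG) == pytest.approx(base, abs=1e-12)

    def test_gaussian_jitter_at_sigma_s_has_mean_oks_one_half(self, square_keypoints):
        # With per-axis jitter sd a = s*sigma, d^2 ~ a^2 chi^2_2 and
        # E[exp(-d^2/(2 s^2 sigma^2))] = 1/(1 + a^2/(s^2 sigma^2)) = 1/2.
        s = math.sqrt(square_keypoints.bbox_area)
        a = s * 0.05
        vals = [oks(perturb_keypoints(square_keypoints, a, seed=i), square_keypoints, CFG)
                for i in range(4000)]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.01)

    def test_calibrated_fixed_radius_jitter_scores_exactly_exp_minus_one(self, square_keypoints):
        s = math.sqrt(square_keypoints.bbox_area)
        pred = calibrated_jitter(square_keypoints, CFG.sigmas, s, seed=3)
        assert oks(pred, square_keypoints, CFG) == pytest.approx(math.exp(-1), abs=1e-12)


class TestAPAndRates:
    def test_ap_counts_strict_exceedances(self):
        assert ap_at_threshold([0.9, 0.6, 0.3], 0.5) == pytest.approx(2 / 3)

    def test_all_above_threshold_saturates_at_one(self):
        assert ap_at_threshold([0.8, 0.9], 0.5) == 1.0

    def test_value_equal_to_threshold_is_not_counted(self):
        assert ap_at_threshold([0.5], 0.5) == 0.0

    def test_ap_is_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            vals = rng.random(rng.integers(1, 50))
            aps = [ap_at_threshold(vals, t) for t in np.linspace(0.05, 0.95, 19)]
            assert all(a >= b for a, b in zip(aps, aps[1:]))

    def test_mean_ap_is_the_arithmetic_mean(self):
        assert mean_ap([0.8, 0.6]) == pytest.approx(0.7)
        assert mean_ap([0.42]) == 0.42

    def test_threshold_grid_has_ten_values(self):
        assert len(CFG.thresholds) == 10
        assert CFG.thresholds[0] == 0.50 and CFG.thresholds[-1] == 0.95

    def test_empty_lists_are_errors(self):
        with pytest.raises(ValueError):
            ap_at_threshold([], 0.5)
        with pytest.raises(ValueError):
            mean_ap([])

    def test_precision_recall_arithmetic(self):
        p, r, flags = precision_recall(8, 2, 2)
        assert (p, r) == (0.8, 0.8) and not flags

    def test_zero_over_zero_is_zero_with_flag(self):
        p, r, flags = precision_recall(0, 0, 5)
        assert p == 0.0 and flags.get("precision_undefined")

    def test_perfect_detector(self):
        p, r, flags = precision_recall(10, 0, 0)
        assert p == r == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            precision_recall(-1, 0, 0)

    def test_ap_improvement_reproduces_model_comparison_deltas(self):
        assert ap_improvement_pp(0.9310, 0.9096) == 2.14
        assert ap_improvement_pp(0.8680, 0.8371) == 3.09


class TestMatching:
    def test_single_pair_matches_without_fp_or_fn(self, square_keypoints):
        res = match_predictions([square_keypoints], [square_keypoints], CFG)
        assert res.pairs == [(0, 0)]
        assert not res.unmatched_preds and not res.unmatched_gts
        assert res.fp == 0 and res.fn == 0 and res.tp == 6

    def test_surplus_prediction_is_a_false_positive(self, square_keypoints):
        far = make_keypoint_set(square_keypoints.as_array() + 500.0)
        res = match_predictions([square_keypoints, far], [square_keypoints], CFG)
        assert len(res.pairs) == 1 and len(res.unmatched_preds) == 1
        assert res.fp >= 6  # the surplus instance's keypoints

    def test_missed_ground_truth_is_a_false_negative(self, square_keypoints):
        res = match_predictions([], [square_keypoints], CFG)
        assert res.unmatched_gts == [0] and res.fn == 6

    @pytest.mark.parametrize("n_pred,n_gt", [(1, 1), (2, 2), (3, 3), (2, 3), (3, 2)])
    def test_greedy_matching_agrees_with_exhaustive_enumeration(self, n_pred, n_gt,
                                                                square_keypoints):
        """Each prediction targets a distinct well-separated instance (surplus
        predictions are far from everything), so the greedy assignment must
        attain the exhaustively enumerated maximum total OKS."""
        rng = np.random.default_rng(n_pred * 10 + n_gt)
        gts = [make_keypoint_set(square_keypoints.as_array() + 400.0 * i)
               for i in range(n_gt)]
        preds = []
        for i in range(n_pred):
            if i < n_gt:
                coords = gts[i].as_array() + rng.normal(0, 8, (6, 2))
            else:
                coords = square_keypoints.as_array() + 1e6  # spurious detection
            preds.append(make_keypoint_set(coords, confidence=[1.0 - 0.1 * i] * 6))
        res = match_predictions(preds, gts, CFG)
        best = exhaustive_best_matching(preds, gts, CFG)
        assert sum(res.oks_values) == pytest.approx(best, abs=1e-9)


class TestEvaluate:
    def test_perfect_predictions_score_perfectly(self, square_keypoints):
        gts = [square_keypoints, make_keypoint_set(square_keypoints.as_array() + 300.0)]
        summary = evaluate(gts, gts, CFG)
        assert summary.ap50 == 1.0
        assert summary.map_thresholds == 1.0
        assert summary.precision == summary.recall == 1.0
        assert summary.tp == 12 and summary.fp == 0 and summary.fn == 0

    def test_tp_plus_fn_equals_ground_truth_keypoints(self, square_keypoints):
        gts = [square_keypoints, make_keypoint_set(square_keypoints.as_array() + 300.0)]
        preds = [perturb_keypoints(gts[0], 6.0, seed=1)]  # one instance missed
        summary = evaluate(preds, gts, CFG)
        assert summary.tp + summary.fn == sum(g.visible_count() for g in gts)
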