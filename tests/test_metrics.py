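"""Bipartite matching, the 15 um criterion, border exclusion and coherence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from somaloc.core import CellCenters
from somaloc.metrics import (
    RawMatching,
    annotator_coherence,
    classify_matches,
    evaluate,
    exclude_border,
    f1_from_percent,
    match_centers,
    match_total_weight_bruteforce,
    stereology_crop_alignment,
)


def um(points):
    return CellCenters(np.asarray(points, dtype=float), space="um")


class TestMatchCenters:
    def test_identical_single_point(self):
        raw = match_centers(um([[0, 0, 0]]), um([[0, 0, 0]]))
        assert len(raw.pairs) == 1
        assert raw.distances_um[0] == 0.0

    def test_minimum_weight_beats_crossing_assignment(self):
        gt = um([[0, 0, 0], [0, 0, 4]])
        pred = um([[0, 0, 3], [0, 0, 5]])
        raw = match_centers(gt, pred)
        # optimal: 0<->3 and 4<->5, total 4 (crossing would cost 6)
        assert raw.distances_um.sum() == pytest.approx(4.0)
        assert {tuple(p) for p in raw.pairs} == {(0, 0), (1, 1)}

    def test_surplus_prediction_stays_unmatched(self):
        raw = match_centers(um([[0, 0, 0]]), um([[1, 0, 0], [100, 0, 0]]))
        assert len(raw.pairs) == 1
        assert raw.pairs[0][1] == 0
        assert list(raw.unmatched_pred) == [1]

    def test_empty_sets_allowed(self):
        raw = match_centers(um([]), um([[1, 2, 3]]))
        assert len(raw.pairs) == 0
        assert list(raw.unmatched_pred) == [0]

    @given(st.integers(0, 6), st.integers(0, 6), st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_total_weight_matches_bruteforce(self, n, m, seed):
        r = np.random.default_rng(seed)
        gt = r.uniform(0, 50, size=(n, 3))
        pred = r.uniform(0, 50, size=(m, 3))
        raw = match_centers(um(gt), um(pred))
        assert raw.distances_um.sum() == pytest.approx(
            match_total_weight_bruteforce(gt, pred), abs=1e-8
        )


class TestClassify:
    def test_pair_just_below_threshold_is_tp(self):
        raw = RawMatching(np.array([[0, 0]]), np.array([14.9]), np.array([], int), np.array([], int))
        rep = classify_matches(raw)
        assert (rep.tp, rep.fp, rep.fn) == (1, 0, 0)

    def test_pair_at_threshold_is_fp_plus_fn(self):
        raw = RawMatching(np.array([[0, 0]]), np.array([15.0]), np.array([], int), np.array([], int))
        rep = classify_matches(raw)
        assert (rep.tp, rep.fp, rep.fn) == (0, 1, 1)

    def test_formula_arithmetic(self):
        raw = RawMatching(
            np.array([[0, 0], [1, 1]]), np.array([1.0, 20.0]),
            np.array([2, 3], int), np.array([], int),
        )
        rep = classify_matches(raw)
        assert (rep.tp, rep.fp, rep.fn) == (1, 1, 3)
        assert rep.precision == pytest.approx(50.0)
        assert rep.recall == pytest.approx(25.0)
        assert rep.f1 == pytest.approx(100 / 3, abs=0.05)

    def test_both_empty_is_flagged_perfect(self):
        raw = RawMatching(np.empty((0, 2), int), np.empty(0), np.array([], int), np.array([], int))
        rep = classify_matches(raw)
        assert rep.f1 == 100.0 and rep.degenerate

    def test_one_side_empty_is_zero(self):
        raw = RawMatching(np.empty((0, 2), int), np.empty(0), np.array([0], int), np.array([], int))
        rep = classify_matches(raw)
        assert rep.f1 == 0.0 and rep.degenerate


class TestExcludeBorder:
    def _raw(self, gt, pred):
        return match_centers(gt, pred, 1.0)

    def test_frame_boundary_semantics(self):
        shape = (100, 100, 100)
        gt = CellCenters([[5.0, 50, 50], [6.0, 50, 50], [93.0, 50, 50], [94.0, 50, 50]])
        pred = CellCenters(np.empty((0, 3)))
        raw = self._raw(gt, pred)
        filtered, ex_gt, _ = exclude_border(gt, pred, raw, shape, 6)
        kept = set(filtered.unmatched_gt)
        assert kept == {1, 2}  # index 6 kept, 5 removed; 93 kept (< 94), 94 removed
        assert ex_gt == 2

    def test_dissolved_pair_leaves_unmatched_partner(self):
        shape = (100, 100, 100)
        gt = CellCenters([[50.0, 50, 50]])
        pred = CellCenters([[3.0, 50, 50]])  # in frame
        raw = self._raw(gt, pred)
        filtered, _, ex_pred = exclude_border(gt, pred, raw, shape, 6)
        assert ex_pred == 1
        assert list(filtered.unmatched_gt) == [0]
        assert len(filtered.pairs) == 0

    def test_frame_swallowing_volume_raises(self):
        gt = CellCenters([[5.0, 5, 5]])
        with pytest.raises(ValueError):
            exclude_border(gt, gt, self._raw(gt, gt), (10, 10, 10), 6)


class TestEvaluate:
    def test_perfect_prediction_scores_100(self, rng):
        pts = rng.uniform(10, 54, size=(30, 3))
        gt = CellCenters(pts)
        rep = evaluate(gt, CellCenters(pts.copy()), (64, 64, 64), 3.6)
        assert rep.precision == rep.recall == rep.f1 == 100.0

    def test_f1_identity_from_published_precision_recall(self):
        # published cross-method comparison: P=69.0, R=84.4 => F1=75.9
        assert f1_from_percent(69.0, 84.4) == pytest.approx(75.9, abs=0.05)

    def test_small_jitter_keeps_f1_at_100(self):
        # 2 um jitter: P(||jitter|| >= 15 um) is negligible
        for seed in range(20):
            r = np.random.default_rng(seed)
            pts = r.uniform(8, 56, size=(200, 3))
            jit = pts + r.normal(0, 2 / 3.6, size=pts.shape)
            rep = evaluate(CellCenters(pts), CellCenters(jit), (64, 64, 64), 3.6)
            assert rep.f1 == 100.0

    def test_far_prediction_lowers_precision_only(self, rng):
        pts = rng.uniform(20, 40, size=(10, 3))
        base = evaluate(CellCenters(pts), CellCenters(pts.copy()), (64, 64, 64), 3.6)
        extra = np.vstack([pts, [[50.0, 50.0, 50.0]]])
        rep = evaluate(CellCenters(pts), CellCenters(extra), (64, 64, 64), 3.6)
        assert rep.precision < base.precision
        assert rep.recall == base.recall

    def test_role_swap_exchanges_p_and_r(self, rng):
        a = CellCenters(rng.uniform(8, 56, size=(25, 3)))
        b = CellCenters(rng.uniform(8, 56, size=(30, 3)))
        ab = evaluate(a, b, (64, 64, 64), 3.6)
        ba = evaluate(b, a, (64, 64, 64), 3.6)
        assert ab.precision == pytest.approx(ba.recall)
        assert ab.recall == pytest.approx(ba.precision)
        assert ab.f1 == pytest.approx(ba.f1)

    def test_tp_bounded_by_smaller_set(self, rng):
        a = CellCenters(rng.uniform(8, 56, size=(12, 3)))
        b = CellCenters(rng.uniform(8, 56, size=(40, 3)))
        rep = evaluate(a, b, (64, 64, 64), 3.6)
        assert rep.tp <= 12


class TestAnnotatorCoherence:
    def test_self_comparison_is_100(self, rng):
        pts = CellCenters(rng.uniform(8, 56, size=(20, 3)))
        rows, mean, sd = annotator_coherence([pts, pts], (64, 64, 64), 3.6)
        assert mean == 100.0

    def test_all_unordered_pairs(self, rng):
        sets = [CellCenters(rng.uniform(8, 56, size=(15, 3))) for _ in range(3)]
        rows, mean, sd = annotator_coherence(sets, (64, 64, 64), 3.6)
        assert len(rows) == 3


class TestCropAlignment:
    def test_shifted_window_arithmetic(self):
        pred = um([[7.0, 7.0, 7.0], [106.9, 7.0, 7.0], [107.0, 7.0, 7.0], [6.9, 7.0, 7.0]])
        pred = CellCenters(pred.points, space="voxel")
        out = stereology_crop_alignment(pred, (10, 10, 10), (100, 100, 100), (200, 200, 200), 3)
        # retained region [7, 107) per axis, half-open
        np.testing.assert_allclose(out.points[:, 0], [7.0, 106.9])

    def test_out_of_bounds_box_raises(self):
        pred = CellCenters(np.empty((0, 3)))
        with pytest.raises(ValueError):
            stereology_crop_alignment(pred, (1, 1, 1), (100, 100, 100), (100, 100, 100), 3)

    def test_empty_predictions_stay_empty(self):
        pred = CellCenters(np.empty((0, 3)))
        out = stereology_crop_alignment(pred, (10, 10, 10), (50, 50, 50), (100, 100, 100), 3)
        assert len(out) == 0
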