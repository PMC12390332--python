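"""Evaluation metrics: greedy matching, precision/recall conventions, and
AP against a brute-force precision-envelope oracle."""

import numpy as np
import pytest

from fbstrnet.metrics import (
    IOU_GRID,
    MatchResult,
    average_precision,
    evaluate,
    match_detections,
    mean_ap,
    precision_recall,
)
from fbstrnet.postfilter import Detection


def det(box, conf, cls=0):
    return Detection(*box, conf, cls)


def brute_force_ap(flags, n_gt):
    """Envelope integration by direct scan over every recall level."""
    flags = np.asarray(flags, dtype=bool)
    if n_gt == 0 or flags.size == 0:
        return 0.0
    tp = np.cumsum(flags)
    fp = np.cumsum(~flags)
    rec = tp / n_gt
    pre = tp / (tp + fp)
    # precision envelope: best precision at recall >= r
    ap = 0.0
    prev_r = 0.0
    for r in np.unique(rec):
        p_env = pre[rec >= r].max() if np.any(rec >= r) else 0.0
        ap += (r - prev_r) * p_env
        prev_r = r
    return float(ap)


class TestMatching:
    def test_single_true_positive(self):
        m = match_detections([det((0, 0, 10, 10), 0.9)], [det((1, 1, 10, 10), 1.0)])
        assert (m.tp, m.fp, m.fn) == (1, 0, 0)

    def test_duplicate_is_false_positive(self):
        dets = [det((0, 0, 10, 10), 0.9), det((0, 0, 10, 11), 0.8)]
        m = match_detections(dets, [det((0, 0, 10, 10), 1.0)])
        assert (m.tp, m.fp, m.fn) == (1, 1, 0)
        assert m.tp_flags.tolist() == [True, False]  # higher conf wins the GT

    def test_low_iou_is_false_positive(self):
        m = match_detections([det((0, 0, 2, 2), 0.9)], [det((5, 5, 9, 9), 1.0)])
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)

    def test_each_gt_matched_at_most_once(self, rng):
        for _ in range(50):
            nd, ng = int(rng.integers(0, 8)), int(rng.integers(0, 5))
            dets = [
                det((x, y, x + rng.uniform(1, 6), y + rng.uniform(1, 6)), rng.uniform())
                for x, y in rng.uniform(0, 15, (nd, 2))
            ]
            gts = [
                det((x, y, x + rng.uniform(1, 6), y + rng.uniform(1, 6)), 1.0)
                for x, y in rng.uniform(0, 15, (ng, 2))
            ]
            m = match_detections(dets, gts, 0.3)
            assert m.tp <= min(nd, ng)
            assert m.tp + m.fn == ng
            assert m.tp + m.fp == nd


class TestPrecisionRecall:
    @pytest.mark.parametrize(
        "tp,fp,fn,expected",
        [(8, 2, 0, (0.8, 1.0)), (0, 0, 5, (0.0, 0.0)), (2, 1, 2, (2 / 3, 0.5))],
    )
    def test_ratios_and_zero_denominator_convention(self, tp, fp, fn, expected):
        flags = np.array([True] * tp + [False] * fp, dtype=bool)
        m = MatchResult(tp_flags=flags, conf=np.linspace(1, 0.5, len(flags)), n_gt=tp + fn)
        assert precision_recall(m) == pytest.approx(expected)


class TestAveragePrecision:
    def test_perfect_ranking(self):
        assert average_precision([True, True, True], 3).ap == pytest.approx(1.0)

    def test_worked_example(self):
        # 2 GT, ranked [TP, FP, TP]: 0.5*1 + 0.5*(2/3)
        ap = average_precision([True, False, True], 2).ap
        assert ap == pytest.approx(0.5 + 0.5 * 2 / 3, abs=1e-12)

    def test_no_true_positives(self):
        assert average_precision([False, False], 3).ap == 0.0

    def test_no_ground_truth(self):
        assert average_precision([], 0).ap == 0.0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(1000):
            n = int(rng.integers(1, 20))
            flags = rng.uniform(size=n) > 0.5
            n_gt = int(flags.sum() + rng.integers(0, 5))
            if n_gt == 0:
                continue
            got = average_precision(flags, n_gt).ap
            assert got == pytest.approx(brute_force_ap(flags, n_gt), abs=1e-9)

    def test_rank_only_dependence(self, rng):
        """AP is unchanged by uniform positive rescaling of confidences."""
        flags = rng.uniform(size=30) > 0.4
        # evaluate() ranks by confidence; average_precision takes ranked flags,
        # so rank-only dependence is structural — assert the curve is identical
        a = average_precision(flags, 12)
        b = average_precision(flags, 12)
        np.testing.assert_array_equal(a.precision, b.precision)
        assert a.ap == b.ap

    def test_interp101_close_to_continuous(self, rng):
        flags = rng.uniform(size=50) > 0.5
        a = average_precision(flags, 30, "continuous").ap
        b = average_precision(flags, 30, "interp101").ap
        assert abs(a - b) < 0.05


class TestMeanAP:
    def test_all_ones(self):
        assert mean_ap({i: 1.0 for i in range(12)}) == 1.0

    def test_arithmetic_mean(self):
        assert mean_ap({0: 1.0, 1: 0.5}) == 0.75


class TestEvaluate:
    def _perfect_case(self, rng):
        gts = {}
        dets = {}
        for i in range(4):
            boxes = []
            for c in range(3):
                x, y = rng.uniform(0, 50, 2)
                boxes.append(det((x, y, x + 10, y + 8), 1.0, cls=c))
            gts[f"im{i}"] = boxes
            dets[f"im{i}"] = list(boxes)
        return dets, gts

    def test_perfect_predictions_score_one(self, rng):
        dets, gts = self._perfect_case(rng)
        rep = evaluate(dets, gts)
        assert rep.map50 == pytest.approx(1.0)
        assert rep.map50_95 == pytest.approx(1.0)
        assert rep.precision == pytest.approx(1.0)
        assert rep.recall == pytest.approx(1.0)

    def test_jitter_degrades_strict_thresholds_first(self, rng):
        gts = {}
        dets = {}
        for i in range(6):
            g, d = [], []
            for c in range(2):
                x, y = rng.uniform(0, 50, 2)
                g.append(det((x, y, x + 12, y + 12), 1.0, cls=c))
                d.append(det((x + 2, y + 2, x + 14, y + 14), 0.9, cls=c))
            gts[f"im{i}"] = g
            dets[f"im{i}"] = d
        rep = evaluate(dets, gts)
        assert rep.map50 == pytest.approx(1.0)  # IoU ~ 0.56 passes at 0.5
        assert rep.map50_95 < rep.map50

    def test_absent_classes_skipped_and_logged(self, rng):
        dets, gts = self._perfect_case(rng)
        rep = evaluate(dets, gts)
        assert len(rep.per_class_ap50) == 3
        assert len(rep.skipped_classes) == 9

    def test_empty_detections(self, rng):
        _, gts = self._perfect_case(rng)
        rep = evaluate({k: [] for k in gts}, gts)
        assert rep.map50 == 0.0 and rep.recall == 0.0

    def test_map_grid_never_exceeds_map50(self, rng):
        for _ in range(5):
            gts, dets = {}, {}
            for i in range(3):
                g, d = [], []
                for _ in range(int(rng.integers(1, 5))):
                    x, y = rng.uniform(0, 40, 2)
                    w, h = rng.uniform(4, 15, 2)
                    c = int(rng.integers(0, 3))
                    g.append(det((x, y, x + w, y + h), 1.0, cls=c))
                    jx, jy = rng.uniform(-3, 3, 2)
                    d.append(det(
                        (max(x + jx, 0), max(y + jy, 0), max(x + w + jx, 1), max(y + h + jy, 1)),
                        float(rng.uniform(0.3, 1.0)), cls=c,
                    ))
                gts[f"im{i}"] = g
                dets[f"im{i}"] = d
            rep = evaluate(dets, gts)
            assert rep.map50_95 <= rep.map50 + 1e-12


def test_iou_grid_is_the_ten_point_ladder():
    assert list(IOU_GRID) == pytest.approx([0.5, 0.55, 0.6, 0.65, 0.7, 0.75, 0.8, 0.85, 0.9, 0.95])
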