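"""Greedy matching, PR formulas, average precision vs a brute-force oracle,
and the workflow-level report."""

import numpy as np
import pytest

from _oracles import brute_force_ap, random_ap_instance
from madmdet.annotations import BoundingBox, CellClass, Detection, GroundTruthRecord
from madmdet.evaluation import (
    MatchResult,
    average_precision,
    evaluate_workflow,
    match,
    pr_curve,
    precision_recall_f1,
)

LABEL = CellClass("neuron", "red")


def det(x1, y1, x2, y2, conf):
    return Detection(BoundingBox(x1, y1, x2, y2), LABEL, conf)


def gt(x1, y1, x2, y2, label=LABEL):
    return GroundTruthRecord(BoundingBox(x1, y1, x2, y2), label)


class TestMatch:
    def test_second_hit_on_same_object_is_false_positive(self):
        truth = [gt(0, 0, 10, 10)]
        preds = [det(0, 0, 10, 9, 0.9), det(0, 1, 10, 10, 0.7)]  # both IoU 0.8
        m = match(preds, truth)
        assert (m.tp, m.fp, m.fn) == (1, 1, 0)
        assert m.verdicts == ((0, True), (1, False))

    def test_perfect_predictions(self):
        truth = [gt(0, 0, 10, 10), gt(20, 20, 35, 40)]
        preds = [det(0, 0, 10, 10, 0.8), det(20, 20, 35, 40, 0.6)]
        m = match(preds, truth)
        assert (m.tp, m.fp, m.fn) == (2, 0, 0)

    def test_iou_exactly_at_threshold_is_false_positive(self):
        truth = [gt(0, 0, 10, 10)]
        # IoU([0,0,10,10], [0,0,10,5]) = 50/100 = 0.5 exactly
        m = match([det(0, 0, 10, 5, 0.9)], truth)
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)

    def test_greedy_prefers_highest_iou_ground_truth(self):
        truth = [gt(0, 0, 10, 10), gt(2, 0, 12, 10)]
        m = match([det(1, 0, 11, 10, 0.9)], truth)
        # prediction overlaps both; must claim the higher-IoU one only
        assert (m.tp, m.fp, m.fn) == (1, 0, 1)


class TestPrecisionRecallF1:
    @pytest.mark.parametrize(
        "tp, fp, fn, expected",
        [
            (8, 2, 2, (0.8, 0.8, 0.8)),
            (0, 5, 3, (0.0, 0.0, 0.0)),
            (0, 0, 0, (0.0, 0.0, 0.0)),
            (3, 1, 0, (0.75, 1.0, 2 * 0.75 / 1.75)),
        ],
    )
    def test_formulas_and_conventions(self, tp, fp, fn, expected):
        m = MatchResult(tp, fp, fn, (), ())
        assert precision_recall_f1(m) == pytest.approx(expected)

    def test_identical_predictions_give_f1_one(self):
        truth = [gt(0, 0, 10, 10), gt(30, 30, 45, 50)]
        preds = [det(0, 0, 10, 10, 0.9), det(30, 30, 45, 50, 0.8)]
        _p, _r, f1 = precision_recall_f1(match(preds, truth))
        assert f1 == 1.0


class TestAveragePrecision:
    def test_all_correct_full_recall(self):
        truth = [gt(0, 0, 10, 10), gt(30, 30, 45, 50)]
        preds = [det(0, 0, 10, 10, 0.9), det(30, 30, 45, 50, 0.8)]
        assert average_precision(preds, truth) == 1.0

    def test_single_false_positive(self):
        assert average_precision([det(50, 50, 60, 60, 0.9)], [gt(0, 0, 10, 10)]) == 0.0

    def test_worked_example_tp_fp_tp(self):
        # ranks: TP, FP, TP over 2 GT
        # pairs (0.5, 1.0), (0.5, 0.5), (1.0, 2/3)
        # adjusted: 1.0 up to recall 0.5, then 2/3 -> AP = 0.5 + 0.5 * 2/3
        truth = [gt(0, 0, 10, 10), gt(40, 40, 50, 50)]
        preds = [
            det(0, 0, 10, 10, 0.9),
            det(70, 70, 80, 80, 0.8),
            det(40, 40, 50, 50, 0.7),
        ]
        assert average_precision(preds, truth) == pytest.approx(5 / 6)

    def test_empty_ground_truth_rejected(self):
        with pytest.raises(ValueError):
            average_precision([det(0, 0, 10, 10, 0.9)], [])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(500):
            preds, gts = random_ap_instance(rng)
            assert average_precision(preds, gts) == brute_force_ap(preds, gts)

    def test_confidence_ties_broken_deterministically(self):
        # equal confidences: rank order is the input order, reproducibly
        truth = [gt(0, 0, 10, 10), gt(40, 40, 50, 50)]
        a = det(0, 0, 10, 10, 0.5)
        b = det(40, 40, 50, 50, 0.5)
        c = det(70, 70, 80, 80, 0.5)
        assert average_precision([a, b, c], truth) == average_precision([a, b, c], truth)
        m = match([a, b, c], truth)
        assert [i for i, _hit in m.verdicts] == [0, 1, 2]

    def test_permuting_distinct_confidences_is_invariant(self):
        truth = [gt(0, 0, 10, 10), gt(40, 40, 50, 50)]
        a = det(0, 0, 10, 10, 0.9)
        b = det(40, 40, 50, 50, 0.7)
        c = det(70, 70, 80, 80, 0.5)
        base = average_precision([a, b, c], truth)
        assert average_precision([c, a, b], truth) == base
        assert average_precision([b, c, a], truth) == base

    def test_invariant_under_monotone_confidence_rescaling(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            preds, gts = random_ap_instance(rng)
            rescaled = [
                Detection(p.box, p.label, p.confidence**2) for p in preds
            ]
            assert average_precision(rescaled, gts) == average_precision(preds, gts)

    def test_adjusted_precision_non_increasing(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            preds, gts = random_ap_instance(rng)
            if not preds:
                continue
            curve = pr_curve(preds, gts)
            assert all(
                a >= b
                for a, b in zip(curve.adjusted_precisions, curve.adjusted_precisions[1:])
            )
            assert all(
                r1 <= r2 for r1, r2 in zip(curve.recalls, curve.recalls[1:])
            )


class TestEvaluateWorkflow:
    def test_predictions_equal_ground_truth(self):
        truth = [
            gt(0, 0, 10, 10),
            gt(30, 30, 45, 50, CellClass("glia", "yellow")),
            gt(60, 60, 90, 95, CellClass("glia_cluster")),
        ]
        preds = [Detection(r.box, r.label, 0.9) for r in truth]
        report = evaluate_workflow(preds, truth, "seven")
        assert report.mean_ap == 1.0
        assert set(report.per_class_f1.values()) == {1.0}

    def test_empty_predictions(self):
        truth = [gt(0, 0, 10, 10), gt(30, 30, 45, 50)]
        report = evaluate_workflow([], truth, "six")
        assert report.mean_ap == 0.0
        assert report.per_class_f1["red_neuron"] == 0.0

    def test_mean_of_identical_per_class_aps(self):
        truth = [
            gt(0, 0, 10, 10),
            gt(40, 40, 50, 50, CellClass("glia", "red")),
        ]
        preds = [Detection(r.box, r.label, 0.9) for r in truth]
        report = evaluate_workflow(preds, truth, "six")
        assert set(report.per_class_ap.values()) == {1.0}
        assert report.mean_ap == 1.0

    def test_unknown_prediction_class_rejected(self):
        preds = [Detection(BoundingBox(0, 0, 10, 10), CellClass("glia_cluster"), 0.9)]
        with pytest.raises(ValueError):
            evaluate_workflow(preds, [gt(0, 0, 10, 10)], "six")

    def test_f1_respects_confidence_filter(self):
        truth = [gt(0, 0, 10, 10)]
        # the only matching prediction is below the 0.5 display threshold
        preds = [det(0, 0, 10, 10, 0.4)]
        report = evaluate_workflow(preds, truth, "six")
        assert report.per_class_f1["red_neuron"] == 0.0
        assert report.per_class_ap["red_neuron"] == 1.0
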