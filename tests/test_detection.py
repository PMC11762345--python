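import math

import numpy as np
import pytest

from endospec import detection
from endospec.detection import BoxAnnotation, ConfusionMatrix


def box(cls, cx, cy, w, h, conf=None):
    return BoxAnnotation(cls, cx, cy, w, h, confidence=conf)


class TestIou:
    def test_identical(self):
        a = box(0, 0.5, 0.5, 0.2, 0.2)
        assert detection.iou(a, a) == 1.0

    def test_disjoint(self):
        assert detection.iou(box(0, 0.2, 0.2, 0.1, 0.1), box(0, 0.8, 0.8, 0.1, 0.1)) == 0.0

    def test_half_offset_squares(self):
        # unit-fraction squares offset by half a side: inter 0.5s², union 1.5s²
        a = box(0, 0.4, 0.5, 0.2, 0.2)
        b = box(0, 0.5, 0.5, 0.2, 0.2)
        assert detection.iou(a, b) == pytest.approx(1.0 / 3.0)

    def test_symmetry(self):
        a = box(0, 0.3, 0.3, 0.3, 0.2)
        b = box(1, 0.4, 0.35, 0.25, 0.3)
        assert detection.iou(a, b) == detection.iou(b, a)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            box(0, 0.5, 0.5, 0.0, 0.1)


class TestMatchDetections:
    def test_perfect_predictions_diagonal(self):
        truths = [box(c, 0.2 + 0.2 * c, 0.5, 0.1, 0.1) for c in range(3)]
        preds = [box(c, 0.2 + 0.2 * c, 0.5, 0.1, 0.1, conf=0.9) for c in range(3)]
        cm = detection.match_detections(preds, truths)
        assert np.array_equal(np.diag(cm.counts)[:3], [1, 1, 1])
        assert cm.counts.sum() == 3

    def test_no_predictions_all_background_row(self):
        truths = [box(0, 0.5, 0.5, 0.2, 0.2), box(2, 0.2, 0.2, 0.1, 0.1)]
        cm = detection.match_detections([], truths)
        assert cm.counts[3, 0] == 1 and cm.counts[3, 2] == 1
        assert cm.counts.sum() == 2

    def test_low_iou_splits_into_fp_and_fn(self):
        # IoU 0.4 < threshold 0.5: one background-column FP, one background-row FN
        t = box(0, 0.5, 0.5, 0.2, 0.2)
        p = box(0, 0.5 + 0.0857, 0.5, 0.2, 0.2, conf=0.9)
        assert detection.iou(p, t) < 0.5
        cm = detection.match_detections([p], [t])
        assert cm.counts[0, 3] == 1  # FP vs background
        assert cm.counts[3, 0] == 1  # missed truth

    def test_greedy_confidence_order(self):
        t = box(0, 0.5, 0.5, 0.2, 0.2)
        strong = box(0, 0.5, 0.5, 0.2, 0.2, conf=0.9)
        weak = box(1, 0.51, 0.5, 0.2, 0.2, conf=0.3)
        cm = detection.match_detections([weak, strong], [t])
        assert cm.counts[0, 0] == 1  # strong claims the truth
        assert cm.counts[1, 3] == 1  # weak relegated to background column

    def test_missing_confidence_rejected(self):
        with pytest.raises(ValueError, match="confidence"):
            detection.match_detections([box(0, 0.5, 0.5, 0.1, 0.1)], [])


class TestMetricsFromConfusion:
    def test_reference_rgb_wli_scc_sensitivity(self):
        cm = detection.load_reference_confusion("rgb-wli")
        t = detection.metrics_from_confusion(cm)
        assert t.sensitivity[0] == pytest.approx(521 / 666)
        assert round(t.sensitivity[0], 2) == 0.78

    def test_reference_rgb_wli_overall_accuracy(self):
        cm = detection.load_reference_confusion("rgb-wli")
        t = detection.metrics_from_confusion(cm)
        assert round(t.accuracy, 2) == 0.78

    def test_perfect_diagonal(self):
        counts = np.diag([5, 5, 5, 0])
        t = detection.metrics_from_confusion(ConfusionMatrix(counts))
        assert np.allclose(t.sensitivity, 1.0)
        assert np.allclose(t.precision, 1.0)
        assert np.allclose(t.f1, 1.0)
        assert t.accuracy == 1.0

    def test_zero_denominator_is_nan_not_zero(self):
        counts = np.zeros((4, 4), dtype=int)
        counts[0, 0] = 3
        t = detection.metrics_from_confusion(ConfusionMatrix(counts))
        assert math.isnan(t.sensitivity[1])
        assert math.isnan(t.precision[2])

    def test_brute_force_tally_oracle(self, rng):
        # independent per-class TP/FP/FN tally over random matrices
        for _ in range(20):
            counts = rng.integers(0, 50, (4, 4))
            counts[3, 3] = 0
            cm = ConfusionMatrix(counts)
            t = detection.metrics_from_confusion(cm)
            for c in range(3):
                tp = counts[c, c]
                fn = counts[:, c].sum() - tp
                fp = counts[c, :].sum() - tp
                if tp + fn:
                    assert t.sensitivity[c] == pytest.approx(tp / (tp + fn))
                if tp + fp:
                    assert t.precision[c] == pytest.approx(tp / (tp + fp))
            acc_oracle = sum(counts[c, c] for c in range(3)) / counts[:, :3].sum()
            assert t.accuracy == pytest.approx(acc_oracle)

    def test_kappa_standard_definition(self):
        cm = detection.load_reference_confusion("rgb-wli")
        counts = cm.counts.astype(float)
        total = counts.sum()
        po = np.trace(counts) / total
        pe = counts.sum(1) @ counts.sum(0) / total**2
        t = detection.metrics_from_confusion(cm)
        assert t.kappa == pytest.approx((po - pe) / (1 - pe))

    def test_specificity_standard_definition(self):
        cm = detection.load_reference_confusion("rgb-wli")
        t = detection.metrics_from_confusion(cm)
        counts = cm.counts.astype(float)
        fp = counts[0, :].sum() - counts[0, 0]
        negatives = counts.sum() - counts[:, 0].sum()
        assert t.specificity[0] == pytest.approx((negatives - fp) / negatives)


class TestAveragePrecision:
    def test_single_perfect_detection(self):
        t = {"img": [box(0, 0.5, 0.5, 0.2, 0.2)]}
        p = {"img": [box(0, 0.5, 0.5, 0.2, 0.2, conf=0.99)]}
        aps, mean_ap = detection.average_precision(p, t)
        assert aps["scc"] == pytest.approx(1.0)

    def test_all_wrong_class(self):
        t = {"img": [box(0, 0.5, 0.5, 0.2, 0.2)]}
        p = {"img": [box(1, 0.5, 0.5, 0.2, 0.2, conf=0.99)]}
        aps, _ = detection.average_precision(p, t)
        assert aps["scc"] == 0.0

    def test_toy_case_matches_enumeration_oracle(self):
        # 2 truths; detections at conf 0.9 (TP), 0.8 (FP), 0.7 (TP)
        truths = {"img": [box(0, 0.2, 0.2, 0.1, 0.1), box(0, 0.8, 0.8, 0.1, 0.1)]}
        preds = {
            "img": [
                box(0, 0.2, 0.2, 0.1, 0.1, conf=0.9),
                box(0, 0.5, 0.5, 0.1, 0.1, conf=0.8),
                box(0, 0.8, 0.8, 0.1, 0.1, conf=0.7),
            ]
        }
        aps, _ = detection.average_precision(preds, truths)
        # exhaustive PR enumeration: points (r=0.5, p=1), (0.5, 0.5), (1.0, 2/3)
        recalls = np.array([0.5, 0.5, 1.0])
        precisions = np.array([1.0, 0.5, 2.0 / 3.0])
        ap_oracle = 0.0
        for r in np.linspace(0, 1, 101):
            mask = recalls >= r - 1e-12
            ap_oracle += precisions[mask].max() if mask.any() else 0.0
        ap_oracle /= 101.0
        assert aps["scc"] == pytest.approx(ap_oracle)
        assert aps["scc"] == pytest.approx((51 + 50 * 2 / 3) / 101)

    def test_reorder_invariance(self):
        truths = {"img": [box(0, 0.2, 0.2, 0.1, 0.1), box(0, 0.8, 0.8, 0.1, 0.1)]}
        p1 = [
            box(0, 0.2, 0.2, 0.1, 0.1, conf=0.9),
            box(0, 0.5, 0.5, 0.1, 0.1, conf=0.8),
            box(0, 0.8, 0.8, 0.1, 0.1, conf=0.7),
        ]
        a1, _ = detection.average_precision({"img": p1}, truths)
        a2, _ = detection.average_precision({"img": p1[::-1]}, truths)
        assert a1 == a2

    def test_class_without_truths_excluded_from_map(self):
        truths = {"img": [box(0, 0.5, 0.5, 0.2, 0.2)]}
        preds = {"img": [box(0, 0.5, 0.5, 0.2, 0.2, conf=0.9)]}
        aps, mean_ap = detection.average_precision(preds, truths)
        assert math.isnan(aps["dysplasia"])
        assert mean_ap == pytest.approx(1.0)


class TestYoloIO:
    def test_round_trip(self, tmp_path):
        boxes = [
            box(0, 0.5, 0.5, 0.2, 0.1, conf=0.93),
            box(2, 0.25, 0.75, 0.1, 0.1),
        ]
        p = tmp_path / "img.txt"
        detection.write_yolo_annotations(boxes, p)
        back = detection.read_yolo_annotations(p)
        assert back == boxes

    def test_four_field_row_names_line(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("0 0.5 0.5 0.2\n")
        with pytest.raises(ValueError, match=":1"):
            detection.read_yolo_annotations(p)

    def test_format_definition(self, tmp_path):
        p = tmp_path / "one.txt"
        p.write_text("0 0.5 0.5 0.2 0.1 0.93\n")
        (b,) = detection.read_yolo_annotations(p)
        assert b.class_id == 0 and b.confidence == pytest.approx(0.93)

    def test_unparsable_field(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("0 0.5 x 0.2 0.1\n")
        with pytest.raises(ValueError, match=":1"):
            detection.read_yolo_annotations(p)


class TestConfusionCsv:
    def test_round_trip(self, tmp_path):
        cm = detection.load_reference_confusion("hsi-nbi")
        p = tmp_path / "cm.csv"
        detection.write_confusion_csv(cm, p)
        back = detection.read_confusion_csv(p)
        assert np.array_equal(back.counts, cm.counts)
        assert back.class_names == cm.class_names

    def test_bad_labels_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("predicted,a,b\na,1,0\nb,0,1\n")
        with pytest.raises(ValueError, match="background"):
            detection.read_confusion_csv(p)

    def test_unknown_reference_name(self):
        with pytest.raises(ValueError):
            detection.load_reference_confusion("nope")


class TestDedup:
    def test_keeps_highest_confidence(self):
        a = box(0, 0.5, 0.5, 0.2, 0.2, conf=0.9)
        b = box(0, 0.51, 0.5, 0.2, 0.2, conf=0.5)
        c = box(1, 0.51, 0.5, 0.2, 0.2, conf=0.4)  # other class survives
        kept = detection.dedup_boxes([b, a, c])
        assert a in kept and b not in kept and c in kept


class TestAccumulate:
    def test_sums_over_images(self):
        truths = {
            "a": [box(0, 0.5, 0.5, 0.2, 0.2)],
            "b": [box(1, 0.5, 0.5, 0.2, 0.2)],
        }
        preds = {
            "a": [box(0, 0.5, 0.5, 0.2, 0.2, conf=0.9)],
            "b": [],
        }
        cm = detection.accumulate_confusion(preds, truths)
        assert cm.counts[0, 0] == 1
        assert cm.counts[3, 1] == 1
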