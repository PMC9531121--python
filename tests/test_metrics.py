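"""Evaluation metrics: hand values, algebraic identities, naive oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tongue_mtl import metrics as M


counts = st.tuples(st.integers(0, 500), st.integers(0, 500),
                   st.integers(0, 500), st.integers(0, 500)).filter(
                       lambda t: sum(t) > 0)


class TestConfusion:
    def test_perfect_agreement(self):
        c = M.confusion([1, 0, 1], [1, 0, 1])
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 0, 1, 0)

    def test_enumerated_four_cases(self):
        c = M.confusion([1, 1, 0, 0], [1, 0, 1, 0])
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 1, 1, 1)

    def test_total_disagreement_has_no_correct_cells(self):
        truth = np.array([1, 0, 1, 1])
        c = M.confusion(1 - truth, truth)
        assert c.tp == 0 and c.tn == 0

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError, match="binary"):
            M.confusion([0, 2], [0, 1])


class TestClassificationMetrics:
    def test_hand_computed_example(self):
        got = M.classification_metrics(M.ConfusionCounts(tp=8, fp=2, tn=9, fn=1))
        assert got["accuracy"] == pytest.approx(0.85)
        assert got["precision"] == pytest.approx(0.8)
        assert got["recall"] == pytest.approx(8 / 9)
        assert got["f1"] == pytest.approx(2 / (1 / 0.8 + 9 / 8))

    def test_f1_equals_precision_when_balanced(self):
        got = M.classification_metrics(M.ConfusionCounts(tp=3, fp=1, tn=5, fn=1))
        assert got["precision"] == got["recall"] == got["f1"] == pytest.approx(0.75)

    def test_perfect_prediction_is_all_ones(self):
        got = M.classification_metrics(M.ConfusionCounts(tp=4, tn=6))
        assert all(v == 1.0 for v in got.values())

    def test_zero_denominators_yield_zero(self):
        got = M.classification_metrics(M.ConfusionCounts(tn=5, fn=2))
        assert got["precision"] == got["recall"] == got["f1"] == 0.0


class TestSegmentationMetrics:
    def test_hand_computed_example(self):
        got = M.segmentation_metrics(M.ConfusionCounts(tp=2, fp=1, tn=2, fn=1))
        assert got["dsc"] == pytest.approx(2 / 3)
        assert got["ji"] == pytest.approx(0.5)
        assert got["miou"] == pytest.approx(0.5)
        assert got["fwiou"] == pytest.approx(0.5)

    def test_perfect_prediction_is_all_ones(self):
        got = M.segmentation_metrics(M.ConfusionCounts(tp=7, tn=3))
        assert all(v == 1.0 for v in got.values())

    @settings(max_examples=1000, deadline=None, derandomize=True)
    @given(counts)
    def test_dsc_ji_identity(self, t):
        """DSC = 2 JI / (1 + JI) for every confusion tuple."""
        got = M.segmentation_metrics(M.ConfusionCounts(*t))
        assert got["dsc"] == pytest.approx(2 * got["ji"] / (1 + got["ji"]))

    @settings(max_examples=500, deadline=None, derandomize=True)
    @given(counts)
    def test_all_metrics_within_unit_interval(self, t):
        c = M.ConfusionCounts(*t)
        for d in (M.segmentation_metrics(c), M.classification_metrics(c)):
            assert all(0.0 <= v <= 1.0 for v in d.values())

    def test_miou_equals_fwiou_for_symmetric_counts(self):
        # balanced classes and equal per-class IoU
        got = M.segmentation_metrics(M.ConfusionCounts(tp=6, fp=2, tn=6, fn=2))
        assert got["miou"] == pytest.approx(got["fwiou"])

    def test_matches_naive_double_loop_oracle(self):
        """Exact agreement with a per-pixel loop + literal formulas on 100
        random 16x16 mask pairs."""
        rng = np.random.default_rng(3)
        for _ in range(100):
            pred = (rng.random((16, 16)) > rng.random()).astype(np.uint8)
            truth = (rng.random((16, 16)) > rng.random()).astype(np.uint8)
            tp = fp = tn = fn = 0
            for y in range(16):
                for x in range(16):
                    p, t = int(pred[y, x]), int(truth[y, x])
                    tp += p & t
                    fp += p & ~t & 1
                    tn += (1 - p) & (1 - t)
                    fn += (1 - p) & t
            got = M.segmentation_metrics(M.confusion(pred, truth))
            total = tp + fp + tn + fn
            if 2 * tp + fp + fn:
                assert got["dsc"] == 2 * tp / (2 * tp + fp + fn)
                assert got["ji"] == tp / (tp + fp + fn)
            iou_f = tp / (tp + fp + fn) if tp + fp + fn else 1.0
            iou_b = tn / (tn + fp + fn) if tn + fp + fn else 1.0
            assert got["miou"] == (iou_f + iou_b) / 2
            assert got["fwiou"] == ((tp + fn) * iou_f + (tn + fp) * iou_b) / total


class FixedOutputModel:
    """Stub model returning canned per-image class probabilities."""

    def __init__(self, probs):
        self._probs = np.asarray(probs, np.float32)

    def forward(self, batch):
        from tongue_mtl.model import MtlOutput
        from tongue_mtl.nn import Tensor

        n = len(batch)
        out = self._probs[:n]
        self._probs = self._probs[n:]
        return MtlOutput(cls_probs=Tensor(out))


class TestEvaluateSplit:
    def test_perfect_single_sample_report(self, trained_tiny):
        model, _, _, images = trained_tiny
        from tongue_mtl.trainer import arrays_from_annotated

        arrs = arrays_from_annotated([images[0]])
        report = M.evaluate_split(model, arrs.images,
                                  np.stack([images[0].mask]),
                                  arrs.labels, mode="both")
        assert report.n_items == 1
        assert report.dsc_sd == 0.0

    def test_mean_and_population_sd_convention(self):
        """Two images with per-image DSC 1.0 and 0.5 -> mean .75, sd .25."""
        from tongue_mtl.model import MtlOutput
        from tongue_mtl.nn import Tensor

        masks = np.zeros((2, 4, 4), np.uint8)
        masks[:, :2, :] = 1
        pred = np.zeros((2, 2, 4, 4), np.float32)
        pred[0, 1] = masks[0]           # exact -> DSC 1
        pred[0, 0] = 1 - masks[0]
        pred[1, 1, 0, :] = 1.0          # half the tongue rows -> DSC 2*4/(8+4)
        pred[1, 0] = 1 - pred[1, 1]

        class Seg:
            def forward(self, batch):
                return MtlOutput(seg_probs=Tensor(pred[:len(batch)]))

        report = M.evaluate_split(Seg(), np.zeros((2, 3, 4, 4), np.float32),
                                  masks, None, mode="segmentation")
        d1 = 2 * 4 / (2 * 4 + 4)
        assert report.dsc == pytest.approx((1.0 + d1) / 2)
        assert report.dsc_sd == pytest.approx((1.0 - d1) / 2)

    def test_classification_accuracy_matches_heuristic_oracle(self):
        """evaluate_split on canned predictions equals the accuracy derived
        independently from the heuristic classifier's confusion counts."""
        from tongue_mtl import synthetic as syn

        images = syn.generate_dataset(12, 8, seed=17)
        labels = np.array([im.quality == "high" for im in images], np.uint8)
        heur = np.array([syn.heuristic_quality(im) == "high" for im in images],
                        np.uint8)
        probs = np.stack([1.0 - heur, heur], axis=1).astype(np.float32)
        report = M.evaluate_split(FixedOutputModel(probs),
                                  np.zeros((20, 3, 8, 8), np.float32), None,
                                  labels, mode="classification")
        expect = M.classification_metrics(M.confusion(heur, labels))["accuracy"]
        assert report.accuracy == pytest.approx(expect)

    def test_empty_split_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="empty"):
            M.evaluate_split(tiny_model, np.zeros((0, 3, 32, 32)), None,
                             np.zeros(0), mode="classification")

    def test_report_table_has_expected_columns(self):
        r = M.MetricsReport(accuracy=0.9, precision=0.8, recall=0.7, f1=0.75,
                            n_items=10)
        table = M.report_table({"STL_OTI": r})
        assert "Accuracy" in table and "FWIoU" in table
        assert "0.9000" in table and "--" in table
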