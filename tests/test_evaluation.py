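"""Confusion-matrix construction, metrics and rendering."""

import numpy as np
import pytest
from sklearn.metrics import confusion_matrix as sk_confusion

from skitech.evaluation import (
    ConfusionMatrix,
    accuracy,
    build_confusion,
    merge_classes,
    precision,
    render_confusion,
    sensitivity,
)
from skitech.io import CLASSES, SubTechnique

S = SubTechnique


class TestBuildConfusion:
    def test_all_correct_is_diagonal(self):
        pairs = [(c, c) for c in CLASSES for _ in range(3)]
        cm = build_confusion(pairs)
        assert np.trace(cm.counts) == cm.total == 24
        assert np.all(cm.counts == 3 * np.eye(8))

    def test_single_confused_pair_orientation(self):
        # labeled DIA, classified HRB -> row HRB, column DIA
        cm = build_confusion([(S.DIA, S.HRB)])
        r, c = CLASSES.index(S.HRB), CLASSES.index(S.DIA)
        assert cm.counts[r, c] == 1
        assert cm.total == 1

    def test_empty_input_is_zero_matrix(self):
        cm = build_confusion([])
        assert cm.total == 0
        assert cm.accuracy() is None

    def test_exc_pairs_only_counted_as_excluded(self):
        pairs = [(S.DIA, S.DIA), (S.EXC, S.DIA), (S.DK, S.EXC)]
        cm = build_confusion(pairs)
        assert cm.total == 1
        assert cm.excluded_count == 2

    def test_margins_are_label_and_prediction_counts(self):
        pairs = [(S.DIA, S.DIA), (S.DIA, S.DP), (S.DK, S.DP)]
        cm = build_confusion(pairs)
        assert cm.labeled_counts()[CLASSES.index(S.DIA)] == 2
        assert cm.classified_counts()[CLASSES.index(S.DP)] == 2


class TestMetrics:
    def _worked_matrix(self):
        """72 true positives for HRB with 4 HRB cycles classified DIA;
        117 true positives for TRN with 4 foreign cycles classified TRN."""
        counts = np.zeros((8, 8), dtype=int)
        i = {c: k for k, c in enumerate(CLASSES)}
        counts[i[S.HRB], i[S.HRB]] = 72
        counts[i[S.DIA], i[S.HRB]] = 4
        counts[i[S.TRN], i[S.TRN]] = 117
        counts[i[S.TRN], i[S.TCK]] = 2
        counts[i[S.TRN], i[S.DIA]] = 1
        counts[i[S.TRN], i[S.DP]] = 1
        return ConfusionMatrix(counts)

    def test_sensitivity_worked_example(self):
        cm = self._worked_matrix()
        assert sensitivity(cm, S.HRB) == pytest.approx(100 * 72 / 76)
        assert round(sensitivity(cm, S.HRB), 1) == 94.7

    def test_precision_worked_example(self):
        cm = self._worked_matrix()
        assert precision(cm, S.TRN) == pytest.approx(100 * 117 / 121)
        assert round(precision(cm, S.TRN), 1) == 96.7

    def test_perfect_class_is_100(self):
        cm = build_confusion([(S.DP, S.DP)] * 5)
        assert sensitivity(cm, S.DP) == 100.0
        assert precision(cm, S.DP) == 100.0

    def test_zero_tp_is_0_and_absent_class_na(self):
        cm = build_confusion([(S.DIA, S.DK)])
        assert sensitivity(cm, S.DIA) == 0.0
        assert precision(cm, S.DK) == 0.0
        assert sensitivity(cm, S.TCK) is None
        assert precision(cm, S.TCK) is None

    def test_accuracy_arithmetic(self):
        counts = np.zeros((8, 8), dtype=int)
        counts[np.diag_indices(8)] = [5, 2, 3, 1, 2, 1, 1, 0]  # trace 15
        counts[0, 1] = 5  # total 20
        cm = ConfusionMatrix(counts)
        assert accuracy(cm) == pytest.approx(75.0)

    def test_uniform_matrix_accuracy_one_eighth(self):
        cm = ConfusionMatrix(np.ones((8, 8), dtype=int))
        assert accuracy(cm) == pytest.approx(12.5)

    def test_metrics_match_brute_force_recount(self, rng):
        # independent recount via sklearn on random label/prediction pairs
        for _ in range(30):
            n = rng.integers(5, 200)
            truth = rng.integers(0, 8, n)
            pred = rng.integers(0, 8, n)
            pairs = [(CLASSES[a], CLASSES[b]) for a, b in zip(truth, pred)]
            cm = build_confusion(pairs)
            ref = sk_confusion(truth, pred, labels=range(8))
            # sklearn: rows = true; ours: rows = classified
            np.testing.assert_array_equal(cm.counts, ref.T)
            assert accuracy(cm) == pytest.approx(100 * np.mean(truth == pred), abs=1e-12)

    def test_accuracy_is_weighted_mean_of_sensitivities(self, rng):
        counts = rng.integers(0, 30, size=(8, 8))
        cm = ConfusionMatrix(counts)
        col = cm.labeled_counts()
        sens = np.array([
            cm.sensitivity(c) if col[i] else 0.0 for i, c in enumerate(CLASSES)])
        weighted = float(np.sum(sens * col) / col.sum())
        assert accuracy(cm) == pytest.approx(weighted, abs=1e-9)


class TestMergeClasses:
    def test_merging_self_confused_classes_never_decreases_accuracy(self, rng):
        fam = [S.DIA, S.HRB, S.TDIA, S.FDIA]
        idx = [CLASSES.index(c) for c in fam]
        for _ in range(20):
            counts = np.diag(rng.integers(1, 50, 8))
            # confusion only within the family
            for a in idx:
                for b in idx:
                    if a != b:
                        counts[a, b] += rng.integers(0, 10)
            cm = ConfusionMatrix(counts)
            merged = merge_classes(cm, {"DIA-family": fam})
            assert merged.accuracy() >= cm.accuracy() - 1e-12
            assert merged.total == cm.total

    def test_merged_matrix_shape(self):
        cm = build_confusion([(S.DIA, S.TDIA), (S.DP, S.DP)])
        merged = merge_classes(cm, {"DIA-family": [S.DIA, S.HRB, S.TDIA, S.FDIA]})
        assert len(merged.classes) == 5
        assert merged.accuracy() == pytest.approx(100.0)


class TestRender:
    def test_zero_matrix_renders_na_margins(self):
        text = render_confusion(build_confusion([]))
        assert "N/A" in text

    def test_worked_margins_appear(self):
        cm = TestMetrics()._worked_matrix()
        text = render_confusion(cm)
        assert "94.7%" in text and "96.7%" in text

    def test_single_row_predictions(self):
        cm = build_confusion([(S.DIA, S.TRN), (S.DK, S.TRN), (S.DP, S.TRN)])
        assert np.count_nonzero(cm.classified_counts()) == 1
        assert "0.0%" in render_confusion(cm)
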