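"""Agreement metrics: published worked examples and cross-checks."""

import numpy as np
import pytest

from sleepwvd.metrics import (
    ConfusionMatrix2, ConfusionMatrixK, cohen_kappa, confusion_counts,
    evaluate_pairs, global_accuracy, map_to_predicted_classes,
    sensitivity_accuracy,
)
from sleepwvd.signal_io import Hypnogram, PREDICTED_STAGES, TECHNICIAN_STAGES

# published wake-vs-rest and N3-vs-rest confusion counts of a 10-night,
# 8207-epoch evaluation, used as exact worked examples
WAKE_COUNTS = dict(A=1971, B=517, C=136, D=5583)
N3_COUNTS = dict(A=1263, B=457, C=149, D=6338)
MULTI_COUNTS = [[1971, 30, 487], [36, 1263, 421], [100, 119, 3780]]


def hypnos_from_binary(A, B, C, D, positive="WAKE"):
    """Predicted/truth label pairs realizing the binary counts."""
    neg = "OTHER"
    pred = [positive] * (A + B) + [neg] * (C + D)
    truth = [positive] * A + [neg] * B + [positive] * C + [neg] * D
    return (Hypnogram(tuple(pred), PREDICTED_STAGES),
            Hypnogram(tuple(truth), PREDICTED_STAGES))


def hypnos_from_multi(counts):
    classes = ("WAKE", "N3", "OTHER")
    pred, truth = [], []
    for i, row in enumerate(counts):
        for j, n in enumerate(row):
            pred += [classes[i]] * n
            truth += [classes[j]] * n
    return (Hypnogram(tuple(pred), PREDICTED_STAGES),
            Hypnogram(tuple(truth), PREDICTED_STAGES))


class TestLabelCollapse:
    def test_technician_to_three_classes(self):
        h = Hypnogram(("W", "N1", "N2", "N3", "REM"), TECHNICIAN_STAGES)
        assert map_to_predicted_classes(h).labels == \
            ("WAKE", "OTHER", "OTHER", "N3", "OTHER")

    def test_idempotent_on_predicted_labels(self):
        h = Hypnogram(("WAKE", "N3", "OTHER"), PREDICTED_STAGES)
        assert map_to_predicted_classes(h).labels == h.labels


class TestConfusionCounts:
    def test_identical_vectors_are_diagonal(self):
        h = Hypnogram(("WAKE", "N3", "OTHER", "N3"), PREDICTED_STAGES)
        m = confusion_counts(h, h)
        assert np.trace(m.counts) == 4
        assert m.counts.sum() - np.trace(m.counts) == 0

    def test_reconstructs_published_binary_counts(self):
        pred, truth = hypnos_from_binary(**WAKE_COUNTS)
        m = confusion_counts(pred, truth, positive="WAKE")
        assert (m.A, m.B, m.C, m.D) == (1971, 517, 136, 5583)
        assert m.N == 8207

    def test_matches_per_epoch_tally_oracle(self, rng):
        labels = PREDICTED_STAGES
        pred = Hypnogram(tuple(rng.choice(labels, 200)), PREDICTED_STAGES)
        truth = Hypnogram(tuple(rng.choice(labels, 200)), PREDICTED_STAGES)
        m = confusion_counts(pred, truth)
        for i, pi in enumerate(("WAKE", "N3", "OTHER")):
            for j, tj in enumerate(("WAKE", "N3", "OTHER")):
                brute = sum(1 for p, t in zip(pred.labels, truth.labels)
                            if p == pi and t == tj)
                assert m.counts[i, j] == brute

    def test_binary_collapse_equals_direct_binary_count(self, rng):
        pred = Hypnogram(tuple(rng.choice(PREDICTED_STAGES, 300)), PREDICTED_STAGES)
        truth = Hypnogram(tuple(rng.choice(PREDICTED_STAGES, 300)), PREDICTED_STAGES)
        for stage in ("WAKE", "N3"):
            m = confusion_counts(pred, truth, positive=stage)
            a = sum(p == stage and t == stage for p, t in zip(pred.labels, truth.labels))
            b = sum(p == stage and t != stage for p, t in zip(pred.labels, truth.labels))
            c = sum(p != stage and t == stage for p, t in zip(pred.labels, truth.labels))
            assert (m.A, m.B, m.C) == (a, b, c)

    def test_length_mismatch_rejected(self):
        h1 = Hypnogram(("WAKE",), PREDICTED_STAGES)
        h2 = Hypnogram(("WAKE", "N3"), PREDICTED_STAGES)
        with pytest.raises(ValueError, match="mismatch"):
            confusion_counts(h1, h2)


class TestBinaryMetrics:
    def test_wake_table_sensitivity_accuracy_kappa(self):
        m = ConfusionMatrix2(**WAKE_COUNTS)
        sens, acc = sensitivity_accuracy(m)
        assert round(100 * sens, 2) == 93.55
        assert round(100 * acc, 2) == 92.04
        assert round(cohen_kappa(m), 2) == 0.80

    def test_n3_table_sensitivity_accuracy_kappa(self):
        m = ConfusionMatrix2(**N3_COUNTS)
        sens, acc = sensitivity_accuracy(m)
        assert round(100 * sens, 2) == 89.45
        assert round(100 * acc, 2) == 92.62
        assert round(cohen_kappa(m), 2) == 0.76

    def test_perfect_agreement(self):
        m = ConfusionMatrix2(A=40, B=0, C=0, D=60)
        sens, acc = sensitivity_accuracy(m)
        assert (sens, acc) == (1.0, 1.0)
        assert cohen_kappa(m) == pytest.approx(1.0)

    def test_kappa_zero_when_agreement_is_chance_level(self):
        # po == pc exactly when rows are proportional to column margins
        m = ConfusionMatrix2(A=10, B=10, C=10, D=10)
        assert cohen_kappa(m) == pytest.approx(0.0)

    def test_kappa_matches_sklearn_oracle(self, rng):
        from sklearn.metrics import cohen_kappa_score

        for _ in range(20):
            pred = rng.choice([0, 1], 100)
            truth = rng.choice([0, 1], 100)
            A = int(np.sum((pred == 1) & (truth == 1)))
            B = int(np.sum((pred == 1) & (truth == 0)))
            C = int(np.sum((pred == 0) & (truth == 1)))
            D = int(np.sum((pred == 0) & (truth == 0)))
            m = ConfusionMatrix2(A, B, C, D)
            try:
                ours = cohen_kappa(m)
            except ValueError:
                continue  # degenerate draw
            assert ours == pytest.approx(cohen_kappa_score(truth, pred), abs=1e-12)

    def test_degenerate_cases_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_accuracy(ConfusionMatrix2(0, 5, 0, 5))  # no truth positives
        with pytest.raises(ValueError):
            cohen_kappa(ConfusionMatrix2(10, 0, 0, 0))          # single-cell


class TestMulticlass:
    def test_published_global_accuracy_and_tp_rates(self):
        m = ConfusionMatrixK(np.array(MULTI_COUNTS))
        acc, rates = global_accuracy(m)
        assert m.total == 8207
        assert round(100 * acc, 2) == 85.46
        assert round(100 * rates["WAKE"], 2) == 93.55
        assert round(100 * rates["N3"], 2) == 89.45
        assert round(100 * rates["OTHER"], 2) == 80.63

    def test_identity_matrix_is_perfect(self):
        m = ConfusionMatrixK(np.diag([5, 7, 9]))
        acc, rates = global_accuracy(m)
        assert acc == 1.0
        assert all(r == 1.0 for r in rates.values())

    def test_uniform_matrix_is_one_third(self):
        acc, _ = global_accuracy(ConfusionMatrixK(np.ones((3, 3), int)))
        assert acc == pytest.approx(1 / 3)

    def test_joint_permutation_invariance(self, rng):
        pred, truth = hypnos_from_multi([[5, 2, 1], [0, 7, 3], [2, 2, 8]])
        perm = rng.permutation(len(pred))
        pred2 = Hypnogram(tuple(np.array(pred.labels)[perm]), PREDICTED_STAGES)
        truth2 = Hypnogram(tuple(np.array(truth.labels)[perm]), PREDICTED_STAGES)
        np.testing.assert_array_equal(confusion_counts(pred, truth).counts,
                                      confusion_counts(pred2, truth2).counts)


class TestEvaluateReport:
    def test_reproduces_published_tables_from_label_pairs(self):
        report = evaluate_pairs([hypnos_from_multi(MULTI_COUNTS)])
        assert report["n_epochs"] == 8207
        assert report["wake"]["sensitivity_pct"] == 93.55
        assert report["wake"]["accuracy_pct"] == 92.04
        assert report["wake"]["kappa"] == 0.80
        assert report["n3"]["sensitivity_pct"] == 89.45
        assert report["n3"]["accuracy_pct"] == 92.62
        assert report["n3"]["kappa"] == 0.76
        assert report["multiclass"]["global_accuracy_pct"] == 85.46

    def test_perfect_and_single_wrong(self):
        h = Hypnogram(("WAKE", "N3", "OTHER"), PREDICTED_STAGES)
        rep = evaluate_pairs([(h, h)])
        assert rep["multiclass"]["global_accuracy_pct"] == 100.0
        assert rep["wake"]["kappa"] == 1.0
        pred = Hypnogram(("WAKE", "N3", "OTHER"), PREDICTED_STAGES)
        truth = Hypnogram(("N3", "WAKE", "OTHER"), PREDICTED_STAGES)
        rep = evaluate_pairs([(pred, truth)])
        assert rep["multiclass"]["global_accuracy_pct"] == pytest.approx(33.33)
        assert rep["wake"]["sensitivity_pct"] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            evaluate_pairs([])
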