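import numpy as np
import pytest

from apoloc import (
    LabeledDataset,
    ParameterError,
    UndefinedMetricError,
    accuracy,
    compute_metrics,
    confusion_from_predictions,
    jackknife,
    mcc,
    sensitivity,
    specificity,
)
from oracle_knn import standard_mcc
from worked_example import FN, FP, SIZES, benchmark_predictions


def separable_dataset():
    """Two orthogonal clusters per class: every leave-one-out vote is trivial."""
    rows, labels = [], []
    for c, cls in enumerate(["a", "b", "c"]):
        for _ in range(4):
            v = np.zeros(6)
            v[2 * c] = 1.0
            v[2 * c + 1] = 1.0
            rows.append(v)
            labels.append(cls)
    return LabeledDataset(
        accessions=[f"P{i}" for i in range(len(labels))],
        labels=labels,
        X=np.asarray(rows),
    )


class TestJackknife:
    def test_one_prediction_per_row_and_determinism(self):
        data = separable_dataset()
        p1 = jackknife(data, K=3)
        p2 = jackknife(data, K=3)
        assert len(p1) == len(data)
        assert p1 == p2

    def test_separable_classes_fully_recovered(self):
        preds = jackknife(separable_dataset(), K=1)
        assert all(t == p for _, t, p in preds)

    def test_k_must_leave_room_for_training(self):
        with pytest.raises(ParameterError):
            jackknife(separable_dataset(), K=12)

    def test_matches_explicit_leave_one_out(self):
        """The pooled-distance-matrix jackknife equals literal predict-on-rest."""
        from apoloc import predict

        rng = np.random.default_rng(11)
        X = rng.choice([0.0, 0.25, 0.5, 1.0], size=(15, 4))
        labels = [str(l) for l in rng.integers(0, 3, size=15)]
        data = LabeledDataset([f"P{i}" for i in range(15)], labels, X)
        fast = jackknife(data, K=4)
        for i, (_, _, predicted) in enumerate(fast):
            rest = LabeledDataset(
                [a for j, a in enumerate(data.accessions) if j != i],
                [l for j, l in enumerate(labels) if j != i],
                np.delete(X, i, axis=0),
            )
            assert predict(X[i], rest, 4).predicted == predicted


class TestConfusion:
    def test_all_correct(self):
        stats = confusion_from_predictions([("p", "a", "a"), ("q", "b", "b")])
        assert stats.fn == {"a": 0, "b": 0} and stats.fp == {"a": 0, "b": 0}

    def test_single_error_bookkeeping(self):
        stats = confusion_from_predictions(
            [("p", "A", "B"), ("q", "A", "A"), ("r", "B", "B")]
        )
        assert stats.fn["A"] == 1 and stats.fp["B"] == 1
        assert stats.n_pos["A"] + stats.n_neg["A"] == stats.N

    def test_conservation_on_benchmark_counts(self):
        preds = benchmark_predictions()
        stats = confusion_from_predictions(preds)
        assert stats.n_pos == SIZES
        assert stats.fn == FN
        assert stats.fp == FP
        assert sum(stats.fn.values()) == sum(stats.fp.values()) == 10


class TestMetricFormulas:
    def test_sensitivity_examples(self):
        assert sensitivity(110, 2) == pytest.approx(0.981818, abs=1e-6)
        assert sensitivity(55, 0) == 1.0
        assert sensitivity(17, 17) == 0.0
        with pytest.raises(UndefinedMetricError):
            sensitivity(0, 0)

    def test_specificity_examples(self):
        assert specificity(204, 5) == pytest.approx(0.975490, abs=1e-6)
        assert specificity(100, 0) == 1.0
        assert specificity(100, 100) == 0.0
        with pytest.raises(UndefinedMetricError):
            specificity(0, 0)

    def test_mcc_reference_points(self):
        assert mcc(47, 267, 0, 0) == 1.0
        assert mcc(110, 204, 55, 102) == pytest.approx(0.0, abs=1e-12)  # random
        assert mcc(55, 259, 1, 1) == pytest.approx(0.978, abs=5e-4)
        assert mcc(51, 263, 5, 2) == pytest.approx(0.917, abs=5e-4)
        assert mcc(10, 20, 10, 20) == pytest.approx(-1.0)  # total disagreement

    def test_mcc_equals_standard_formula_on_grid(self):
        for n_pos in range(1, 7):
            for n_neg in range(1, 7):
                for fn in range(n_pos + 1):
                    for fp in range(n_neg + 1):
                        ours = mcc(n_pos, n_neg, fn, fp)
                        assert ours == pytest.approx(
                            standard_mcc(n_pos, n_neg, fn, fp), abs=1e-12
                        )
                        assert -1.0 - 1e-12 <= ours <= 1.0 + 1e-12

    def test_accuracy_identity_and_extremes(self):
        stats = confusion_from_predictions(benchmark_predictions())
        acc = accuracy(stats)
        assert acc == pytest.approx(304 / 314)
        assert acc == pytest.approx(1 - sum(stats.fn.values()) / stats.N)
        all_right = confusion_from_predictions([("p", "a", "a")] * 1)
        assert accuracy(all_right) == 1.0
        all_wrong = confusion_from_predictions([("p", "a", "b"), ("q", "b", "a")])
        assert accuracy(all_wrong) == 0.0


class TestReport:
    def test_table_formatting_matches_display_conventions(self):
        report = compute_metrics(confusion_from_predictions(benchmark_predictions()))
        text = report.to_tsv()
        assert "Cy\t98.2\t97.5\t0.952" in text  # exact MCC 0.95154, rounded
        assert "Me\t98.2\t99.6\t0.978" in text
        assert "Nu\t90.2\t99.2\t0.917" in text
        assert "En\t100.0\t100.0\t1.000" in text
        assert text.strip().endswith("ACC\t96.8\t\t".strip())

    def test_full_precision_dict(self):
        report = compute_metrics(confusion_from_predictions(benchmark_predictions()))
        d = report.to_dict()
        assert d["acc"] == pytest.approx(304 / 314)
        assert d["per_class"]["En"]["mcc"] == 1.0
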