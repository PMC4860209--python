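"""Jackknife (leave-one-out) evaluation and the per-class metrics.

The jackknife holds each protein out in turn and predicts it from the
remaining N−1; it is deterministic, so two runs on the same inputs give
identical predictions.  Feature vectors are computed once for the whole
dataset: a protein's vector depends only on the annotation and homology
inputs, never on the other proteins or their labels, so leaving one out
needs no re-featurization.

Per class i with N⁺(i) true members, N⁻(i) non-members, N₋⁺(i) members
predicted elsewhere (false negatives) and N₊⁻(i) non-members predicted as
i (false positives):

    SN_i  = 1 − N₋⁺(i)/N⁺(i)
    SP_i  = 1 − N₊⁻(i)/N⁻(i)
    MCC_i = [1 − N₋⁺/N⁺ − N₊⁻/N⁻] /
            sqrt{[1 + (N₊⁻ − N₋⁺)/N⁺]·[1 + (N₋⁺ − N₊⁻)/N⁻]}
    ACC   = Σ_i (N⁺(i) − N₋⁺(i)) / N

MCC_i is algebraically the usual Matthews correlation coefficient of the
one-vs-rest confusion table (a denominator of zero maps to 0, the common
convention for degenerate tables).  These metrics are for single-label
classification only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .annotations import AnnotationStore
from .classifier import predict_from_distances
from .errors import ParameterError, UndefinedMetricError, ValidationError
from .features import LabeledDataset, featurize_dataset
from .homology import HomologTable
from .ontology import CompressMap

Prediction = tuple[str, str, str]  # (accession, true label, predicted label)


def jackknife(data: LabeledDataset, K: int) -> list[Prediction]:
    """Leave-one-out predictions for every row of ``data``.

    Each prediction uses the dataset minus that row as training set, so
    ``K`` must be at most ``len(data) - 1``.
    """
    n = len(data)
    if n < 2:
        raise ParameterError("jackknife needs at least 2 samples")
    if K >= n:
        raise ParameterError(f"K={K} must be smaller than the dataset size {n}")
    D = squareform(pdist(data.X, metric="euclidean"))
    labels = np.asarray(data.labels, dtype=object)
    keep = np.ones(n, dtype=bool)
    out: list[Prediction] = []
    for i in range(n):
        keep[i] = False
        result = predict_from_distances(D[i][keep], labels[keep], K)
        keep[i] = True
        out.append((data.accessions[i], data.labels[i], result.predicted))
    return out


@dataclass
class ConfusionStats:
    """Per-class one-vs-rest counts over a set of predictions."""

    classes: list[str]
    n_pos: dict[str, int]
    n_neg: dict[str, int]
    fn: dict[str, int]  # members of i predicted elsewhere
    fp: dict[str, int]  # non-members predicted as i

    @property
    def N(self) -> int:
        return sum(self.n_pos.values())


def confusion_from_predictions(preds: Iterable[Prediction]) -> ConfusionStats:
    """Aggregate (accession, truth, prediction) triples into per-class counts."""
    preds = list(preds)
    classes = sorted({t for _, t, _ in preds})
    class_set = set(classes)
    for _, _, p in preds:
        if p not in class_set:
            raise ValidationError(f"predicted label {p!r} not among true labels")
    n_pos = {c: 0 for c in classes}
    fn = {c: 0 for c in classes}
    fp = {c: 0 for c in classes}
    for _, truth, pred in preds:
        n_pos[truth] += 1
        if pred != truth:
            fn[truth] += 1
            fp[pred] += 1
    N = len(preds)
    n_neg = {c: N - n_pos[c] for c in classes}
    return ConfusionStats(classes=classes, n_pos=n_pos, n_neg=n_neg, fn=fn, fp=fp)


def sensitivity(n_pos: int, fn: int) -> float:
    """Fraction of class members recovered: 1 − fn/n_pos."""
    if n_pos <= 0:
        raise UndefinedMetricError("sensitivity undefined for an empty class")
    if not 0 <= fn <= n_pos:
        raise ParameterError("fn must lie in [0, n_pos]")
    return 1.0 - fn / n_pos


def specificity(n_neg: int, fp: int) -> float:
    """Fraction of non-members kept out: 1 − fp/n_neg."""
    if n_neg <= 0:
        raise UndefinedMetricError("specificity undefined with no negatives")
    if not 0 <= fp <= n_neg:
        raise ParameterError("fp must lie in [0, n_neg]")
    return 1.0 - fp / n_neg


def mcc(n_pos: int, n_neg: int, fn: int, fp: int) -> float:
    """One-vs-rest Matthews correlation coefficient from FN/FP counts."""
    if n_pos <= 0 or n_neg <= 0:
        raise UndefinedMetricError("MCC needs at least one positive and one negative")
    numerator = 1.0 - fn / n_pos - fp / n_neg
    den_sq = (1.0 + (fp - fn) / n_pos) * (1.0 + (fn - fp) / n_neg)
    if den_sq <= 0.0:
        return 0.0
    denominator = math.sqrt(den_sq)
    if denominator == 0.0:
        return 0.0
    return numerator / denominator


def accuracy(stats: ConfusionStats) -> float:
    """Overall fraction of correctly classified samples."""
    N = stats.N
    if N <= 0:
        raise UndefinedMetricError("accuracy undefined on an empty prediction set")
    correct = sum(stats.n_pos[c] - stats.fn[c] for c in stats.classes)
    return correct / N


@dataclass
class MetricsReport:
    """Full-precision per-class SN/SP/MCC plus overall ACC, with table formatting."""

    classes: list[str]
    sn: dict[str, float]
    sp: dict[str, float]
    mcc: dict[str, float]
    acc: float

    def to_tsv(self) -> str:
        """Display table: SN/SP as percentages to 1 decimal, MCC to 3 decimals."""
        lines = ["#location\tSN(%)\tSP(%)\tMCC"]
        for c in self.classes:
            lines.append(
                f"{c}\t{100 * self.sn[c]:.1f}\t{100 * self.sp[c]:.1f}\t{self.mcc[c]:.3f}"
            )
        lines.append(f"ACC\t{100 * self.acc:.1f}\t\t")
        return "\n".join(lines) + "\n"

    def to_dict(self) -> dict:
        return {
            "per_class": {
                c: {"sn": self.sn[c], "sp": self.sp[c], "mcc": self.mcc[c]}
                for c in self.classes
            },
            "acc": self.acc,
        }


def compute_metrics(stats: ConfusionStats) -> MetricsReport:
    return MetricsReport(
        classes=list(stats.classes),
        sn={c: sensitivity(stats.n_pos[c], stats.fn[c]) for c in stats.classes},
        sp={c: specificity(stats.n_neg[c], stats.fp[c]) for c in stats.classes},
        mcc={
            c: mcc(stats.n_pos[c], stats.n_neg[c], stats.fn[c], stats.fp[c])
            for c in stats.classes
        },
        acc=accuracy(stats),
    )


def evaluate_jackknife(data: LabeledDataset, K: int) -> tuple[list[Prediction], MetricsReport]:
    """Convenience: jackknife + metrics in one call."""
    preds = jackknife(data, K)
    return preds, compute_metrics(confusion_from_predictions(preds))


def sweep_homologs(
    labels: Sequence[tuple[str, str]],
    table: HomologTable,
    store: AnnotationStore,
    cmap: CompressMap,
    K: int,
    h_range: Sequence[int],
    allow_null_vectors: bool = False,
    backfill: bool = False,
) -> list[tuple[int, float]]:
    """Jackknife ACC as a function of the homolog count h.

    Returns one (h, acc) row per value in ``h_range``; deterministic given
    the inputs (no randomness anywhere in the pipeline).
    """
    if len(h_range) == 0:
        raise ParameterError("h_range must be nonempty")
    rows: list[tuple[int, float]] = []
    for h in h_range:
        if h < 0:
            raise ParameterError("h must be >= 0")
        data = featurize_dataset(
            labels, table, store, cmap, h,
            allow_null_vectors=allow_null_vectors, backfill=backfill,
        )
        preds = jackknife(data, K)
        rows.append((h, accuracy(confusion_from_predictions(preds))))
    return rows
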