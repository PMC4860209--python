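"""GO-frequency feature vectors.

A protein P is represented over the T mapped cellular-component terms by
per-term hit frequencies across its *representative set* — P itself plus
its top-h annotated homologs.  With n members, the value at position u is

    f_u = (# members annotated with the term at position u) / n,

so every entry lies in [0, 1] and is a multiple of 1/n; with h = 0 the
vector is exactly the query's binary annotation indicator.  A member
counts at most once per term (set semantics), however often the source
annotation file repeats a (protein, term) pair.

Because each protein's vector depends only on the annotation and homology
inputs — never on other dataset members or their labels — a dataset is
featurized once and reused across leave-one-out folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .annotations import AnnotationStore
from .errors import ParseError, ValidationError
from .homology import HomologTable, select_homologs
from .ontology import CompressMap, format_go_id, parse_go_id

logger = logging.getLogger(__name__)

# Accession curation applied when reading a label file for the benchmark of
# 317 apoptosis proteins: two cytoplasmic entries were renamed in Swiss-Prot
# (merging with entries already present) and one nuclear entry was deleted,
# leaving 314 proteins.
CL317_ACCESSION_REMAP: dict[str, str] = {"P03405": "P03404", "Q07814": "Q07812"}
CL317_EXCLUDED_ACCESSIONS: frozenset[str] = frozenset({"Q9Z1S4"})


@dataclass(frozen=True)
class RepresentativeSet:
    """The query plus its selected homologs, query first, members distinct."""

    query_ac: str
    members: tuple[str, ...]

    @property
    def n(self) -> int:
        """Denominator of the frequency features (query + retained homologs)."""
        return len(self.members)


@dataclass
class LabeledDataset:
    """Featurized labeled proteins: row order follows the label file."""

    accessions: list[str]
    labels: list[str]
    X: np.ndarray  # shape (n_proteins, T)

    def __len__(self) -> int:
        return len(self.accessions)

    def __iter__(self) -> Iterator[tuple[str, str, np.ndarray]]:
        for i in range(len(self.accessions)):
            yield self.accessions[i], self.labels[i], self.X[i]


def build_representative_set(
    ac: str,
    table: HomologTable,
    store: AnnotationStore,
    h: int,
    backfill: bool = False,
) -> RepresentativeSet:
    """Members = [ac] + selected homologs; degenerates to {ac} when none remain."""
    homologs = select_homologs(ac, table, store, h, backfill=backfill)
    members = [ac] + [m for m in homologs if m != ac]
    return RepresentativeSet(query_ac=ac, members=tuple(members))


def featurize(
    rset: RepresentativeSet, store: AnnotationStore, cmap: CompressMap
) -> np.ndarray:
    """Frequency vector of length ``cmap.T`` for one representative set."""
    vec = np.zeros(cmap.T, dtype=float)
    for member in rset.members:
        for go_id in store.terms_for(member):
            pos = cmap.position(go_id)
            if pos is not None:  # stores only hold mapped ids; guard anyway
                vec[pos] += 1.0
    vec /= rset.n
    return vec


def load_labels(
    path: str | Path,
    accession_remap: dict[str, str] | None = None,
    exclude: Iterable[str] | None = None,
) -> list[tuple[str, str]]:
    """Read a two-column (accession, class label) TSV, applying curation.

    A raw duplicate accession is a :class:`ValidationError`.  Duplicates
    *created* by the remap merge into the first occurrence when the labels
    agree (that is what an accession merge means); a label conflict is an
    error.
    """
    excluded = set(exclude or ())
    remap = accession_remap or {}
    raw: list[tuple[str, str]] = []
    seen_raw: set[str] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ParseError("expected 2 columns (accession, label)", line=lineno)
            ac, label = parts[0].strip(), parts[1].strip()
            if not ac or not label:
                raise ParseError("empty accession or label", line=lineno)
            if ac in seen_raw:
                raise ValidationError(f"duplicate accession in labels: {ac}")
            seen_raw.add(ac)
            raw.append((ac, label))
    result: list[tuple[str, str]] = []
    label_of: dict[str, str] = {}
    for ac, label in raw:
        if ac in excluded:
            logger.info("excluding accession %s from labels", ac)
            continue
        ac = remap.get(ac, ac)
        if ac in label_of:
            if label_of[ac] != label:
                raise ValidationError(
                    f"remapped accession {ac} has conflicting labels "
                    f"{label_of[ac]!r} and {label!r}"
                )
            logger.info("merging remapped duplicate accession %s", ac)
            continue
        label_of[ac] = label
        result.append((ac, label))
    return result


def featurize_dataset(
    labels: str | Path | Sequence[tuple[str, str]],
    table: HomologTable,
    store: AnnotationStore,
    cmap: CompressMap,
    h: int,
    allow_null_vectors: bool = False,
    backfill: bool = False,
    accession_remap: dict[str, str] | None = None,
    exclude: Iterable[str] | None = None,
) -> LabeledDataset:
    """Build the (n, T) feature matrix for a labeled protein list.

    ``labels`` is either a labels-TSV path or an in-memory sequence of
    (accession, label) pairs; row order is preserved.  A protein whose
    whole representative set carries no mapped CC annotation yields a null
    vector, which is an error unless ``allow_null_vectors`` — the method
    presumes every benchmark protein is GO-annotated.
    """
    if isinstance(labels, (str, Path)):
        pairs = load_labels(labels, accession_remap=accession_remap, exclude=exclude)
    else:
        pairs = list(labels)
        seen: set[str] = set()
        for ac, _ in pairs:
            if ac in seen:
                raise ValidationError(f"duplicate accession in labels: {ac}")
            seen.add(ac)
    accessions: list[str] = []
    class_labels: list[str] = []
    X = np.zeros((len(pairs), cmap.T), dtype=float)
    for i, (ac, label) in enumerate(pairs):
        rset = build_representative_set(ac, table, store, h, backfill=backfill)
        vec = featurize(rset, store, cmap)
        if not allow_null_vectors and not vec.any():
            raise ValidationError(
                f"protein {ac}: no member of its representative set has a mapped "
                "cellular_component annotation (null feature vector); pass "
                "allow_null_vectors=True to permit zero vectors"
            )
        accessions.append(ac)
        class_labels.append(label)
        X[i] = vec
    return LabeledDataset(accessions=accessions, labels=class_labels, X=X)


def write_feature_matrix(
    path: str | Path, data: LabeledDataset, cmap: CompressMap
) -> None:
    """Dense TSV export: header of GO ids, one row per protein, lossless floats."""
    go_ids = [go_id for go_id, _ in sorted(cmap.index.items(), key=lambda kv: kv[1])]
    with open(path, "w") as out:
        out.write(
            "#accession\tlabel\t" + "\t".join(format_go_id(g) for g in go_ids) + "\n"
        )
        for ac, label, vec in data:
            out.write(
                f"{ac}\t{label}\t" + "\t".join(f"{v:.17g}" for v in vec) + "\n"
            )


def read_feature_matrix(path: str | Path) -> tuple[LabeledDataset, list[int]]:
    """Read a matrix written by :func:`write_feature_matrix`.

    Returns the dataset and the GO-id column order (dense-position order).
    """
    with open(path) as handle:
        header = handle.readline()
        if not header.startswith("#accession"):
            raise ParseError("missing feature-matrix header", line=1)
        go_ids = [parse_go_id(tok) for tok in header.rstrip("\n").split("\t")[2:]]
        accessions, labels_, rows = [], [], []
        for lineno, line in enumerate(handle, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2 + len(go_ids):
                raise ParseError("row width disagrees with header", line=lineno)
            accessions.append(parts[0])
            labels_.append(parts[1])
            rows.append([float(v) for v in parts[2:]])
    X = np.asarray(rows, dtype=float) if rows else np.zeros((0, len(go_ids)))
    return LabeledDataset(accessions=accessions, labels=labels_, X=X), go_ids
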