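"""Protein → GO annotation loading.

Annotations come either from a GAF 2.x association file (the GOA exchange
format) or from a minimal two-column TSV (accession, GO id) convenient for
fixtures.  Either way the store keeps, per accession, the *set* of
cellular-component GO ids that resolve in the active compress map:
duplicates collapse, NOT-qualified rows are excluded (they assert absence,
not presence), alt ids are remapped to their primary id, and annotations
to obsolete or non-CC terms are dropped with a logged warning.

All evidence codes are accepted by default — GOA coverage outside model
organisms is dominated by electronic (IEA) annotations — but a code
whitelist can be supplied.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Collection, Iterable

from Bio.UniProt.GOA import gafiterator

from .errors import ParseError
from .ontology import CompressMap, format_go_id, parse_go_id

logger = logging.getLogger(__name__)

_GAF_COLUMNS = 17


@dataclass
class AnnotationStore:
    """Map accession → set of mapped CC GO ids (possibly empty)."""

    assoc: dict[str, frozenset[int]] = field(default_factory=dict)

    def terms_for(self, ac: str) -> frozenset[int]:
        """CC term ids annotated to ``ac``; unknown accessions give the empty set."""
        return self.assoc.get(ac, frozenset())

    def __len__(self) -> int:
        return len(self.assoc)

    def __contains__(self, ac: str) -> bool:
        return ac in self.assoc


def _add(pending: dict[str, set[int]], ac: str, go_id: int, cmap: CompressMap) -> None:
    primary = cmap.resolve_primary(go_id)
    if primary is None:
        logger.warning(
            "dropping annotation %s -> %s (not a mapped cellular_component term)",
            ac,
            format_go_id(go_id),
        )
        return
    pending.setdefault(ac, set()).add(primary)


def load_gaf(
    path: str | Path,
    cmap: CompressMap,
    evidence_codes: Collection[str] | None = None,
) -> AnnotationStore:
    """Load a GAF 2.x file, keeping aspect-C, non-NOT, resolvable rows.

    ``evidence_codes`` restricts rows to the given codes; None accepts all.
    A data row with the wrong column count raises :class:`ParseError`
    naming the 1-based line number.
    """
    path = Path(path)
    rows: list[str] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if line.startswith("!") or not line.strip():
                rows.append(line)
                continue
            ncol = len(line.rstrip("\n").split("\t"))
            if ncol != _GAF_COLUMNS:
                raise ParseError(
                    f"GAF row has {ncol} columns, expected {_GAF_COLUMNS}", line=lineno
                )
            rows.append(line)
    pending: dict[str, set[int]] = {}
    for rec in gafiterator(io.StringIO("".join(rows))):
        if rec["Aspect"] != "C":
            continue
        if any("NOT" in q for q in rec["Qualifier"]):
            continue
        if evidence_codes is not None and rec["Evidence"] not in evidence_codes:
            continue
        _add(pending, rec["DB_Object_ID"], parse_go_id(rec["GO_ID"]), cmap)
    return AnnotationStore({ac: frozenset(s) for ac, s in pending.items()})


def load_tsv_annotations(path: str | Path, cmap: CompressMap) -> AnnotationStore:
    """Load two-column (accession, GO:NNNNNNN) TSV annotations.

    Same filtering contract as :func:`load_gaf` minus the qualifier/aspect
    columns; a non-GO token in column 2 raises :class:`ParseError` with the
    line number.  An empty file yields an empty store.
    """
    pending: dict[str, set[int]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ParseError("expected 2 columns (accession, GO id)", line=lineno)
            ac, token = parts
            try:
                go_id = parse_go_id(token)
            except ParseError as exc:
                raise ParseError(str(exc), line=lineno) from exc
            _add(pending, ac, go_id, cmap)
    return AnnotationStore({ac: frozenset(s) for ac, s in pending.items()})


def terms_for(ac: str, store: AnnotationStore) -> frozenset[int]:
    """Functional alias of :meth:`AnnotationStore.terms_for`."""
    return store.terms_for(ac)
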