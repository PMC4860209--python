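"""BLAST tabular hits and selection of the top-h annotated homologs.

The method pools the GO annotations of a query with those of its most
similar database proteins ("representative proteins").  This module
consumes standard BLAST+ ``-outfmt 6`` tabular output; it never runs BLAST
itself.  Hits are ranked per query by descending bitscore (BLAST's
canonical similarity ranking), ties broken by descending percent identity
then ascending subject accession, so the ordering is deterministic across
runs.  Self-hits are removed — the query joins its own representative set
separately and must not count twice.

Homolog selection takes the first ``h`` ranked hits; a hit without any
mapped CC annotation is then discarded.  Under the default slot-consuming
policy the discarded hit is *not* replaced; with ``backfill=True`` ranked
hits beyond position ``h`` fill the vacated slots instead.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .annotations import AnnotationStore
from .errors import ParseError

_OUTFMT6_COLUMNS = 12


@dataclass(frozen=True)
class HomologHit:
    """One BLAST hit (subset of the outfmt-6 columns the ranking needs)."""

    query_ac: str
    subject_ac: str
    pident: float
    bitscore: float
    evalue: float


def _rank_key(hit: HomologHit):
    return (-hit.bitscore, -hit.pident, hit.subject_ac)


@dataclass
class HomologTable:
    """Per-query lists of hits, each sorted best-first by the ranking key."""

    hits: dict[str, list[HomologHit]] = field(default_factory=dict)

    def hits_for(self, ac: str) -> list[HomologHit]:
        return self.hits.get(ac, [])

    def __len__(self) -> int:
        return len(self.hits)


def load_blast_tab(path: str | Path) -> HomologTable:
    """Parse BLAST+ ``-outfmt 6`` (12-column) output into a ranked table.

    Rows are grouped by query, self-hits removed, lists sorted best-first.
    Non-numeric pident/evalue/bitscore raises :class:`ParseError` with the
    line number.  An empty file yields a table with no queries.
    """
    grouped: dict[str, list[HomologHit]] = {}
    with open(path) as handle:
        reader = csv.reader(handle, delimiter="\t")
        for lineno, row in enumerate(reader, 1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].startswith("#"):
                continue
            if len(row) != _OUTFMT6_COLUMNS:
                raise ParseError(
                    f"BLAST tabular row has {len(row)} columns, expected {_OUTFMT6_COLUMNS}",
                    line=lineno,
                )
            qseqid, sseqid = row[0], row[1]
            try:
                pident = float(row[2])
                evalue = float(row[10])
                bitscore = float(row[11])
            except ValueError as exc:
                raise ParseError(f"non-numeric field: {exc}", line=lineno) from exc
            if sseqid == qseqid:
                continue
            grouped.setdefault(qseqid, []).append(
                HomologHit(qseqid, sseqid, pident, bitscore, evalue)
            )
    for query, hits in grouped.items():
        hits.sort(key=_rank_key)
        # one entry per subject: keep only its best-ranked HSP
        seen: set[str] = set()
        deduped = []
        for hit in hits:
            if hit.subject_ac not in seen:
                seen.add(hit.subject_ac)
                deduped.append(hit)
        grouped[query] = deduped
    return HomologTable(grouped)


def select_homologs(
    ac: str,
    table: HomologTable,
    store: AnnotationStore,
    h: int,
    backfill: bool = False,
) -> list[str]:
    """Accessions of the homologs of ``ac`` used for feature building.

    Takes the top ``min(h, available)`` ranked hits; hits whose CC
    annotation set is empty are dropped.  Default policy: an unannotated
    hit consumes its slot (the returned list may be shorter than ``h``);
    ``backfill=True`` instead keeps walking down the ranking until ``h``
    annotated homologs are found or hits run out.
    """
    if h < 0:
        raise ValueError("h must be >= 0")
    hits = table.hits_for(ac)
    selected: list[str] = []
    if backfill:
        for hit in hits:
            if len(selected) == h:
                break
            if store.terms_for(hit.subject_ac):
                selected.append(hit.subject_ac)
    else:
        for hit in hits[:h]:
            if store.terms_for(hit.subject_ac):
                selected.append(hit.subject_ac)
    return selected
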