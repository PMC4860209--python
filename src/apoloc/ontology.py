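"""Gene Ontology parsing and the dense cellular-component term index.

GO term identifiers (``GO:0005737``) are sparse and non-contiguous, so they
cannot be used directly as positions of a feature vector.  This module
parses an OBO ontology, keeps the non-obsolete cellular-component (CC)
terms, and assigns each a dense position ``0..T-1`` in ascending numeric
GO-id order.  That index — the *compress map* — fixes the feature-vector
dimension T for everything downstream.

Ascending-id ordering is a deliberate choice: it is deterministic and
independent of the order stanzas appear in the OBO file, so the same term
set always yields a byte-identical serialized map.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import obonet

from .errors import OntologyError, ParseError

logger = logging.getLogger(__name__)

CELLULAR_COMPONENT = "cellular_component"
BIOLOGICAL_PROCESS = "biological_process"
MOLECULAR_FUNCTION = "molecular_function"

_GO_ID_RE = re.compile(r"^GO:(\d{1,7})$")


def parse_go_id(token: str) -> int:
    """Return the numeric part of a ``GO:NNNNNNN`` token.

    >>> parse_go_id("GO:0005737")
    5737
    """
    m = _GO_ID_RE.match(token.strip())
    if m is None:
        raise ParseError(f"not a GO identifier: {token!r}")
    return int(m.group(1))


def format_go_id(go_id: int) -> str:
    """Inverse of :func:`parse_go_id` (zero-padded to 7 digits)."""
    return f"GO:{go_id:07d}"


@dataclass(frozen=True)
class OntologyTerm:
    """One ontology term as read from an OBO ``[Term]`` stanza."""

    go_id: int
    namespace: str
    obsolete: bool = False
    alt_ids: frozenset[int] = frozenset()
    name: str = ""


def parse_obo(path: str | Path) -> list[OntologyTerm]:
    """Parse an OBO file into a list of :class:`OntologyTerm`.

    Obsolete terms are retained (flagged), because annotations referring to
    them must be recognized and dropped, not silently unmatched.  Raises
    :class:`OntologyError` if the file holds no ``[Term]`` stanzas and lets
    I/O errors propagate.
    """
    path = Path(path)
    with open(path) as handle:  # surfaces OSError for unreadable files
        try:
            graph = obonet.read_obo(handle, ignore_obsolete=False)
        except Exception as exc:  # malformed stanza structure
            raise ParseError(f"cannot parse OBO file {path}: {exc}") from exc
    terms: list[OntologyTerm] = []
    for node, data in graph.nodes(data=True):
        m = _GO_ID_RE.match(node)
        if m is None:
            logger.warning("skipping non-GO term id %r", node)
            continue
        alt_ids = frozenset(parse_go_id(a) for a in data.get("alt_id", []))
        terms.append(
            OntologyTerm(
                go_id=int(m.group(1)),
                namespace=data.get("namespace", ""),
                obsolete=str(data.get("is_obsolete", "")).lower() == "true",
                alt_ids=alt_ids,
                name=data.get("name", ""),
            )
        )
    if not terms:
        raise OntologyError(f"no [Term] stanzas found in {path}")
    terms.sort(key=lambda t: t.go_id)
    return terms


@dataclass(frozen=True)
class CompressMap:
    """Bijection between non-obsolete CC GO ids and dense positions 0..T-1.

    ``index`` maps primary GO ids to positions; ``alt_to_primary`` maps
    secondary (alt) ids of mapped terms onto their primary id so stale
    annotation files still resolve.
    """

    index: dict[int, int]
    alt_to_primary: dict[int, int] = field(default_factory=dict)

    @property
    def T(self) -> int:
        """Feature-vector dimension: number of mapped CC terms."""
        return len(self.index)

    def position(self, go_id: int) -> int | None:
        """Dense position of ``go_id`` (resolving alt ids), or None if unmapped."""
        if go_id in self.index:
            return self.index[go_id]
        primary = self.alt_to_primary.get(go_id)
        if primary is not None:
            return self.index[primary]
        return None

    def resolve_primary(self, go_id: int) -> int | None:
        """Primary mapped GO id for ``go_id`` (itself or via alt id), or None."""
        if go_id in self.index:
            return go_id
        return self.alt_to_primary.get(go_id)

    def to_tsv(self, path: str | Path) -> None:
        """Serialize as two-column TSV (go_id, position), ascending go_id."""
        with open(path, "w") as out:
            out.write("#go_id\tposition\n")
            for go_id in sorted(self.index):
                out.write(f"{format_go_id(go_id)}\t{self.index[go_id]}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CompressMap":
        """Read a map written by :meth:`to_tsv` (alt-id table is not persisted)."""
        index: dict[int, int] = {}
        with open(path) as handle:
            for lineno, line in enumerate(handle, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 2:
                    raise ParseError("expected 2 columns (go_id, position)", line=lineno)
                index[parse_go_id(parts[0])] = int(parts[1])
        return cls(index=index)


def build_compress_map(terms: Iterable[OntologyTerm]) -> CompressMap:
    """Assign dense positions to the non-obsolete CC terms, ascending go_id.

    Raises :class:`OntologyError` when no CC term survives the filters, and
    :class:`ValidationError`-grade problems (duplicate primary ids, alt ids
    colliding with primary ids) as :class:`OntologyError` since they make
    the ontology itself inconsistent.
    """
    terms = list(terms)
    primary_ids = [t.go_id for t in terms]
    if len(primary_ids) != len(set(primary_ids)):
        raise OntologyError("duplicate primary GO ids in ontology")
    cc = sorted(
        (t for t in terms if t.namespace == CELLULAR_COMPONENT and not t.obsolete),
        key=lambda t: t.go_id,
    )
    if not cc:
        raise OntologyError("ontology contains no usable cellular_component terms")
    index = {t.go_id: u for u, t in enumerate(cc)}
    primary_set = set(primary_ids)
    alt_to_primary: dict[int, int] = {}
    for t in cc:
        for alt in t.alt_ids:
            if alt in primary_set:
                raise OntologyError(
                    f"alt id {format_go_id(alt)} collides with a primary id"
                )
            alt_to_primary[alt] = t.go_id
    return CompressMap(index=index, alt_to_primary=alt_to_primary)


def resolve_term(go_id: int, cmap: CompressMap) -> int | None:
    """Dense position for ``go_id`` under ``cmap``; None means unmapped.

    Total function: BP/MF, obsolete and unknown ids all yield None.
    """
    return cmap.position(go_id)
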