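"""Synthetic ontology / annotation / homology / label generators.

The generators emit exactly the text formats the parsers consume (an OBO
subset, a two-column annotation TSV, BLAST outfmt-6 TSV, a labels TSV), so
every pipeline stage can be exercised end to end without touching the real
GO, GOA or Swiss-Prot releases.

The statistical model mirrors what the method assumes about real data:

* each subcellular class has a *signature* — a small, disjoint block of
  CC terms its proteins tend to carry;
* a protein carries each signature term with probability ``p_on`` and each
  off-signature term with probability ``p_noise`` (per-term Bernoulli
  noise), with one forced signature term if the draw comes up empty (the
  benchmark premise that every protein is GO-annotated);
* each protein has similarity-ranked homologs with strictly decreasing
  synthetic bitscores, whose annotation sets are per-term flipped copies
  of the protein's own set at rate ``homolog_annotation_noise``.

The defaults reproduce the benchmark's class imbalance (class sizes
110/55/34/17/51/47, 314 proteins over six locations).

:func:`make_sweep_regime` instead copies homolog annotations from the
*class signature* with a flip rate that grows with homolog rank, so close
homologs denoise the query while distant ones inject noise — the regime in
which accuracy rises and then falls with the number of homologs used.

Every generator is a pure function of its configuration (all randomness
flows from ``cfg.seed`` through one ``numpy`` Generator), so the same
config yields byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .ontology import format_go_id

DEFAULT_CLASS_LABELS = ("Cy", "Me", "Mi", "Se", "Nu", "En")
DEFAULT_CLASS_SIZES = (110, 55, 34, 17, 51, 47)

# go-id layout: sparse CC ids, decoy BP/MF ids, one obsolete CC id, one alt id
_CC_ID_BASE, _CC_ID_STEP = 1000, 10
_BP_IDS = (101, 102, 103)
_MF_IDS = (201, 202)
_OBSOLETE_CC_ID = 3
_ALT_OF_FIRST_CC = 7


@dataclass(frozen=True)
class SimulationConfig:
    """Shape and noise parameters of the synthetic benchmark."""

    n_cc_terms: int = 60
    class_sizes: tuple[int, ...] = DEFAULT_CLASS_SIZES
    class_labels: tuple[str, ...] = DEFAULT_CLASS_LABELS
    signature_size: int = 8
    p_on: float = 0.9
    p_noise: float = 0.02
    homologs_per_protein: int = 3
    homolog_annotation_noise: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("p_on", "p_noise", "homolog_annotation_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} is not a probability")
        if self.n_cc_terms < 1:
            raise ConfigError("n_cc_terms must be >= 1")
        if len(self.class_sizes) != len(self.class_labels):
            raise ConfigError("class_sizes and class_labels lengths differ")
        if any(s < 1 for s in self.class_sizes):
            raise ConfigError("every class size must be >= 1")
        if self.signature_size < 1:
            raise ConfigError("signature_size must be >= 1")
        if self.signature_size * len(self.class_sizes) > self.n_cc_terms:
            raise ConfigError(
                "signatures cannot be pairwise disjoint: "
                "signature_size * n_classes exceeds n_cc_terms"
            )
        if self.homologs_per_protein < 0:
            raise ConfigError("homologs_per_protein must be >= 0")


def cc_go_ids(cfg: SimulationConfig) -> list[int]:
    """The sparse (deliberately non-contiguous) CC GO ids of the synthetic ontology."""
    return [_CC_ID_BASE + _CC_ID_STEP * u for u in range(cfg.n_cc_terms)]


def class_signatures(cfg: SimulationConfig) -> dict[str, list[int]]:
    """Disjoint per-class signature term blocks (GO ids)."""
    ids = cc_go_ids(cfg)
    return {
        label: ids[c * cfg.signature_size : (c + 1) * cfg.signature_size]
        for c, label in enumerate(cfg.class_labels)
    }


def make_ontology(cfg: SimulationConfig) -> str:
    """OBO text with the CC terms plus decoys exercising every ontology filter.

    Includes BP/MF decoy terms (must never enter the compress map), one
    obsolete CC term, and an alt id on the first CC term.
    """
    stanzas = ["format-version: 1.2", "ontology: synthetic-go", ""]

    def stanza(go_id: int, name: str, namespace: str, obsolete=False, alt=None):
        lines = ["[Term]", f"id: {format_go_id(go_id)}", f"name: {name}",
                 f"namespace: {namespace}"]
        if alt is not None:
            lines.append(f"alt_id: {format_go_id(alt)}")
        if obsolete:
            lines.append("is_obsolete: true")
        lines.append("")
        return "\n".join(lines)

    stanzas.append(stanza(_OBSOLETE_CC_ID, "retired compartment",
                          "cellular_component", obsolete=True))
    for b in _BP_IDS:
        stanzas.append(stanza(b, f"decoy process {b}", "biological_process"))
    for m in _MF_IDS:
        stanzas.append(stanza(m, f"decoy function {m}", "molecular_function"))
    for u, go_id in enumerate(cc_go_ids(cfg)):
        stanzas.append(
            stanza(go_id, f"synthetic compartment {u}", "cellular_component",
                   alt=_ALT_OF_FIRST_CC if u == 0 else None)
        )
    return "\n".join(stanzas)


@dataclass
class SyntheticData:
    """The generated file contents, writable as a fixture tree."""

    obo: str
    labels_tsv: str
    annotations_tsv: str
    blast_tsv: str
    config: SimulationConfig = field(repr=False, default=None)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, text in (
            ("ontology.obo", self.obo),
            ("labels.tsv", self.labels_tsv),
            ("annotations.tsv", self.annotations_tsv),
            ("hits.tsv", self.blast_tsv),
        ):
            p = outdir / name
            p.write_text(text)
            paths[name.split(".")[0]] = p
        return paths


def _draw_protein_terms(
    rng: np.random.Generator, signature: list[int], others: list[int], cfg: SimulationConfig
) -> list[int]:
    terms = [g for g in signature if rng.random() < cfg.p_on]
    terms += [g for g in others if rng.random() < cfg.p_noise]
    if not terms:  # every protein is annotated (no-null-vector premise)
        terms = [signature[0]]
    return sorted(terms)


def _flip_terms(
    rng: np.random.Generator, base: set[int], universe: list[int], rate: float
) -> list[int]:
    """Per-term membership flips of ``base`` across the whole CC universe."""
    out = []
    for g in universe:
        member = g in base
        if rng.random() < rate:
            member = not member
        if member:
            out.append(g)
    return out


def _emit(cfg: SimulationConfig, homolog_model) -> SyntheticData:
    """Shared generator body.

    ``homolog_model(rng, rank, own_terms, label, signatures)`` returns the
    (base term set, per-term flip rate) for the homolog at that similarity
    rank.
    """
    rng = np.random.default_rng(cfg.seed)
    ids = cc_go_ids(cfg)
    signatures = class_signatures(cfg)
    labels_rows: list[str] = []
    annot_rows: list[str] = []
    blast_rows: list[str] = []
    idx = 0
    for label, size in zip(cfg.class_labels, cfg.class_sizes):
        signature = signatures[label]
        others = [g for g in ids if g not in signature]
        for _ in range(size):
            ac = f"SYNP{idx:05d}"
            terms = _draw_protein_terms(rng, signature, others, cfg)
            labels_rows.append(f"{ac}\t{label}")
            annot_rows.extend(f"{ac}\t{format_go_id(g)}" for g in terms)
            for rank in range(cfg.homologs_per_protein):
                sac = f"SYNH{idx:05d}R{rank}"
                base, rate = homolog_model(rng, rank, set(terms), label, signatures)
                h_terms = _flip_terms(rng, base, ids, rate)
                annot_rows.extend(f"{sac}\t{format_go_id(g)}" for g in h_terms)
                bitscore = 500.0 - 10.0 * rank  # strictly decreasing: unambiguous rank
                pident = 99.0 - rank
                evalue = 10.0 ** (-50 + rank)
                blast_rows.append(
                    f"{ac}\t{sac}\t{pident:.1f}\t100\t{rank}\t0\t1\t100\t1\t100\t"
                    f"{evalue:.1e}\t{bitscore:.1f}"
                )
            idx += 1
    return SyntheticData(
        obo=make_ontology(cfg),
        labels_tsv="\n".join(labels_rows) + "\n",
        annotations_tsv="\n".join(annot_rows) + "\n",
        blast_tsv="\n".join(blast_rows) + "\n" if blast_rows else "",
        config=cfg,
    )


def make_labeled_dataset(cfg: SimulationConfig) -> SyntheticData:
    """Class-conditional benchmark with rank-independent homolog noise."""

    def model(rng, rank, own_terms, label, signatures):
        return own_terms, cfg.homolog_annotation_noise

    return _emit(cfg, model)


def sweep_noise_schedule(rank: int) -> float:
    """Per-term flip rate of a (faithful) homolog at a similarity rank."""
    return min(0.45, 0.02 + 0.06 * rank)


def sweep_misannotation_rate(rank: int) -> float:
    """Probability that the homolog at this rank is a spurious hit.

    A spurious homolog carries another compartment's signature instead of
    the query's — the realistic failure mode of distant BLAST matches.
    The two best-ranked homologs are always faithful.
    """
    return min(1.0, max(0.0, 0.35 * (rank - 1)))


def make_sweep_regime(cfg: SimulationConfig) -> SyntheticData:
    """Fixture where homolog quality degrades with similarity rank.

    The top-ranked homologs are near-clean copies of the class signature
    (they denoise the query's Bernoulli draw), while lower ranks carry
    growing per-term flip noise (:func:`sweep_noise_schedule`) and, with
    probability :func:`sweep_misannotation_rate`, the signature of a
    uniformly chosen *other* class — distant hits are not merely noisy but
    misleading.  Pooling a few homologs therefore raises jackknife
    accuracy and pooling many lowers it.  Requires at least 3 homologs per
    protein for the shape to exist.
    """
    if cfg.homologs_per_protein < 3:
        raise ConfigError("make_sweep_regime requires homologs_per_protein >= 3")

    def model(rng, rank, own_terms, label, signatures):
        rate = sweep_noise_schedule(rank)
        if rng.random() < sweep_misannotation_rate(rank):
            other = [l for l in signatures if l != label]
            wrong = other[rng.integers(len(other))]
            return set(signatures[wrong]), rate
        return set(signatures[label]), rate

    return _emit(cfg, model)
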