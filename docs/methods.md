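# Methods

## Model and procedure

The predictor assigns a single subcellular location to a protein from the
cellular-component (CC) GO annotations of the protein and of its most
similar database proteins. It is a transduction of annotation evidence,
not a sequence model: homology enters only through a ranked hit table
(BLAST tabular output), and the ontology enters only through the set of
non-obsolete CC terms.

1. **Dense CC index.** Every non-obsolete primary CC term of the supplied
   ontology receives a position 0..T−1 in ascending numeric GO-id order.
   T is whatever the supplied release yields; nothing is hard-coded to a
   particular GO release. Secondary (alt) ids resolve to their primary
   term; annotations to obsolete or non-CC terms are dropped with a
   warning.
2. **Representative set.** For query P, hits are ranked by descending
   bitscore, ties by descending percent identity then ascending subject
   accession. The top h hits are taken; hits with no mapped CC annotation
   are discarded *after* selection (they consume their slot), so the set
   size n = N_P^h may be smaller than h+1. An optional backfill mode
   keeps walking down the ranking instead. Self-hits are removed at parse
   time; the query itself is always member 0.
3. **Features.** f_u = (members annotated with term u)/n ∈ [0,1], a
   multiple of 1/n. With h = 0 this is P's binary indicator vector.
4. **Classification.** Euclidean distance to all training vectors; the K
   nearest vote with weight 1/d; largest aggregate weight wins.
5. **Evaluation.** Leave-one-out over the labeled set, then per-class
   SN/SP/MCC and overall ACC from the one-vs-rest confusion counts.

### Assumptions

* Single-label localization: each protein has exactly one location, and
  the metric set is valid only under that assumption.
* Every benchmark protein carries at least one CC annotation, so no
  feature vector is null; a truly unannotated query is an error by
  default (`allow_null_vectors` relaxes this to a zero vector).
* Direct annotations only: no is_a/part_of ancestor propagation. The
  feature space is the flat CC term set.
* Annotation transfer by homology is informative for the top-ranked hits
  and degrades with rank.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| h (`--homologs`) | annotated homologs pooled with the query | 2 | the homolog count at which jackknife accuracy peaks; the sweep facilities re-derive this on any dataset |
| K (`--k`) | neighbors in the weighted vote | 5 | no canonical value exists for this method; 5 is a standard small odd choice and the jackknife/sweep commands accept any K ≥ 1. The K behind the original benchmark figure is unknown — the main reproducibility gap of the method as published |
| evidence codes | GAF evidence filter | accept all (incl. IEA) | GOA coverage outside model organisms is mostly electronic; a whitelist is available |
| slot policy | unannotated homolog handling | slot-consuming | the simpler literal reading of "ignore"; backfill behind a flag |
| tie-breaks | neighbor boundary / vote ties | stable (distance, index); nearest-class, then lexicographic | full determinism across runs and platforms |

## Zero distance and ties

The weight 1/d is undefined at d = 0. Zero-distance neighbors are treated
as infinitely heavy: if any of the K neighbors is at distance zero, the
vote restricts to those neighbors with uniform weights (majority among
exact matches, then the usual tie rules). Aggregate-weight ties prefer
the class of the single nearest neighbor among the K if it is tied, then
the lexicographically smallest label. Equal-weight comparison is exact
floating-point equality: ties in practice arise from symmetric integer
configurations whose weights are bit-identical, and near-ties are treated
as genuine orderings.

The jackknife computes the full pairwise distance matrix once and masks
one row per fold. This is exact, not an approximation: feature vectors
depend only on the annotation/homology inputs, never on other dataset
members or labels, so leaving a protein out changes nothing about the
remaining vectors (verified in the tests against literal
predict-on-the-rest).

MCC uses the FN/FP reformulation and equals the textbook
(TP·TN−FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)) exactly (exhaustively
tested); a vanishing denominator maps to 0, the common convention for
degenerate confusion tables. Display formatting rounds SN/SP/ACC to one
decimal percent and MCC to three decimals; machine outputs keep full
precision. On the classic benchmark's implied confusion counts two of the
six published MCC digits (Cy, Se) sit one unit below the exactly computed
values (0.95154, 0.96851) — no rounding or truncation convention
reproduces all six published digits simultaneously, so agreement with
published MCCs should be judged at ±0.001.

## Synthetic data: what it emulates, what it does not

`SimulationConfig` defaults define a benchmark-shaped world: six classes
with sizes 110/55/34/17/51/47 (314 proteins, the classic imbalance),
T = 60 CC terms, disjoint 8-term class signatures, signature terms drawn
with p_on = 0.9, off-signature terms with p_noise = 0.02, three homologs
per protein whose annotation sets are per-term flipped copies of the
protein's own set at rate 0.05. T = 60 rather than the thousands of a
real GO release keeps every test and example fast while preserving the
property that matters — sparse class-informative signatures in a larger
term universe; scale enters nowhere in the algorithm except O(T) vector
length. One signature term is forced for a protein whose Bernoulli draw
comes up empty, mirroring the premise that every benchmark protein is
annotated. The generated ontology carries decoy BP/MF terms, an obsolete
CC term and an alt id so the parsers' filters are all exercised. All
generators are pure functions of the config; the same seed gives
byte-identical files.

The sweep regime (`make_sweep_regime`) models homolog quality degrading
with similarity rank. Two components act per rank r: per-term flip noise
min(0.45, 0.02+0.06·r), and misannotation — with probability
min(1, 0.35·(r−1)) the homolog carries the signature of a uniformly
chosen *other* class. The second component is essential: symmetric flip
noise alone is class-neutral and only dilutes the features, which
measurably never reverses the accuracy curve at high h; misannotated
distant hits, the realistic failure mode of distant BLAST matches, do.
Under this regime (query draws at p_on = 0.6, p_noise = 0.08, ten
homologs per protein) jackknife accuracy rises from the low 90s at h = 0
to ~100% at h = 1–3 and falls monotonically thereafter.

What passing these tests does *not* show about real data: real CC
annotation vectors are not class-conditionally independent Bernoulli
draws (terms are correlated through the ontology graph and through
annotation pipelines), real homolog annotation error is not symmetric
per-term noise, and real class signatures overlap. The synthetic results
validate the machinery and its qualitative behavior, not the published
accuracy on the real benchmark, which depends on specific 2015
GO/GOA/Swiss-Prot releases and an unknown K and is out of scope here.

## Numerical and design choices

* Ascending-GO-id ordering for the dense index: the original compression
  scheme's ordering is unspecified; ascending id is deterministic and
  independent of file order. Any fixed bijection gives identical
  distances, so this choice cannot affect predictions — only serialized
  layouts.
* NOT-qualified GAF rows are excluded (they assert absence); duplicate
  (protein, term) pairs collapse by set semantics.
* Accession curation for the classic benchmark (merge P03405→P03404 and
  Q07814→Q07812, drop Q9Z1S4) ships as constants applied when reading a
  labels file with `--cl317-curation`; raw duplicate accessions in a
  labels file are an error, remap-induced duplicates merge when labels
  agree.
* Best HSP per (query, subject) pair is kept so a subject never occupies
  two homolog slots.
* Feature matrices serialize with `%.17g` floats and round-trip
  losslessly.

## Known limitations

* Single-label only; multi-location proteins are outside the model.
* No ancestor propagation in GO; annotations to a parent and a child
  term count as unrelated features.
* K is a free parameter with no principled default here; use the sweep /
  grid facilities on your own data.
* The homolog ranking uses bitscore; a percent-identity ranking is
  plausible too and can matter when hit tables come from other tools.
* Performance targets datasets of hundreds of proteins (dense distance
  matrix, O(N²T) jackknife); it is not engineered for proteome scale.
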