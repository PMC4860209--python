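import numpy as np
import pytest

from apoloc import (
    ConfigError,
    SimulationConfig,
    build_compress_map,
    confusion_from_predictions,
    accuracy,
    featurize_dataset,
    jackknife,
    load_blast_tab,
    load_labels,
    load_tsv_annotations,
    make_labeled_dataset,
    make_ontology,
    make_sweep_regime,
    parse_obo,
)

SMALL = dict(class_sizes=(12, 8, 6), class_labels=("a", "b", "c"), n_cc_terms=30,
             signature_size=6)


def load_all(data, tmp_path):
    paths = data.write(tmp_path / "fix")
    cmap = build_compress_map(parse_obo(paths["ontology"]))
    store = load_tsv_annotations(paths["annotations"], cmap)
    table = load_blast_tab(paths["hits"])
    pairs = load_labels(paths["labels"])
    return cmap, store, table, pairs


class TestConfigValidation:
    def test_bad_probability(self):
        with pytest.raises(ConfigError):
            SimulationConfig(p_on=1.5)

    def test_overlapping_signatures_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(n_cc_terms=10, signature_size=3,
                             class_sizes=(5, 5, 5, 5), class_labels=("a", "b", "c", "d"))

    def test_sweep_needs_homolog_depth(self):
        with pytest.raises(ConfigError):
            make_sweep_regime(SimulationConfig(homologs_per_protein=2, **{
                k: v for k, v in SMALL.items()}))


class TestOntologyFixture:
    def test_compress_map_dimension(self, tmp_path):
        cfg = SimulationConfig(seed=1, **SMALL)
        p = tmp_path / "o.obo"
        p.write_text(make_ontology(cfg))
        cmap = build_compress_map(parse_obo(p))
        assert cmap.T == cfg.n_cc_terms

    def test_decoys_never_mapped(self, tmp_path):
        from apoloc.synthetic import _BP_IDS, _MF_IDS, _OBSOLETE_CC_ID

        cfg = SimulationConfig(seed=1, **SMALL)
        p = tmp_path / "o.obo"
        p.write_text(make_ontology(cfg))
        cmap = build_compress_map(parse_obo(p))
        for decoy in (*_BP_IDS, *_MF_IDS, _OBSOLETE_CC_ID):
            assert cmap.position(decoy) is None


class TestReproducibility:
    @pytest.mark.parametrize("maker", [make_labeled_dataset, make_sweep_regime])
    def test_same_seed_byte_identical(self, maker):
        cfg = SimulationConfig(seed=42, **SMALL)
        a, b = maker(cfg), maker(cfg)
        assert (a.obo, a.labels_tsv, a.annotations_tsv, a.blast_tsv) == (
            b.obo, b.labels_tsv, b.annotations_tsv, b.blast_tsv
        )

    def test_different_seeds_differ(self):
        a = make_labeled_dataset(SimulationConfig(seed=1, **SMALL))
        b = make_labeled_dataset(SimulationConfig(seed=2, **SMALL))
        assert a.annotations_tsv != b.annotations_tsv


class TestDatasetShape:
    def test_benchmark_shaped_row_count(self, tmp_path):
        data = make_labeled_dataset(SimulationConfig(seed=0))
        _, _, _, pairs = load_all(data, tmp_path)
        assert len(pairs) == 314
        from collections import Counter

        counts = Counter(label for _, label in pairs)
        assert counts == {"Cy": 110, "Me": 55, "Mi": 34, "Se": 17, "Nu": 51, "En": 47}

    def test_roundtrip_through_parsers(self, tmp_path):
        cfg = SimulationConfig(seed=3, **SMALL)
        cmap, store, table, pairs = load_all(make_labeled_dataset(cfg), tmp_path)
        data = featurize_dataset(pairs, table, store, cmap, h=2)
        assert len(data) == sum(cfg.class_sizes)
        assert data.X.shape == (len(data), cfg.n_cc_terms)

    def test_every_protein_annotated(self, tmp_path):
        # forced signature term: even near-zero draw probabilities leave no
        # protein without a mapped CC annotation
        cfg = SimulationConfig(seed=5, p_on=0.01, p_noise=0.0, **SMALL)
        cmap, store, table, pairs = load_all(make_labeled_dataset(cfg), tmp_path)
        for ac, _ in pairs:
            assert store.terms_for(ac)


class TestDegenerateLimit:
    def test_zero_noise_vectors_identical_within_orthogonal_between(self, tmp_path):
        cfg = SimulationConfig(seed=9, p_on=1.0, p_noise=0.0,
                               homolog_annotation_noise=0.0, **SMALL)
        cmap, store, table, pairs = load_all(make_labeled_dataset(cfg), tmp_path)
        data = featurize_dataset(pairs, table, store, cmap, h=2)
        by_class: dict[str, list[np.ndarray]] = {}
        for (_, label, vec) in data:
            by_class.setdefault(label, []).append(vec)
        for label, vecs in by_class.items():
            for v in vecs[1:]:
                assert np.array_equal(v, vecs[0])
        classes = list(by_class)
        for i in range(len(classes)):
            for j in range(i + 1, len(classes)):
                assert float(by_class[classes[i]][0] @ by_class[classes[j]][0]) == 0.0


class TestSignalControl:
    def test_accuracy_monotone_in_annotation_noise(self, tmp_path):
        """Mean jackknife accuracy does not rise when p_noise grows."""
        levels = [0.02, 0.2, 0.4]
        means = []
        for p_noise in levels:
            accs = []
            for seed in range(5):
                cfg = SimulationConfig(seed=seed, p_on=0.75, p_noise=p_noise, **SMALL)
                cmap, store, table, pairs = load_all(make_labeled_dataset(cfg), tmp_path / f"{p_noise}-{seed}")
                data = featurize_dataset(pairs, table, store, cmap, h=2)
                preds = jackknife(data, K=3)
                accs.append(accuracy(confusion_from_predictions(preds)))
            means.append(float(np.mean(accs)))
        tol = 0.03  # sampling-error slack on 26-protein datasets
        assert means[0] >= means[1] - tol
        assert means[1] >= means[2] - tol
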