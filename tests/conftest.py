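import pytest
from hypothesis import settings

from apoloc import (
    build_compress_map,
    load_blast_tab,
    load_tsv_annotations,
    parse_obo,
)

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

TINY_OBO = """\
format-version: 1.2
ontology: tiny

[Term]
id: GO:0000001
name: compartment one
namespace: cellular_component
alt_id: GO:0000004

[Term]
id: GO:0000005
name: process five
namespace: biological_process

[Term]
id: GO:0000007
name: retired compartment
namespace: cellular_component
is_obsolete: true

[Term]
id: GO:0000009
name: compartment nine
namespace: cellular_component

[Term]
id: GO:0000013
name: compartment thirteen
namespace: cellular_component

[Term]
id: GO:0000021
name: compartment twenty-one
namespace: cellular_component
"""

# P1: terms 1, 9 / P2: term 13 / H1: 1, 13 / H2: 13 / H3: unannotated (only BP)
TINY_ANNOTATIONS = """\
P1\tGO:0000001
P1\tGO:0000009
P2\tGO:0000013
H1\tGO:0000001
H1\tGO:0000013
H2\tGO:0000013
H3\tGO:0000005
"""

# query P1: hits H1 (best), H3, H2, plus a self-hit to be dropped
TINY_BLAST = """\
P1\tH1\t95.0\t100\t5\t0\t1\t100\t1\t100\t1e-50\t200.0
P1\tH3\t90.0\t100\t10\t0\t1\t100\t1\t100\t1e-40\t150.0
P1\tH2\t85.0\t100\t15\t0\t1\t100\t1\t100\t1e-30\t100.0
P1\tP1\t100.0\t100\t0\t0\t1\t100\t1\t100\t0.0\t300.0
"""


@pytest.fixture
def tiny_obo(tmp_path):
    p = tmp_path / "tiny.obo"
    p.write_text(TINY_OBO)
    return p


@pytest.fixture
def tiny_terms(tiny_obo):
    return parse_obo(tiny_obo)


@pytest.fixture
def tiny_cmap(tiny_terms):
    return build_compress_map(tiny_terms)


@pytest.fixture
def tiny_store(tmp_path, tiny_cmap):
    p = tmp_path / "ann.tsv"
    p.write_text(TINY_ANNOTATIONS)
    return load_tsv_annotations(p, tiny_cmap)


@pytest.fixture
def tiny_table(tmp_path):
    p = tmp_path / "hits.tsv"
    p.write_text(TINY_BLAST)
    return load_blast_tab(p)
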