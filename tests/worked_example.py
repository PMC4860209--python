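"""The six-location benchmark worked example shared across tests.

Class sizes and the per-class false-negative / false-positive counts that
the published per-class sensitivities and specificities imply, together
with an explicit routing of each misclassified protein to a destination
class that realizes exactly those counts.
"""

SIZES = {"Cy": 110, "Me": 55, "Mi": 34, "Se": 17, "Nu": 51, "En": 47}
FN = {"Cy": 2, "Me": 1, "Mi": 1, "Se": 1, "Nu": 5, "En": 0}
FP = {"Cy": 5, "Me": 1, "Mi": 2, "Se": 0, "Nu": 2, "En": 0}
N = sum(SIZES.values())

# destination classes of each class's false negatives; column sums give FP
ROUTES = {
    "Cy": ["Nu", "Nu"],
    "Me": ["Cy"],
    "Mi": ["Cy"],
    "Se": ["Cy"],
    "Nu": ["Cy", "Cy", "Me", "Mi", "Mi"],
    "En": [],
}


def benchmark_predictions():
    """(accession, truth, prediction) triples realizing SIZES/FN/FP exactly."""
    received = {c: 0 for c in SIZES}
    preds = []
    i = 0
    for cls, size in SIZES.items():
        routes = ROUTES[cls]
        assert len(routes) == FN[cls]
        for j in range(size):
            if j < len(routes):
                target = routes[j]
                assert target != cls
                received[target] += 1
                preds.append((f"P{i}", cls, target))
            else:
                preds.append((f"P{i}", cls, cls))
            i += 1
    assert received == FP
    return preds
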