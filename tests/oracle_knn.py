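"""Independent brute-force oracle for the distance-weighted KNN vote.

Deliberately written in plain Python with explicit loops and no reuse of
the package's classifier internals, so it can serve as an oracle.  It
implements the same documented decision rules: stable (distance, index)
neighbor order, infinitely-heavy zero-distance neighbors, nearest-label
then lexicographic tie-breaking.
"""

import math


def brute_force_predict(query, X, labels, K):
    dists = []
    for i, row in enumerate(X):
        s = 0.0
        for a, b in zip(row, query):
            s += (a - b) ** 2
        dists.append((math.sqrt(s), i))
    dists.sort(key=lambda t: (t[0], t[1]))
    top = dists[:K]
    zero = [(d, i) for d, i in top if d == 0.0]
    voters = zero if zero else top
    weights = {}
    for d, i in voters:
        w = 1.0 if zero else 1.0 / d
        weights[labels[i]] = weights.get(labels[i], 0.0) + w
    best = max(weights.values())
    tied = sorted(label for label, w in weights.items() if w == best)
    nearest_label = labels[voters[0][1]]
    return nearest_label if nearest_label in tied else tied[0]


def standard_mcc(n_pos, n_neg, fn, fp):
    """Textbook MCC from the one-vs-rest confusion table; 0 on zero denominator."""
    tp = n_pos - fn
    tn = n_neg - fp
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if den == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(den)
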