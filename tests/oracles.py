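"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's incremental algorithms: the
linkage oracle recomputes every inter-cluster squared centroid distance
from the original matrix at every step, and the silhouette oracle
evaluates the definition point by point.
"""

from itertools import combinations

import numpy as np


def naive_centroid_linkage(sq: np.ndarray) -> np.ndarray:
    """Centroid-criterion linkage by explicit per-step recomputation.

    The squared centroid distance between clusters A and B is evaluated
    directly from the squared input distances as

        mean(d2[A, B]) - mean(d2[A, A]) / 2 - mean(d2[B, B]) / 2

    (the centroid identity, self-pairs included in the within means).
    Ties pick the lexicographically smallest cluster-id pair.  Heights
    are square roots of the minimal squared distance, clipped at zero.
    """
    n = sq.shape[0]
    d2 = np.asarray(sq, dtype=float) ** 2
    clusters = {i: [i] for i in range(n)}
    merges = np.empty((n - 1, 4))
    for t in range(n - 1):
        best = None
        for ci, cj in combinations(sorted(clusters), 2):
            A, B = clusters[ci], clusters[cj]
            val = (
                d2[np.ix_(A, B)].mean()
                - d2[np.ix_(A, A)].mean() / 2
                - d2[np.ix_(B, B)].mean() / 2
            )
            key = (val, ci, cj)
            if best is None or key < best:
                best = key
        val, ci, cj = best
        merged = clusters.pop(ci) + clusters.pop(cj)
        clusters[n + t] = merged
        merges[t] = (ci, cj, np.sqrt(max(val, 0.0)), len(merged))
    return merges


def naive_silhouette(sq: np.ndarray, labels) -> float:
    """Pointwise evaluation of the mean silhouette coefficient."""
    labels = np.asarray(labels)
    s = []
    for i in range(len(labels)):
        own = np.flatnonzero((labels == labels[i]))
        if len(own) == 1:
            s.append(0.0)
            continue
        a = sq[i, own[own != i]].mean()
        b = min(
            sq[i, labels == c].mean() for c in np.unique(labels) if c != labels[i]
        )
        s.append(0.0 if max(a, b) == 0 else (b - a) / max(a, b))
    return float(np.mean(s))
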