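"""Agglomerative hierarchical clustering with the centroid-linkage criterion.

The linkage operates directly on a precomputed distance matrix: inputs
are squared and the squared centroid distance between merged clusters is
maintained with the Lance-Williams centroid recurrence

    D2(k, i+j) = (n_i D2(k,i) + n_j D2(k,j)) / (n_i + n_j)
                 - n_i n_j D2(i,j) / (n_i + n_j)^2.

At each step the pair of active clusters with minimal squared centroid
distance is merged; ties are broken by the lexicographically smallest
(cluster_id_a, cluster_id_b) pair, which makes the merge sequence fully
deterministic.  Recorded merge heights are square roots of the minimal
squared distance (clipped at zero: on non-Euclidean input the recurrence
can produce small negative values).

Because the input distance is generally non-Euclidean, dendrogram
*inversions* (a merge lower than an earlier one) are possible and
legitimate under centroid linkage; nothing here assumes monotone
heights.  Cluster ids follow the usual linkage convention: leaves are
0..n-1 and the cluster created by merge t is n+t.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .distance import DistanceMatrix
from .errors import ConfigError, DataError

__all__ = [
    "LinkageTree",
    "ClusterAssignment",
    "centroid_linkage",
    "average_linkage",
    "cut_tree",
    "silhouette_score",
    "leaf_order",
    "largest_gap_heights",
    "write_linkage",
    "read_linkage",
    "write_assignment",
    "read_assignment",
]


@dataclass(frozen=True)
class LinkageTree:
    """Merge sequence of an agglomerative clustering.

    ``merges`` is an (n_leaves - 1, 4) float array with columns
    (cluster_a, cluster_b, height, new_size), cluster_a < cluster_b.
    """

    merges: np.ndarray
    n_leaves: int
    ids: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.merges.shape != (self.n_leaves - 1, 4):
            raise DataError(
                f"expected {self.n_leaves - 1} merges, got {self.merges.shape}"
            )
        if self.ids is not None and len(self.ids) != self.n_leaves:
            raise DataError("ids length does not match n_leaves")
        if self.n_leaves > 1 and int(self.merges[-1, 3]) != self.n_leaves:
            raise DataError("final merged cluster does not contain all leaves")

    def to_scipy(self) -> np.ndarray:
        """The merge table in scipy's 4-column linkage-matrix layout."""
        return np.asarray(self.merges, dtype=float)


@dataclass(frozen=True)
class ClusterAssignment:
    """Flat labels 1..k over an ordered id axis; no cluster is empty."""

    ids: tuple[str, ...]
    labels: np.ndarray
    k: int
    names: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.ids):
            raise DataError("labels length does not match ids")
        present = set(int(v) for v in self.labels)
        if present != set(range(1, self.k + 1)):
            raise DataError(
                f"labels must be exactly 1..{self.k} with no empty cluster; "
                f"found {sorted(present)}"
            )
        if self.names is not None and len(self.names) != self.k:
            raise DataError("names length does not match k")

    def as_dict(self) -> dict[str, int]:
        return {i: int(v) for i, v in zip(self.ids, self.labels)}

    def members(self, label: int) -> list[str]:
        return [i for i, v in zip(self.ids, self.labels) if int(v) == label]


def _as_square(d: Union[DistanceMatrix, np.ndarray]):
    if isinstance(d, DistanceMatrix):
        return d.square(), d.ids
    sq = np.asarray(d, dtype=float)
    if sq.ndim != 2 or sq.shape[0] != sq.shape[1]:
        raise DataError("distance input must be square or a DistanceMatrix")
    if not np.allclose(sq, sq.T, rtol=1e-12, atol=1e-12):
        raise DataError("distance matrix must be symmetric")
    return sq, None


def centroid_linkage(d: Union[DistanceMatrix, np.ndarray]) -> LinkageTree:
    """Centroid-criterion agglomerative clustering of a distance matrix.

    Nearest-pair bookkeeping keeps the typical cost near O(n^2); worst
    case is O(n^3) when many rows' nearest neighbours are invalidated at
    every step.
    """
    sq, ids = _as_square(d)
    n = sq.shape[0]
    if n < 2:
        raise DataError("centroid linkage requires at least 2 observations")

    D2 = sq.astype(float) ** 2
    np.fill_diagonal(D2, np.inf)
    active = np.ones(n, dtype=bool)
    cid = np.arange(n)  # cluster id currently held by each slot
    size = np.ones(n, dtype=np.int64)
    nn_val = D2.min(axis=1)
    nn_idx = D2.argmin(axis=1)

    merges = np.empty((n - 1, 4))
    for t in range(n - 1):
        masked = np.where(active, nn_val, np.inf)
        m = masked.min()
        rows = np.flatnonzero(masked == m)
        pairs = set()
        for i in rows:
            for j in np.flatnonzero(D2[i] == m):
                if active[j]:
                    pairs.add((min(i, j), max(i, j)))
        i, j = min(pairs, key=lambda p: (min(cid[p[0]], cid[p[1]]),
                                         max(cid[p[0]], cid[p[1]])))
        ca, cb = sorted((int(cid[i]), int(cid[j])))
        si, sj = int(size[i]), int(size[j])
        merges[t] = (ca, cb, math.sqrt(max(m, 0.0)), si + sj)

        # Lance-Williams centroid update into slot i; retire slot j.
        tot = si + sj
        new_row = (si * D2[:, i] + sj * D2[:, j]) / tot - si * sj * m / tot**2
        D2[:, i] = new_row
        D2[i, :] = new_row
        D2[i, i] = np.inf
        D2[j, :] = np.inf
        D2[:, j] = np.inf
        active[j] = False
        nn_val[j] = np.inf
        size[i] = tot
        cid[i] = n + t
        if t == n - 2:
            break

        nn_val[i] = D2[i].min()
        nn_idx[i] = D2[i].argmin()
        # rows whose cached nearest neighbour was invalidated
        stale = active & ((nn_idx == i) | (nn_idx == j))
        stale[i] = False
        for r in np.flatnonzero(stale):
            nn_val[r] = D2[r].min()
            nn_idx[r] = D2[r].argmin()
        # rows for which the new cluster is now the nearest neighbour
        better = active & (D2[:, i] < nn_val)
        better[i] = False
        nn_val[better] = D2[better, i]
        nn_idx[better] = i

    return LinkageTree(merges, n, ids)


def average_linkage(d: Union[DistanceMatrix, np.ndarray]) -> LinkageTree:
    """Average-linkage (UPGMA) clustering, for sanity comparison only."""
    sq, ids = _as_square(d)
    if sq.shape[0] < 2:
        raise DataError("linkage requires at least 2 observations")
    from scipy.spatial.distance import squareform

    Z = sch.linkage(squareform(sq, checks=False), method="average")
    return LinkageTree(np.asarray(Z, dtype=float), sq.shape[0], ids)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def cut_tree(
    tree: LinkageTree,
    k: Optional[int] = None,
    height: Optional[float] = None,
    ids: Optional[Sequence[str]] = None,
) -> ClusterAssignment:
    """Extract flat clusters from a linkage tree.

    Exactly one of ``k`` and ``height`` must be given.  Cutting at ``k``
    undoes the last k-1 merges *by merge order*, which remains well
    defined when centroid linkage produces inversions.  Cutting at a
    ``height`` keeps every merge whose height is <= the threshold and
    takes connected components (an inverted merge below the threshold
    whose children formed above it connects nothing on its own).

    Labels 1..k are assigned by order of first member appearance in the
    original leaf order.
    """
    if (k is None) == (height is None):
        raise ConfigError("specify exactly one of k or height")
    n = tree.n_leaves
    if k is not None and not 1 <= k <= n:
        raise ConfigError(f"k={k} out of range 1..{n}")
    if height is not None and height < 0:
        raise ConfigError(f"height must be non-negative, got {height}")

    uf = _UnionFind(2 * n - 1)
    if k is not None:
        applied = range(n - k)
    else:
        applied = [t for t in range(n - 1) if tree.merges[t, 2] <= height]
    for t in applied:
        node = n + t
        uf.union(node, int(tree.merges[t, 0]))
        uf.union(node, int(tree.merges[t, 1]))

    labels = np.empty(n, dtype=int)
    label_of_root: dict[int, int] = {}
    for leaf in range(n):
        root = uf.find(leaf)
        labels[leaf] = label_of_root.setdefault(root, len(label_of_root) + 1)

    out_ids = tuple(ids) if ids is not None else (
        tree.ids if tree.ids is not None else tuple(str(i) for i in range(n))
    )
    return ClusterAssignment(out_ids, labels, len(label_of_root))


def silhouette_score(
    d: Union[DistanceMatrix, np.ndarray],
    assignment: Union[ClusterAssignment, Sequence[int]],
) -> float:
    """Mean silhouette coefficient on a precomputed distance matrix.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)) with a(i) the mean
    within-cluster distance (excluding i) and b(i) the smallest mean
    distance to another cluster; members of singleton clusters
    contribute s(i) = 0.  Requires k >= 2.
    """
    sq, ids = _as_square(d)
    n = sq.shape[0]
    if isinstance(assignment, ClusterAssignment):
        if ids is not None and assignment.ids != ids:
            raise DataError("assignment ids do not match distance matrix ids")
        labels = np.asarray(assignment.labels, dtype=int)
    else:
        labels = np.asarray(assignment, dtype=int)
    if len(labels) != n:
        raise DataError("labels length does not match distance matrix")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise DataError("silhouette requires at least 2 clusters")

    sums = np.stack([sq[:, labels == c].sum(axis=1) for c in uniq], axis=1)
    counts = np.array([(labels == c).sum() for c in uniq])
    own = np.searchsorted(uniq, labels)

    s = np.zeros(n)
    for i in range(n):
        c = own[i]
        if counts[c] == 1:
            continue  # singleton convention
        a = sums[i, c] / (counts[c] - 1)
        other = np.delete(sums[i] / counts, c)
        b = other.min()
        denom = max(a, b)
        if denom > 0:
            s[i] = (b - a) / denom
    return float(s.mean())


def leaf_order(tree: LinkageTree) -> np.ndarray:
    """Left-to-right dendrogram leaf order.

    At each junction the subtree containing the smaller original leaf
    index is traversed first, so the order is deterministic and places
    the members of the first merge adjacently.
    """
    n = tree.n_leaves
    min_leaf = np.arange(2 * n - 1)
    children = {}
    for t in range(n - 1):
        a, b = int(tree.merges[t, 0]), int(tree.merges[t, 1])
        children[n + t] = (a, b)
        min_leaf[n + t] = min(min_leaf[a], min_leaf[b])

    order = []
    stack = [2 * n - 2]
    while stack:
        node = stack.pop()
        if node < n:
            order.append(node)
            continue
        a, b = children[node]
        first, second = (a, b) if min_leaf[a] <= min_leaf[b] else (b, a)
        stack.append(second)
        stack.append(first)
    return np.asarray(order, dtype=np.intp)


def largest_gap_heights(tree: LinkageTree) -> float:
    """Diagnostic cut height at the largest gap between sorted merge
    heights.  Provided for exploration only; flat cluster counts from
    automatic criteria tend to be very unbalanced on cohort data, so
    ``k`` stays an explicit user input in the pipeline."""
    h = np.sort(tree.merges[:, 2])
    if len(h) < 2:
        return float(h[0]) if len(h) else 0.0
    gaps = np.diff(h)
    i = int(np.argmax(gaps))
    return float((h[i] + h[i + 1]) / 2.0)


# ---------------------------------------------------------------------------
# Delimited-text IO
# ---------------------------------------------------------------------------


def write_linkage(tree: LinkageTree, path, delimiter: str = ",") -> None:
    df = pd.DataFrame(
        {
            "merge_index": np.arange(tree.n_leaves - 1),
            "cluster_a": tree.merges[:, 0].astype(int),
            "cluster_b": tree.merges[:, 1].astype(int),
            "height": [repr(float(v)) for v in tree.merges[:, 2]],
            "new_size": tree.merges[:, 3].astype(int),
        }
    )
    df.to_csv(path, sep=delimiter, index=False)


def read_linkage(path, delimiter: str = ",") -> LinkageTree:
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    merges = np.column_stack(
        [
            df["cluster_a"].to_numpy(float),
            df["cluster_b"].to_numpy(float),
            df["height"].to_numpy(float),
            df["new_size"].to_numpy(float),
        ]
    )
    return LinkageTree(merges, len(df) + 1)


def write_assignment(assignment: ClusterAssignment, path, delimiter: str = ",") -> None:
    pd.DataFrame(
        {"pregnancy_id": assignment.ids, "cluster_label": assignment.labels}
    ).to_csv(path, sep=delimiter, index=False)


def read_assignment(path, delimiter: str = ",") -> ClusterAssignment:
    df = pd.read_csv(path, sep=delimiter, dtype={"pregnancy_id": str})
    labels = df["cluster_label"].to_numpy(int)
    return ClusterAssignment(
        tuple(df["pregnancy_id"]), labels, int(labels.max()) if len(labels) else 0
    )
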