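"""Optional dendrogram / heatmap export hooks (requires matplotlib)."""

from __future__ import annotations

from typing import Optional, Union

import numpy as np

from .distance import DistanceMatrix
from .hca import LinkageTree, leaf_order


def _require_matplotlib():
    try:
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "plotting requires matplotlib; install comedclust[plot]"
        ) from exc
    return plt


def plot_dendrogram(tree: LinkageTree, ax=None, **kwargs):
    """Draw the merge dendrogram (inversions are drawn as-is)."""
    import scipy.cluster.hierarchy as sch

    plt = _require_matplotlib()
    if ax is None:
        _, ax = plt.subplots()
    sch.dendrogram(tree.to_scipy(), ax=ax, no_labels=tree.n_leaves > 50, **kwargs)
    ax.set_ylabel("merge height")
    return ax


def plot_heatmap(
    d: Union[DistanceMatrix, np.ndarray],
    tree: Optional[LinkageTree] = None,
    ax=None,
    **kwargs,
):
    """Pairwise-distance heatmap, rows/columns in dendrogram leaf order."""
    plt = _require_matplotlib()
    sq = d.square() if isinstance(d, DistanceMatrix) else np.asarray(d)
    if tree is not None:
        order = leaf_order(tree)
        sq = sq[np.ix_(order, order)]
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(sq, cmap=kwargs.pop("cmap", "viridis"), **kwargs)
    ax.figure.colorbar(im, ax=ax, label="pairwise distance")
    return ax
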