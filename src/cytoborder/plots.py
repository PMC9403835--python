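"""Diagnostic plots: distance functions, multi-scale candidate matrices,
dendrograms and discriminant scatter."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_distance_function", "plot_block_size_matrix",
           "plot_dendrogram", "plot_discriminant"]


def plot_distance_function(dist, ax=None, mark_maxima=True):
    """Mahalanobis distance vs. profile index, significant maxima circled."""
    import matplotlib.pyplot as plt

    from .borders import detect_maxima

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(dist.positions, dist.d2, lw=1, color="k")
    if mark_maxima:
        for k in detect_maxima(dist):
            i = int(np.nonzero(dist.positions == k)[0][0])
            ax.plot(k, dist.d2[i], "o", mfc="none", mec="red", ms=9)
    ax.set_xlabel("profile index")
    ax.set_ylabel("Mahalanobis distance $D^2$")
    ax.set_title(f"block size b = {dist.block_size}")
    return ax


def plot_block_size_matrix(candidates_by_block_size, consensus=None, ax=None):
    """Candidate maxima as dots in the (profile index, block size) plane."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for b, ks in sorted(candidates_by_block_size.items()):
        for k in ks:
            ax.plot(k, b, "k.", ms=6)
    if consensus:
        for c in consensus:
            ax.axvline(c.position, color="red", lw=0.8, alpha=0.6)
    ax.set_xlabel("profile index")
    ax.set_ylabel("block size")
    return ax


def plot_dendrogram(dendro, ax=None, **kw):
    import matplotlib.pyplot as plt
    from scipy.cluster import hierarchy

    if ax is None:
        _, ax = plt.subplots()
    hierarchy.dendrogram(dendro.linkage_matrix, labels=list(dendro.leaf_labels),
                         ax=ax, orientation=kw.pop("orientation", "right"), **kw)
    ax.set_xlabel("linkage distance")
    return ax


def plot_discriminant(proj, ax=None):
    """Scatter of observations on the first two discriminant axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for c, cen in proj.centroids.items():
        ax.plot(*cen[:2], "x", ms=12, mew=3, label=str(c))
    ax.scatter(proj.coords[:, 0], proj.coords[:, 1] if proj.coords.shape[1] > 1
               else np.zeros(len(proj.coords)), s=14, alpha=0.6, color="gray")
    ax.set_xlabel("canonical axis 1")
    ax.set_ylabel("canonical axis 2")
    ax.legend(title="class")
    return ax
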