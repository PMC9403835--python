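"""Cytoarchitectonic similarity analyses.

Areas are compared through the 10-feature vectors of their mean GLI
profiles: agglomerative hierarchical clustering with Euclidean distance
and Ward linkage quantifies between-area dissimilarity, and a canonical
discriminant projection (at most two axes) visualizes class separation.
Features are z-scored by default before clustering; dendrogram heights
are reported as the Ward merge cost (the increase in within-cluster sum
of squares), not its square root, since conventions differ across
packages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.linalg import eigh

__all__ = ["Dendrogram", "DiscriminantProjection", "hierarchical_cluster",
           "canonical_discriminant"]


@dataclass
class Dendrogram:
    """Agglomerative merge tree with Ward merge costs as heights."""

    merges: np.ndarray        # (n-1, 4): cluster a, cluster b, height, new size
    leaf_labels: tuple
    linkage_matrix: np.ndarray  # scipy linkage (heights on scipy's scale)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def cut(self, n_clusters: int) -> np.ndarray:
        """Flat cluster labels for a horizontal cut into ``n_clusters``."""
        return hierarchy.fcluster(self.linkage_matrix, n_clusters, criterion="maxclust")

    def to_newick(self) -> str:
        """Newick string; branch lengths are height increments."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def rec(node, parent_height):
            h = node.dist**2 / 2.0
            length = max(parent_height - h, 0.0)
            if node.is_leaf():
                return f"{self.leaf_labels[node.id]}:{length:.6g}"
            return (f"({rec(node.left, h)},{rec(node.right, h)}):{length:.6g}")

        root_h = tree.dist**2 / 2.0
        return rec(tree, root_h) + ";"


@dataclass
class DiscriminantProjection:
    """Canonical discriminant axes, projected coordinates and centroids."""

    axes: np.ndarray          # (n_features, n_axes)
    coords: np.ndarray        # (n_obs, n_axes)
    centroids: dict           # class -> (n_axes,) centroid
    eigenvalues: np.ndarray
    classes: tuple
    degenerate: bool = False


def _prepare(X, standardize):
    X = np.atleast_2d(np.asarray(X, float))
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        X = (X - mu) / sd
    return X


def hierarchical_cluster(features, labels=None, standardize: bool = True) -> Dendrogram:
    """Ward-linkage agglomerative clustering of feature vectors.

    At every step the pair of clusters whose union minimally increases the
    within-cluster sum of squares is merged; reported heights are that
    Ward cost increase.
    """
    X = _prepare(features, standardize)
    n = X.shape[0]
    labels = tuple(labels) if labels is not None else tuple(range(n))
    if len(labels) != n:
        raise ValueError("one label per observation required")
    Z = hierarchy.linkage(X, method="ward", metric="euclidean")
    merges = Z.copy()
    merges[:, 2] = Z[:, 2] ** 2 / 2.0  # scipy height d -> Ward merge cost d^2/2
    return Dendrogram(merges=merges, leaf_labels=labels, linkage_matrix=Z)


def canonical_discriminant(features, classes, n_axes: int = 2,
                           standardize: bool = False,
                           shrinkage_ladder=(0.0, 1e-4, 1e-3, 1e-2)) -> DiscriminantProjection:
    """Canonical discriminant (Fisher) projection of labelled feature vectors.

    Axes are the leading eigenvectors of ``Sw^-1 Sb`` (within- and
    between-class scatter); at most ``min(n_classes - 1, n_axes)`` axes are
    returned, orthogonal under the within-class metric.  A degenerate
    between-class scatter (identical class means) is flagged.
    """
    X = _prepare(features, standardize)
    y = np.asarray(classes)
    if len(y) != X.shape[0]:
        raise ValueError("one class label per observation required")
    uniq = sorted(set(y.tolist()))
    if len(uniq) < 2:
        raise ValueError("need at least 2 classes")
    for c in uniq:
        if (y == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 observations")

    grand = X.mean(axis=0)
    p = X.shape[1]
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    for c in uniq:
        Xc = X[y == c]
        mc = Xc.mean(axis=0)
        Sw += (Xc - mc).T @ (Xc - mc)
        Sb += len(Xc) * np.outer(mc - grand, mc - grand)

    solved = False
    for lam in shrinkage_ladder:
        Sws = (1.0 - lam) * Sw + lam * np.diag(np.diag(Sw))
        ev = np.linalg.eigvalsh(Sws)
        if ev[0] > 0 and ev[-1] / ev[0] < 1e8:
            solved = True
            break
    if not solved:
        raise np.linalg.LinAlgError("within-class scatter singular after maximal shrinkage")

    w, v = eigh(Sb, Sws)
    order = np.argsort(w)[::-1]
    k = min(len(uniq) - 1, n_axes)
    axes = v[:, order[:k]]
    eigenvalues = w[order[:k]]
    degenerate = bool(eigenvalues.max(initial=0.0) <= 1e-10)
    coords = X @ axes
    centroids = {c: coords[y == c].mean(axis=0) for c in uniq}
    return DiscriminantProjection(axes=axes, coords=coords, centroids=centroids,
                                  eigenvalues=eigenvalues, classes=tuple(uniq),
                                  degenerate=degenerate)
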