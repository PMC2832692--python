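"""Relatedness analysis over feature vectors.

Pairwise Euclidean distances, a PCA projection (SVD of the centered data
with a deterministic sign convention), and agglomerative hierarchical
clustering with complete linkage.  The clustering is implemented here
rather than delegated because a deterministic tie-break is required:
among equally distant cluster pairs, the pair whose lexicographically
smallest member ids come first is merged.  Merge heights are identical to
any correct complete-linkage implementation; only tie resolution differs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)


def _as_matrix(vectors) -> tuple[list[str], np.ndarray]:
    """Accept a list of FeatureVectors or an (ids, matrix) pair."""
    if isinstance(vectors, tuple) and len(vectors) == 2:
        ids, X = vectors
        return list(ids), np.asarray(X, dtype=float)
    vectors = list(vectors)
    ids = [v.sequence_id for v in vectors]
    dims = {len(v.components) for v in vectors}
    if len(dims) > 1:
        raise ValueError(f"vectors have mixed dimensions {sorted(dims)}")
    X = np.vstack([v.components for v in vectors])
    return ids, X


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise Euclidean distances with zero diagonal."""

    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "ids", tuple(self.ids))
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match id count")
        if np.any(np.isnan(d)):
            raise ValueError("distance matrix contains NaN")
        if np.max(np.abs(d - d.T), initial=0.0) > 1e-9:
            raise ValueError("distance matrix is asymmetric")


@dataclass(frozen=True)
class PCAResult:
    """Scores, orthonormal loadings and per-component explained variance."""

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray


@dataclass(frozen=True)
class Dendrogram:
    """Complete-linkage merge tree.

    ``merges`` is a list of (cluster_a, cluster_b, height) where clusters
    0..n-1 are the leaves (in ``leaves`` order) and cluster n+k is the one
    formed by merge k.  ``linkage`` is the equivalent scipy-style matrix.
    """

    leaves: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]

    @property
    def linkage(self) -> np.ndarray:
        """Scipy-compatible (n-1) x 4 linkage matrix."""
        n = len(self.leaves)
        sizes = {i: 1 for i in range(n)}
        Z = np.zeros((len(self.merges), 4))
        for k, (a, b, h) in enumerate(self.merges):
            size = sizes[a] + sizes[b]
            sizes[n + k] = size
            Z[k] = [a, b, h, size]
        return Z

    def cut(self, k: int) -> np.ndarray:
        """Labels (0..k-1) from cutting the tree into k flat clusters."""
        n = len(self.leaves)
        if not 1 <= k <= n:
            raise ValueError(f"k must be in 1..{n}")
        from scipy.cluster.hierarchy import fcluster

        return fcluster(self.linkage, t=k, criterion="maxclust") - 1


def euclidean_distance(u, v) -> float:
    """Euclidean distance between two feature vectors of equal dimension."""
    a = np.asarray(getattr(u, "components", u), dtype=float)
    b = np.asarray(getattr(v, "components", v), dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def distance_matrix(vectors) -> DistanceMatrix:
    """All pairwise Euclidean distances over a vector collection."""
    ids, X = _as_matrix(vectors)
    if len(ids) < 2:
        raise ValueError("need at least 2 vectors for a distance matrix")
    d = squareform(pdist(X, metric="euclidean"))
    return DistanceMatrix(tuple(ids), d)


def pca_project(vectors, k: int, standardize: bool = False) -> PCAResult:
    """Project onto the top-k principal components.

    Columns are centered (and optionally scaled to unit variance); the
    decomposition is an SVD of the centered data.  Sign convention: the
    largest-magnitude entry of each loading is positive, so output is
    reproducible across runs and libraries.
    """
    ids, X = _as_matrix(vectors)
    m, p = X.shape
    if m < 2:
        raise ValueError("need at least 2 vectors for PCA")
    if not 1 <= k <= p:
        raise ValueError(f"k must be in 1..{p}, got {k}")
    Xc = X - X.mean(axis=0)
    if standardize:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    if not np.any(Xc):
        warnings.warn("zero-variance data: all PCA scores are 0", stacklevel=2)
        return PCAResult(np.zeros((m, k)), np.eye(p)[:, :k], np.zeros(k))
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|entry| of each loading made positive
    for j in range(min(len(s), k)):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    scores = (U[:, :k] * s[:k])
    loadings = Vt[:k].T
    explained = (s[:k] ** 2) / (m - 1)
    return PCAResult(scores, loadings, explained)


def complete_linkage_cluster(matrix: DistanceMatrix) -> Dendrogram:
    """Agglomerative clustering, merging the pair with smallest maximum
    inter-cluster distance at each step.

    Ties are broken by the lexicographically smallest pair of cluster
    representatives (each cluster represented by its smallest member id).
    """
    n = len(matrix.ids)
    if n < 2:
        raise ValueError("need at least 2 leaves to cluster")
    if np.any(np.isnan(matrix.d)):
        raise ValueError("distance matrix contains NaN")
    D = matrix.d.astype(float).copy()
    np.fill_diagonal(D, np.inf)
    active = list(range(n))            # slot -> active flag via membership
    cluster_id = list(range(n))        # slot -> dendrogram cluster id
    rep = [matrix.ids[i] for i in range(n)]  # slot -> smallest member id
    alive = np.ones(n, dtype=bool)
    merges: list[tuple[int, int, float]] = []
    next_id = n
    for _ in range(n - 1):
        sub = np.where(alive)[0]
        Dsub = D[np.ix_(sub, sub)]
        h = float(Dsub.min())
        # all tied minimal pairs, tie-broken lexicographically by reps
        ti, tj = np.where(Dsub == h)
        best = None
        for a, b in zip(ti, tj):
            if a >= b:
                continue
            i, j = int(sub[a]), int(sub[b])
            key = tuple(sorted((rep[i], rep[j])))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        merges.append((cluster_id[i], cluster_id[j], h))
        # complete-linkage update: new cluster distance is the max
        new_row = np.maximum(D[i], D[j])
        D[i, :] = new_row
        D[:, i] = new_row
        D[i, i] = np.inf
        alive[j] = False
        D[j, :] = np.inf
        D[:, j] = np.inf
        rep[i] = min(rep[i], rep[j])
        cluster_id[i] = next_id
        next_id += 1
    return Dendrogram(tuple(matrix.ids), tuple(merges))


def to_newick(tree: Dendrogram) -> str:
    """Serialize the dendrogram as Newick with ultrametric branch lengths.

    Leaves sit at height 0; each branch length is parent height minus
    child height.  Children are ordered lexicographically by their
    smallest member id.
    """
    n = len(tree.leaves)
    height = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    rep = {i: tree.leaves[i] for i in range(n)}
    for k, (a, b, h) in enumerate(tree.merges):
        node = n + k
        children[node] = (a, b)
        height[node] = h
        rep[node] = min(rep[a], rep[b])

    def render(node: int, parent_height: float) -> str:
        length = parent_height - height[node]
        if node < n:
            return f"{tree.leaves[node]}:{length:.10g}"
        a, b = children[node]
        if rep[a] > rep[b]:
            a, b = b, a
        inner = f"({render(a, height[node])},{render(b, height[node])})"
        if parent_height == height[node] and node == n + len(tree.merges) - 1:
            return inner
        return f"{inner}:{length:.10g}"

    root = n + len(tree.merges) - 1
    return render(root, height[root]) + ";"
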