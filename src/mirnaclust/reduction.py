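"""Dimension reduction of GramN matrices: LSA, LLE, and Isomap.

Dimension reduction stands in for feature selection: rather than picking
individual n-gram columns, the full matrix is embedded in d informative
dimensions. Three unsupervised reducers are provided:

* LSA — truncated SVD; rows projected onto the top-d right singular
  vectors (optimal rank-d linear approximation).
* LLE — locally linear embedding; preserves each point's reconstruction
  weights from its k nearest neighbours.
* Isomap — geodesic distances on a k-NN graph followed by classical
  (metric) MDS.

k-NN graphs use city-block distance by default for consistency with the
clustering metric (configurable). Eigenvector signs are canonicalized
(first nonzero loading positive) so repeated runs are bit-identical.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh, svd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial.distance import cdist

from .features import FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReducerSpec:
    """Reducer choice and parameters.

    d defaults to 150, the dimension with the best reported accuracy for
    Gram4 features; 140 is the analogous choice for Gram5. k_neighbors
    defaults to 10 for both LLE and Isomap.
    """

    method: str = "isomap"
    d: int = 150
    k_neighbors: int = 10
    metric: str = "cityblock"
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("isomap", "lle", "lsa", "none"):
            raise ValueError(f"unknown reducer method {self.method!r}")
        if self.method != "none":
            if self.d < 1:
                raise ValueError("d must be >= 1")
            if self.k_neighbors < max(1, self.d // 10):
                warnings.warn(
                    f"k_neighbors={self.k_neighbors} is small relative to "
                    f"d={self.d}; embedding may be unstable",
                    stacklevel=2,
                )


@dataclass
class ReducedMatrix:
    """d-dimensional embedding; rows follow the input FeatureMatrix."""

    values: np.ndarray
    row_ids: list[str]
    spec: ReducerSpec = field(default_factory=ReducerSpec)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.row_ids):
            raise ValueError("row_ids length must match row count")


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Flip column signs so each column's first nonzero entry is positive."""
    out = components.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            out[:, j] = -col
    return out


def reduce_lsa(X: np.ndarray, d: int) -> np.ndarray:
    """Project rows onto the top-d right singular vectors (scaled by σ).

    Equivalent to latent semantic analysis of the n-gram/sequence matrix:
    the returned coordinates are U_d Σ_d, whose pairwise geometry matches
    the optimal rank-d approximation. If rank(X) < d only rank columns
    are returned, with a warning.
    """
    X = np.asarray(X, dtype=float)
    if d < 1:
        raise ValueError("d must be >= 1")
    if d > min(X.shape):
        raise ValueError(f"d={d} exceeds min(n_rows, n_cols)={min(X.shape)}")
    U, s, Vt = svd(X, full_matrices=False)
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    if rank < d:
        warnings.warn(
            f"matrix rank {rank} < requested d={d}; returning {rank} columns",
            stacklevel=2,
        )
        d = rank
    Vt = _fix_signs(Vt[:d].T).T  # canonical sign on the loadings
    return X @ Vt.T


def _knn_indices(D: np.ndarray, k: int) -> np.ndarray:
    """Indices of each point's k nearest neighbours (self excluded)."""
    n = D.shape[0]
    if k >= n:
        raise ValueError(f"k_neighbors={k} must be < n_points={n}")
    order = np.argsort(D, axis=1, kind="stable")
    neigh = np.empty((n, k), dtype=np.int64)
    for i in range(n):
        row = order[i]
        neigh[i] = row[row != i][:k]
    return neigh


def reduce_lle(
    X: np.ndarray, d: int, k_neighbors: int = 10, metric: str = "cityblock"
) -> np.ndarray:
    """Locally linear embedding.

    For each point, reconstruction weights over its k nearest neighbours
    are found by solving the local Gram system (regularized with
    ε = 1e-3·trace/k when near-singular) under the sum-to-one constraint.
    The embedding is the bottom d+1 eigenvectors of (I−W)ᵀ(I−W) with the
    constant eigenvector removed, columns centered and sign-canonicalized.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < k_neighbors + 1:
        raise ValueError("need at least k_neighbors+1 points")
    W = lle_weights(X, k_neighbors, metric)
    I_W = np.eye(n) - W
    M = I_W.T @ I_W
    # bottom d+1 eigenvectors; eigenvalue 0 belongs to the constant vector
    vals, vecs = eigh(M, subset_by_index=(0, min(d, n - 1)))
    del vals
    Y = vecs[:, 1 : d + 1]
    Y = Y - Y.mean(axis=0, keepdims=True)
    return _fix_signs(Y)


def lle_weights(
    X: np.ndarray, k_neighbors: int, metric: str = "cityblock"
) -> np.ndarray:
    """The n×n LLE reconstruction-weight matrix (rows sum to 1)."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    D = cdist(X, X, metric=metric)
    neigh = _knn_indices(D, k_neighbors)
    W = np.zeros((n, n))
    for i in range(n):
        Z = X[neigh[i]] - X[i]  # k × dim, neighbours relative to point i
        G = Z @ Z.T
        trace = np.trace(G)
        eps = 1e-3 * trace / k_neighbors if trace > 0 else 1e-3
        G = G + eps * np.eye(k_neighbors)
        w = np.linalg.solve(G, np.ones(k_neighbors))
        W[i, neigh[i]] = w / w.sum()
    return W


def geodesic_distances(
    X: np.ndarray, k_neighbors: int, metric: str = "cityblock"
) -> np.ndarray:
    """All-pairs shortest-path distances on the symmetrized k-NN graph.

    A disconnected graph is repaired by repeatedly adding the single
    shortest edge joining two components, so every point stays embedded.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    D = cdist(X, X, metric=metric)
    neigh = _knn_indices(D, k_neighbors)
    rows = np.repeat(np.arange(n), k_neighbors)
    cols = neigh.ravel()
    graph = np.zeros((n, n))
    graph[rows, cols] = D[rows, cols]
    graph = np.maximum(graph, graph.T)  # symmetrize (union of edges)

    n_comp, labels = connected_components(csr_matrix(graph), directed=False)
    while n_comp > 1:
        # shortest edge between any two distinct components
        mask = labels[:, None] != labels[None, :]
        masked = np.where(mask, D, np.inf)
        i, j = np.unravel_index(np.argmin(masked), masked.shape)
        graph[i, j] = graph[j, i] = D[i, j]
        logger.warning(
            "neighborhood graph disconnected; bridging components via edge "
            "(%d, %d) of length %.4g", i, j, D[i, j]
        )
        n_comp, labels = connected_components(csr_matrix(graph), directed=False)

    return shortest_path(csr_matrix(graph), method="D", directed=False)


def classical_mds(D: np.ndarray, d: int) -> np.ndarray:
    """Classical (Torgerson) MDS of a distance matrix into d dimensions."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2
    vals, vecs = eigh(B)
    order = np.argsort(vals)[::-1][:d]
    vals, vecs = vals[order], vecs[:, order]
    pos = np.clip(vals, 0.0, None)
    if np.any(vals <= 0):
        logger.debug("MDS: %d of top-%d eigenvalues non-positive", int(np.sum(vals <= 0)), d)
    return _fix_signs(vecs * np.sqrt(pos))


def reduce_isomap(
    X: np.ndarray, d: int, k_neighbors: int = 10, metric: str = "cityblock"
) -> np.ndarray:
    """Isomap: geodesic distances on the k-NN graph, then classical MDS."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < k_neighbors + 1:
        raise ValueError("need at least k_neighbors+1 points")
    G = geodesic_distances(X, k_neighbors, metric)
    return classical_mds(G, d)


def reduce_features(fm: FeatureMatrix, spec: ReducerSpec) -> ReducedMatrix:
    """Apply the configured reducer to a FeatureMatrix.

    ``method="none"`` passes the features through unchanged, reproducing
    the before-feature-selection arm of the pipeline.
    """
    X = fm.values
    if spec.method == "none":
        Y = X.copy()
    elif spec.method == "lsa":
        Y = reduce_lsa(X, spec.d)
    elif spec.method == "lle":
        Y = reduce_lle(X, spec.d, spec.k_neighbors, spec.metric)
    elif spec.method == "isomap":
        Y = reduce_isomap(X, spec.d, spec.k_neighbors, spec.metric)
    else:  # pragma: no cover - guarded by ReducerSpec
        raise ValueError(spec.method)
    return ReducedMatrix(Y, list(fm.row_ids), spec)
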