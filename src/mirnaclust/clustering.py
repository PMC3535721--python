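"""K-means clustering under city-block distance, with a cluster-number sweep.

City-block (L1) distance separates short-sequence n-gram profiles better
than Euclidean distance here, so assignment uses L1 and the centroid
update uses the coordinate-wise median — the L1-optimal centroid. K-means
is sensitive to its random initial centers, so each clustering runs
multiple restarts (default 20) and keeps the one with the lowest final
objective.

The number of clusters K is unknown a priori; given N known families,
the sweep tries 6 values uniformly spaced between N and 2N and keeps the
K with the best vote-strategy accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .evaluation import EvaluationReport, evaluate


@dataclass
class Clustering:
    """Result of one K-means run (best of all restarts)."""

    labels: np.ndarray
    K: int
    objective: float
    n_restarts: int
    seed: int
    converged: bool
    n_iter: int
    objective_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.size and not (0 <= self.labels.min() and self.labels.max() < self.K):
            raise ValueError("labels out of range [0, K)")


def cityblock_objective(X: np.ndarray, labels: np.ndarray, centers: np.ndarray) -> float:
    """Total L1 distance of points to their assigned centroids."""
    return float(np.sum(np.abs(X - centers[labels])))


def _update_centers(
    X: np.ndarray, labels: np.ndarray, centers: np.ndarray, centroid: str
) -> np.ndarray:
    """Recompute centroids; empty clusters re-seed at the worst-fit point."""
    K = centers.shape[0]
    new = centers.copy()
    empty = []
    for c in range(K):
        members = X[labels == c]
        if members.shape[0] == 0:
            empty.append(c)
        elif centroid == "median":
            new[c] = np.median(members, axis=0)
        else:
            new[c] = members.mean(axis=0)
    for c in empty:
        # farthest point from its current centroid claims the empty slot
        dist_to_own = np.abs(X - new[labels]).sum(axis=1)
        far = int(np.argmax(dist_to_own))
        new[c] = X[far]
        labels[far] = c
    return new


def _kmeans_single(
    X: np.ndarray,
    K: int,
    rng: np.random.Generator,
    centroid: str,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, float, bool, int, list[float]]:
    n = X.shape[0]
    centers = X[rng.choice(n, size=K, replace=False)].copy()
    labels = np.full(n, -1, dtype=np.int64)
    prev_obj = np.inf
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        D = cdist(X, centers, metric="cityblock")
        new_labels = np.argmin(D, axis=1)  # ties: lowest cluster index
        obj = float(D[np.arange(n), new_labels].sum())
        history.append(obj)
        unchanged = np.array_equal(new_labels, labels)
        labels = new_labels
        if unchanged or (np.isfinite(prev_obj) and prev_obj > 0
                         and (prev_obj - obj) / prev_obj < tol):
            converged = True
            break
        prev_obj = obj
        centers = _update_centers(X, labels, centers, centroid)
    # objective consistent with final labels/centers
    final_obj = history[-1] if history else 0.0
    return labels, final_obj, converged, it, history


def kmeans_cityblock(
    X: np.ndarray,
    K: int,
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
    centroid: str = "median",
) -> Clustering:
    """K-means with L1 assignment and median (default) centroid update.

    Runs ``n_restarts`` independent seeded initializations (K distinct
    data points each) and returns the restart with the smallest final
    objective. Deterministic given ``seed``.

    Parameters
    ----------
    centroid : {"median", "mean"}
        Median is the L1-optimal update; mean gives strict Lloyd parity.
    """
    X = np.asarray(getattr(X, "values", X), dtype=float)
    n = X.shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds number of points n={n}")
    if centroid not in ("median", "mean"):
        raise ValueError("centroid must be 'median' or 'mean'")
    rng = np.random.default_rng(seed)
    best: tuple | None = None
    for _ in range(n_restarts):
        result = _kmeans_single(X, K, rng, centroid, max_iter, tol)
        if best is None or result[1] < best[1]:
            best = result
    labels, obj, converged, n_iter, history = best
    return Clustering(
        labels=labels,
        K=K,
        objective=obj,
        n_restarts=n_restarts,
        seed=seed,
        converged=converged,
        n_iter=n_iter,
        objective_history=history,
    )


@dataclass(frozen=True)
class SweepPlan:
    """Candidate cluster numbers: 6 values uniformly spaced over [N, 2N]."""

    values: tuple[int, ...]


def plan_sweep(N: int) -> SweepPlan:
    """Cluster-number candidates N + round(i·N/5) for i = 0..5.

    For N = 300 this yields 300, 360, 420, 480, 540, 600. Small N can
    produce duplicate values after rounding; duplicates are removed with
    a warning.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    values = [N + int(np.floor(i * N / 5 + 0.5)) for i in range(6)]
    unique = sorted(set(values))
    if len(unique) < 6:
        warnings.warn(
            f"sweep for N={N} produced duplicate K values {values}; "
            f"deduplicated to {unique}",
            stacklevel=2,
        )
    return SweepPlan(tuple(unique))


def run_sweep(
    X: np.ndarray,
    plan: SweepPlan,
    labels: Sequence[str],
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
    centroid: str = "median",
    min_cluster_size: int = 5,
    vote_fraction: float = 1 / 3,
    ids: Sequence[str] | None = None,
) -> tuple[int, dict[int, tuple[Clustering, EvaluationReport]]]:
    """Cluster at every K in the plan and keep the most accurate.

    Returns the best K (ties broken toward smaller K) and, for every K,
    the clustering and its evaluation report.
    """
    results: dict[int, tuple[Clustering, EvaluationReport]] = {}
    best_K = None
    best_acc = -1.0
    for K in plan.values:
        clustering = kmeans_cityblock(
            X, K, n_restarts=n_restarts, seed=seed + K, max_iter=max_iter,
            tol=tol, centroid=centroid,
        )
        report = evaluate(
            clustering, labels,
            min_cluster_size=min_cluster_size, vote_fraction=vote_fraction,
            ids=ids,
        )
        results[K] = (clustering, report)
        if report.accuracy > best_acc:  # strict: ties keep the smaller K
            best_acc = report.accuracy
            best_K = K
    return best_K, results
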