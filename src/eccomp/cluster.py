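"""Cluster-count selection by subtractive clustering and seeded K-medoids.

Subtractive clustering (mountain method) scores each sequence by a density
proxy over the distance matrix M,

    Mt(S_i) = Σ_j exp(−M_ij),

repeatedly promotes the highest-mountain sequence to the centroid set and
damps every remaining sequence's mountain by the kernel exp(−M_io) of the
newly selected centroid o.  Selection stops once the best remaining
mountain falls below ε·Mt_max (Mt_max = the round-1 maximum) or the
centroid count reaches √n, so K ≤ ⌈√n⌉ always and K ≥ 1 always.

Those centroids seed a K-medoids refinement over the same matrix: assign
every sequence to its nearest centroid, re-pick each cluster's medoid as
the member minimizing the within-cluster distance sum, repeat to a fixed
point.  The cost λ = Σ_clusters Σ_members d(member, medoid) is recorded per
half-step and is non-increasing by construction.

Everything here is deterministic: all ties (argmax, nearest centroid,
medoid update) break to the lowest sequence index.

Note on ε: with the bare-kernel damping above, each selection can remove at
most exp(0) = 1 from any mountain value.  For g balanced clusters of m
members each, after one centroid per cluster has been selected the best
remaining mountain is ≈ (m−1)/m of Mt_max regardless of how well separated
the clusters are, so a useful ε must exceed (m−1)/m.  The default ε = 0.8
targets small families (m ≈ 4); tune ε to the expected cluster size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .distmatrix import DistanceMatrix

__all__ = [
    "SubtractiveResult",
    "Clustering",
    "mountain_values",
    "subtractive_centroids",
    "kmedoids",
    "clustering_cost",
    "SubtractiveKMedoids",
    "DEFAULT_EPSILON",
    "DEFAULT_MAX_ITER",
]

DEFAULT_EPSILON = 0.8
DEFAULT_MAX_ITER = 100


def _as_array(m: DistanceMatrix | np.ndarray) -> np.ndarray:
    return m.d if isinstance(m, DistanceMatrix) else np.asarray(m, dtype=float)


@dataclass
class SubtractiveResult:
    """Centroid seeds chosen by subtractive clustering, in selection order."""

    centroid_indices: list[int]
    epsilon: float
    mt_max: float
    mountain_trace: list[np.ndarray] = field(default_factory=list)

    @property
    def K(self) -> int:
        return len(self.centroid_indices)


@dataclass
class Clustering:
    """A partition of sequence indices with one medoid per cluster.

    ``assignment[i]`` is the cluster id (0..K−1) of sequence i;
    ``centroids[j]`` is the medoid index of cluster j (always a member of
    its own cluster).  ``cost`` is λ; ``cost_trace`` holds λ after every
    assignment and update half-step of the K-medoids loop.
    """

    assignment: np.ndarray
    centroids: np.ndarray
    cost: float
    iterations: int
    converged: bool
    cost_trace: list[float] = field(default_factory=list)

    @property
    def K(self) -> int:
        return int(self.centroids.size)

    @property
    def n(self) -> int:
        return int(self.assignment.size)

    def members(self, j: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == j)

    def validate(self, d: np.ndarray | None = None) -> None:
        counts = np.bincount(self.assignment, minlength=self.K)
        if np.any(counts == 0):
            raise AssertionError("empty cluster")  # cannot arise: medoids self-assign
        for j, c in enumerate(self.centroids):
            if self.assignment[c] != j:
                raise AssertionError(f"medoid {c} not assigned to its own cluster")
        if d is not None and clustering_cost(d, self) != self.cost:
            raise AssertionError("stored cost does not match recomputation")


def mountain_values(m: DistanceMatrix | np.ndarray) -> np.ndarray:
    """Mt(S_i) = Σ_j exp(−M_ij); the self term contributes exp(0) = 1."""
    return np.exp(-_as_array(m)).sum(axis=1)


def subtractive_centroids(
    m: DistanceMatrix | np.ndarray, epsilon: float = DEFAULT_EPSILON
) -> SubtractiveResult:
    """Select centroid seeds and thereby the cluster count K.

    Stops when the best remaining mountain drops below ε·Mt_max or when
    |O| ≥ √n; at least one centroid is always selected and selected indices
    are never revisited.
    """
    if not 0.0 < epsilon < 1.0:
        raise ValueError("epsilon must lie in (0, 1)")
    d = _as_array(m)
    n = d.shape[0]
    mt = mountain_values(d)
    mt_max = float(mt.max())
    result = SubtractiveResult(centroid_indices=[], epsilon=epsilon, mt_max=mt_max)
    remaining = np.ones(n, dtype=bool)
    cap = math.sqrt(n)
    while True:
        if len(result.centroid_indices) >= cap:
            break
        if not remaining.any():
            break
        best = float(mt[remaining].max())
        if result.centroid_indices and best < epsilon * mt_max:
            break
        result.mountain_trace.append(mt.copy())
        cand = np.flatnonzero(remaining & (mt == best))
        o = int(cand[0])  # ties -> lowest index
        result.centroid_indices.append(o)
        remaining[o] = False
        mt = np.where(remaining, mt - np.exp(-d[:, o]), mt)
    return result


def _assign(d: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    # centroids are kept sorted ascending, so argmin's first-hit rule breaks
    # distance ties toward the lowest centroid index
    sub = d[:, centroids]
    assignment = np.argmin(sub, axis=1)
    assignment[centroids] = np.arange(centroids.size)  # a medoid is its own nearest
    return assignment


def _cost(d: np.ndarray, assignment: np.ndarray, centroids: np.ndarray) -> float:
    # summed cluster by cluster so clustering_cost() reproduces it bit-for-bit
    total = 0.0
    for j in range(centroids.size):
        total += float(d[np.flatnonzero(assignment == j), centroids[j]].sum())
    return total


def kmedoids(
    m: DistanceMatrix | np.ndarray,
    seeds: SubtractiveResult | list[int],
    max_iter: int = DEFAULT_MAX_ITER,
) -> Clustering:
    """K-medoids over a precomputed distance matrix from given seed medoids."""
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    d = _as_array(m)
    seed_idx = seeds.centroid_indices if isinstance(seeds, SubtractiveResult) else seeds
    centroids = np.array(sorted(seed_idx), dtype=int)
    if centroids.size == 0:
        raise ValueError("no seed centroids")
    if np.unique(centroids).size != centroids.size:
        raise ValueError("duplicate seed centroids")

    assignment = _assign(d, centroids)
    trace = [_cost(d, assignment, centroids)]
    converged = False
    iterations = 0
    for _ in range(max_iter):
        iterations += 1
        new_centroids = centroids.copy()
        for j in range(centroids.size):
            members = np.flatnonzero(assignment == j)
            sums = d[np.ix_(members, members)].sum(axis=1)
            new_centroids[j] = int(members[np.argmin(sums)])  # ties -> lowest index
        trace.append(_cost(d, assignment, new_centroids))  # before re-sorting ids
        new_centroids = np.sort(new_centroids)
        new_assignment = _assign(d, new_centroids)
        trace.append(_cost(d, new_assignment, new_centroids))
        if np.array_equal(new_centroids, centroids) and np.array_equal(
            new_assignment, assignment
        ):
            converged = True
            centroids, assignment = new_centroids, new_assignment
            break
        centroids, assignment = new_centroids, new_assignment
    result = Clustering(
        assignment=assignment,
        centroids=centroids,
        cost=trace[-1],
        iterations=iterations,
        converged=converged,
        cost_trace=trace,
    )
    result.validate(d)
    return result


def clustering_cost(m: DistanceMatrix | np.ndarray, c: Clustering) -> float:
    """Recompute λ = Σ_clusters Σ_members d(member, medoid) from scratch."""
    d = _as_array(m)
    total = 0.0
    for j in range(c.K):
        total += float(d[c.members(j), c.centroids[j]].sum())
    return total


class SubtractiveKMedoids(ClusterMixin, BaseEstimator):
    """Clustering estimator over a precomputed distance matrix.

    Determines the cluster count by subtractive clustering and refines the
    partition by K-medoids, exactly as the functional API does.  ``X`` for
    :meth:`fit` is the n×n symmetric distance matrix itself (as with
    ``metric='precomputed'`` estimators).

    Parameters
    ----------
    epsilon : float, default 0.8
        Subtractive stopping threshold in (0, 1); see the module note on
        choosing it relative to the expected cluster size.
    max_iter : int, default 100
        Maximum K-medoids refinement rounds.

    Attributes
    ----------
    labels_ : ndarray of shape (n,)
        Cluster id of every sequence.
    medoid_indices_ : ndarray of shape (n_clusters_,)
        Sequence index of each cluster's medoid.
    n_clusters_ : int
        The selected K.
    inertia_ : float
        Final cost λ.
    n_iter_ : int
        K-medoids rounds executed.
    """

    def __init__(self, epsilon: float = DEFAULT_EPSILON, max_iter: int = DEFAULT_MAX_ITER):
        self.epsilon = epsilon
        self.max_iter = max_iter

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] != X.shape[1]:
            raise ValueError("X must be a square precomputed distance matrix")
        if not np.allclose(X, X.T) or np.any(np.diag(X) != 0):
            raise ValueError("X must be symmetric with a zero diagonal")
        seeds = subtractive_centroids(X, epsilon=self.epsilon)
        clustering = kmedoids(X, seeds, max_iter=self.max_iter)
        self.seeds_ = seeds
        self.clustering_ = clustering
        self.labels_ = clustering.assignment
        self.medoid_indices_ = clustering.centroids
        self.n_clusters_ = clustering.K
        self.inertia_ = clustering.cost
        self.n_iter_ = clustering.iterations
        self.n_features_in_ = X.shape[1]
        return self
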