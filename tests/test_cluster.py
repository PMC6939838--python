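"""Subtractive seeding and K-medoids: hand traces, oracles, invariants."""

import itertools
import math

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.metrics import adjusted_rand_score

from conftest import random_distance_matrix
from eccomp.cluster import (
    SubtractiveKMedoids,
    clustering_cost,
    kmedoids,
    mountain_values,
    subtractive_centroids,
)


def subtractive_trace_oracle(d: np.ndarray, epsilon: float) -> list[int]:
    """Independent step-by-step re-statement of the selection procedure."""
    n = d.shape[0]
    mt = [sum(math.exp(-d[i, j]) for j in range(n)) for i in range(n)]
    mt_max = max(mt)
    selected: list[int] = []
    while True:
        if len(selected) >= math.sqrt(n):
            break
        candidates = [i for i in range(n) if i not in selected]
        if not candidates:
            break
        best = max(mt[i] for i in candidates)
        if selected and best < epsilon * mt_max:
            break
        o = min(i for i in candidates if mt[i] == best)
        selected.append(o)
        for i in candidates:
            if i != o:
                mt[i] -= math.exp(-d[i, o])
    return selected


def exhaustive_two_medoid_optimum(d: np.ndarray) -> float:
    """Minimum cost over every (medoid pair, nearest-assignment) configuration."""
    n = d.shape[0]
    best = math.inf
    for a, b in itertools.combinations(range(n), 2):
        cost = sum(min(d[i, a], d[i, b]) for i in range(n))
        best = min(best, cost)
    return best


# -- mountain values ------------------------------------------------------

def test_mountain_values_hand_cases():
    assert mountain_values(np.zeros((3, 3))).tolist() == [3.0, 3.0, 3.0]

    d2 = np.array([[0.0, 0.4], [0.4, 0.0]])
    assert mountain_values(d2) == pytest.approx([1 + math.exp(-0.4)] * 2)

    d3 = np.array([[0, 0.1, 0.2], [0.1, 0, 0.3], [0.2, 0.3, 0]])
    expected = [
        1 + math.exp(-0.1) + math.exp(-0.2),
        1 + math.exp(-0.1) + math.exp(-0.3),
        1 + math.exp(-0.2) + math.exp(-0.3),
    ]
    assert mountain_values(d3) == pytest.approx(expected)
    assert mountain_values(d3) == pytest.approx([2.7236, 2.6457, 2.5596], abs=1e-4)


# -- subtractive seeding --------------------------------------------------

def test_subtractive_single_point():
    r = subtractive_centroids(np.zeros((1, 1)), epsilon=0.5)
    assert r.centroid_indices == [0] and r.K == 1


def test_subtractive_zero_matrix_hand_trace():
    """n=4 all-identical points at eps=0.5: Mt=[4,4,4,4], select 0, Mt drops
    to 3 everywhere, 3 >= 0.5*4 selects 1, then |O| = 2 >= sqrt(4) stops."""
    r = subtractive_centroids(np.zeros((4, 4)), epsilon=0.5)
    assert r.centroid_indices == [0, 1]
    assert r.K == 2
    assert r.mt_max == 4.0
    assert r.mountain_trace[0].tolist() == [4.0, 4.0, 4.0, 4.0]
    assert r.mountain_trace[1].tolist() == pytest.approx([4.0, 3.0, 3.0, 3.0])


@pytest.mark.parametrize("epsilon", [0.3, 0.5, 0.8, 0.9])
def test_subtractive_equals_trace_oracle(two_block_matrix, epsilon):
    r = subtractive_centroids(two_block_matrix, epsilon=epsilon)
    assert r.centroid_indices == subtractive_trace_oracle(two_block_matrix, epsilon)
    assert 1 <= r.K <= math.ceil(math.sqrt(10))


def test_subtractive_two_blocks_one_seed_per_block(two_block_matrix):
    r = subtractive_centroids(two_block_matrix, epsilon=0.9)
    assert r.K == 2
    assert sorted(c < 5 for c in r.centroid_indices) == [False, True]


def test_subtractive_oracle_on_random_matrices():
    rng = np.random.default_rng(3)
    for _ in range(10):
        d = random_distance_matrix(rng, 12)
        r = subtractive_centroids(d, epsilon=0.7)
        assert r.centroid_indices == subtractive_trace_oracle(d, 0.7)


def test_subtractive_epsilon_range_enforced():
    with pytest.raises(ValueError):
        subtractive_centroids(np.zeros((2, 2)), epsilon=1.0)


# -- K-medoids ------------------------------------------------------------

def test_kmedoids_single_cluster_closed_form():
    rng = np.random.default_rng(8)
    d = random_distance_matrix(rng, 7)
    c = kmedoids(d, [0])
    medoid = int(np.argmin(d.sum(axis=1)))
    assert c.K == 1
    assert c.centroids.tolist() == [medoid]
    assert c.cost == pytest.approx(d[medoid].sum())


def test_kmedoids_fixed_point_returned_unchanged(two_block_matrix):
    c = kmedoids(two_block_matrix, [0, 5])
    assert c.converged
    assert c.iterations == 1  # one verification pass
    assert c.centroids.tolist() == [0, 5]
    assert c.assignment.tolist() == [0] * 5 + [1] * 5


def test_kmedoids_matches_exhaustive_optimum(two_block_matrix):
    seeds = subtractive_centroids(two_block_matrix, epsilon=0.9)
    c = kmedoids(two_block_matrix, seeds)
    assert c.assignment.tolist() == [0] * 5 + [1] * 5
    assert c.cost == pytest.approx(exhaustive_two_medoid_optimum(two_block_matrix))


def test_kmedoids_cost_nonincreasing_and_selfconsistent():
    rng = np.random.default_rng(21)
    for _ in range(20):
        d = random_distance_matrix(rng, 15)
        seeds = subtractive_centroids(d, epsilon=0.6)
        c = kmedoids(d, seeds)
        assert all(a >= b - 1e-12 for a, b in zip(c.cost_trace, c.cost_trace[1:]))
        assert clustering_cost(d, c) == c.cost  # exact, same summation order
        c.validate(d)  # partition covers all points, medoids self-assigned


def test_kmedoids_deterministic():
    rng = np.random.default_rng(2)
    d = random_distance_matrix(rng, 20)
    seeds = subtractive_centroids(d, epsilon=0.6)
    a = kmedoids(d, seeds)
    b = kmedoids(d, seeds)
    assert a.assignment.tolist() == b.assignment.tolist()
    assert a.centroids.tolist() == b.centroids.tolist()
    assert a.cost == b.cost


def test_kmedoids_max_iter_validation(two_block_matrix):
    with pytest.raises(ValueError):
        kmedoids(two_block_matrix, [0, 5], max_iter=0)


# -- estimator facade -----------------------------------------------------

def test_estimator_api(two_block_matrix):
    est = SubtractiveKMedoids(epsilon=0.9)
    labels = est.fit_predict(two_block_matrix)
    assert est.n_clusters_ == 2
    assert adjusted_rand_score(labels, [0] * 5 + [1] * 5) == 1.0
    assert est.medoid_indices_.tolist() == est.clustering_.centroids.tolist()
    assert est.inertia_ == est.clustering_.cost

    cloned = clone(est)
    assert cloned.get_params() == {"epsilon": 0.9, "max_iter": 100}
    cloned.set_params(max_iter=5).fit(two_block_matrix)
    assert cloned.labels_.tolist() == labels.tolist()


def test_estimator_rejects_nonsymmetric():
    with pytest.raises(ValueError):
        SubtractiveKMedoids().fit(np.array([[0.0, 0.5], [0.4, 0.0]]))
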