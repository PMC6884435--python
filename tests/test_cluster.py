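"""k-means variant: integer comparison identity, ties, empty clusters."""

from fractions import Fraction

import numpy as np
import pytest

from conftest import exact_sq_distance
from wardflow.cluster import (
    KMeansConfig,
    RationalCentroid,
    assign,
    closer_or_equal,
    init_centroids,
    kmeans,
    sample_centroid_indices,
    score,
    update_centroids,
)
from wardflow.errors import ConfigurationError, InvariantViolationError

FOUR_POINTS = [(0, 0), (0, 2), (10, 10), (10, 12)]


def test_score_worked_example():
    # y=(1,2), c=(2,2)/1: s = (4-4) + (4-8) = -4 and sum(y^2) + s = d^2 = 1.
    c = RationalCentroid((2, 2), 1)
    assert score((1, 2), c) == -4
    assert 1 + 4 + score((1, 2), c) == 1


def test_score_zero_centroid():
    assert score((5, 7), RationalCentroid((0, 0), 3)) == 0


def test_score_dimension_mismatch():
    with pytest.raises(ConfigurationError):
        score((1, 2, 3), RationalCentroid((1, 2), 1))


def test_score_reconstructs_exact_distance():
    rng = np.random.default_rng(0)
    for _ in range(2000):
        m = int(rng.integers(1, 5))
        y = tuple(int(v) for v in rng.integers(0, 50, m))
        c = RationalCentroid(tuple(int(v) for v in rng.integers(-30, 50, m)),
                             int(rng.integers(1, 9)))
        d2 = Fraction(sum(v * v for v in y)) + Fraction(score(y, c), c.denominator ** 2)
        assert d2 == exact_sq_distance(y, c)


def test_closer_or_equal_worked_example():
    # d^2 = 1 vs 4.5: the comparison runs on scaled integer scores only.
    y = (1, 2)
    c = RationalCentroid((2, 2), 1)
    c2 = RationalCentroid((5, 1), 2)
    assert closer_or_equal(y, c, c2) == 1
    assert closer_or_equal(y, c2, c) == 0


def test_closer_or_equal_ties_and_totality():
    c = RationalCentroid((3, 4), 2)
    assert closer_or_equal((1, 1), c, c) == 1
    rng = np.random.default_rng(1)
    for _ in range(500):
        y = tuple(int(v) for v in rng.integers(0, 20, 3))
        a = RationalCentroid(tuple(int(v) for v in rng.integers(-20, 20, 3)),
                             int(rng.integers(1, 6)))
        b = RationalCentroid(tuple(int(v) for v in rng.integers(-20, 20, 3)),
                             int(rng.integers(1, 6)))
        assert closer_or_equal(y, a, b) or closer_or_equal(y, b, a)


def test_closer_or_equal_matches_exact_rational_distance():
    rng = np.random.default_rng(2)
    for _ in range(5000):
        y = tuple(int(v) for v in rng.integers(0, 30, 2))
        a = RationalCentroid(tuple(int(v) for v in rng.integers(-30, 30, 2)),
                             int(rng.integers(1, 8)))
        b = RationalCentroid(tuple(int(v) for v in rng.integers(-30, 30, 2)),
                             int(rng.integers(1, 8)))
        expected = int(exact_sq_distance(y, a) <= exact_sq_distance(y, b))
        assert closer_or_equal(y, a, b) == expected


def test_init_centroids_seeded_and_distinct():
    points = [(i, i) for i in range(10)]
    cents, idx = init_centroids(points, 4, seed=9)
    cents2, idx2 = init_centroids(points, 4, seed=9)
    assert idx == idx2 and len(set(idx)) == 4
    assert all(c.numerators == points[i] and c.denominator == 1
               for c, i in zip(cents, idx))
    with pytest.raises(ConfigurationError):
        init_centroids(points, 11, seed=0)


def test_init_k_equals_n_is_permutation():
    points = [(0,), (1,), (2,)]
    _, idx = init_centroids(points, 3, seed=4)
    assert sorted(idx) == [0, 1, 2]


def test_assign_identity_when_centroids_are_points():
    cents = [RationalCentroid((0, 0), 1), RationalCentroid((10, 10), 1)]
    members = assign([(0, 0), (10, 10)], cents)
    assert np.array_equal(members, np.eye(2, dtype=np.int64))


def test_equidistant_point_goes_to_lowest_index():
    cents = [RationalCentroid((0, 0), 1), RationalCentroid((4, 0), 1)]
    members = assign([(2, 0)], cents)
    assert members.tolist() == [[1, 0]]


def test_assign_matches_nearest_centroid_oracle():
    rng = np.random.default_rng(3)
    for _ in range(50):
        n, k = int(rng.integers(2, 8)), int(rng.integers(1, 4))
        points = [tuple(int(v) for v in rng.integers(0, 15, 2)) for _ in range(n)]
        cents = [RationalCentroid(tuple(int(v) for v in rng.integers(0, 30, 2)),
                                  int(rng.integers(1, 5))) for _ in range(k)]
        members = assign(points, cents)
        assert (members.sum(axis=1) == 1).all()
        for i, y in enumerate(points):
            dists = [exact_sq_distance(y, c) for c in cents]
            best = min(range(k), key=lambda j: (dists[j], j))
            assert members[i].argmax() == best


def test_update_is_mean_of_cluster_plus_old_centroid():
    # Cluster {(0,0),(2,2)} with old centroid (1,3): mean of the three.
    members = np.array([[1], [1]])
    old = [RationalCentroid((1, 3), 1)]
    (new,) = update_centroids([(0, 0), (2, 2)], members, old)
    assert new.numerators == (3, 5) and new.denominator == 3
    assert Fraction(new.numerators[0], new.denominator) == 1
    assert Fraction(new.numerators[1], new.denominator) == Fraction(5, 3)


def test_empty_cluster_keeps_centroid_exactly():
    members = np.array([[1, 0], [1, 0]])
    old = [RationalCentroid((0, 0), 1), RationalCentroid((7, 9), 4)]
    new = update_centroids([(0, 0), (2, 2)], members, old)
    assert new[1] == old[1]


def test_singleton_cluster_at_its_centroid_is_fixed():
    members = np.array([[1]])
    old = [RationalCentroid((5, 6), 1)]
    (new,) = update_centroids([(5, 6)], members, old)
    assert Fraction(new.numerators[0], new.denominator) == 5
    assert Fraction(new.numerators[1], new.denominator) == 6


def test_update_rejects_bad_row_sums():
    with pytest.raises(InvariantViolationError):
        update_centroids([(0, 0)], np.array([[1, 1]]),
                         [RationalCentroid((0, 0), 1)] * 2)


def _seed_for_indices(n, k, want):
    for seed in range(2000):
        if sample_centroid_indices(n, k, seed) == want:
            return seed
    pytest.fail(f"no seed under 2000 yields indices {want}")


def test_kmeans_four_point_instance():
    seed = _seed_for_indices(4, 2, (0, 2))
    result = kmeans(FOUR_POINTS, KMeansConfig(k=2, iterations=2, seed=seed))
    assert result.membership.tolist() == [[1, 0], [1, 0], [0, 1], [0, 1]]
    assert result.converged == 1
    assert result.initial_indices == (0, 2)


def test_kmeans_single_cluster_converges():
    result = kmeans(FOUR_POINTS, KMeansConfig(k=1, iterations=2, seed=0))
    assert result.membership.tolist() == [[1]] * 4
    assert result.converged == 1


def test_kmeans_identical_points_all_in_first_cluster():
    points = [(3, 3)] * 4
    result = kmeans(points, KMeansConfig(k=2, iterations=2, seed=0))
    assert result.membership[:, 0].tolist() == [1, 1, 1, 1]


def test_kmeans_single_iteration_cannot_attest_convergence():
    result = kmeans(FOUR_POINTS, KMeansConfig(k=1, iterations=1, seed=0))
    assert result.converged == 0


def test_kmeans_deterministic():
    cfg = KMeansConfig(k=2, iterations=3, seed=5)
    r1 = kmeans(FOUR_POINTS, cfg)
    r2 = kmeans(FOUR_POINTS, cfg)
    assert np.array_equal(r1.membership, r2.membership)
    assert r1.converged == r2.converged


def test_kmeans_rejects_k_above_n():
    with pytest.raises(ConfigurationError):
        kmeans(FOUR_POINTS, KMeansConfig(k=5, iterations=1, seed=0))


def _wcss(points, members, mode_centroids):
    total = Fraction(0)
    for j, c in enumerate(mode_centroids):
        for i, y in enumerate(points):
            if members[i, j]:
                total += exact_sq_distance(y, c)
    return total


def test_strict_lloyd_wcss_non_increasing():
    from wardflow.cluster import _update_strict, init_centroids

    rng = np.random.default_rng(12)
    for _ in range(25):
        n = int(rng.integers(4, 10))
        points = [tuple(int(v) for v in rng.integers(0, 20, 3)) for _ in range(n)]
        k = int(rng.integers(2, 4))
        cents, _ = init_centroids(points, k, seed=int(rng.integers(0, 100)))
        prev = None
        for _ in range(4):
            members = assign(points, cents)
            new_cents = _update_strict(points, members, cents)
            wcss = _wcss(points, members, new_cents)
            if prev is not None:
                assert wcss <= prev
            prev = wcss
            cents = new_cents
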