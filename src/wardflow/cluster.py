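"""k-means clustering of integer data points with rational centroids.

This is the plaintext reference of phase 2, written so that every step has
an exact secure counterpart:

* centroids are rationals x/w with an integer numerator vector and one
  positive integer denominator, so distance comparisons reduce to the
  integer identity  d2(y,c) <= d2(y,c~)  <=>  w~^2 s(y,c) <= w^2 s(y,c~)
  with the score  s(y,c) = sum_l (x_l^2 - 2 w x_l y_l);
* the centroid update is division-free: the new centroid is the mean of
  the cluster's points *plus its own old centroid*, which keeps empty
  clusters well-defined (their centroid is simply unchanged);
* ties in distance assign the point to the lowest-indexed cluster;
* the iteration count is fixed; convergence is checked once at the end by
  comparing the last two membership matrices.

Only the membership matrix and the convergence flag are returned - never
the centroids, which in the secure setting would leak aggregate data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InvariantViolationError

__all__ = [
    "RationalCentroid",
    "KMeansConfig",
    "KMeansResult",
    "sample_centroid_indices",
    "init_centroids",
    "score",
    "closer_or_equal",
    "assign",
    "update_centroids",
    "kmeans",
]

Point = tuple[int, ...]


@dataclass(frozen=True)
class RationalCentroid:
    """Centroid x/w with integer numerators and positive denominator."""

    numerators: Point
    denominator: int = 1

    def __post_init__(self) -> None:
        if self.denominator < 1:
            raise ConfigurationError("centroid denominator must be >= 1")

    def reduced(self) -> "RationalCentroid":
        g = math.gcd(self.denominator, *[abs(x) for x in self.numerators])
        if g <= 1:
            return self
        return RationalCentroid(tuple(x // g for x in self.numerators),
                                self.denominator // g)


@dataclass(frozen=True)
class KMeansConfig:
    k: int
    iterations: int = 5
    seed: int = 0
    mode: str = "division_free"  # division_free | strict_lloyd

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigurationError("k must be >= 1")
        if self.iterations < 1:
            raise ConfigurationError("iterations must be >= 1")
        if self.mode not in ("division_free", "strict_lloyd"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")


@dataclass
class KMeansResult:
    membership: np.ndarray  # Nn x k binary
    converged: int
    initial_indices: tuple[int, ...]


def sample_centroid_indices(n_points: int, k: int, seed: int) -> tuple[int, ...]:
    """k distinct point indices, uniform without replacement, seed-determined.

    The draw is public: in the two-party setting the hospital chooses it.
    Shared by the plaintext and secure paths so both start identically.
    """
    if k > n_points:
        raise ConfigurationError(f"k={k} exceeds the number of points {n_points}")
    rng = np.random.default_rng(seed)
    return tuple(int(i) for i in rng.choice(n_points, size=k, replace=False))


def init_centroids(points: list[Point], k: int, seed: int
                   ) -> tuple[list[RationalCentroid], tuple[int, ...]]:
    """Initial centroids sampled among the data points (denominator 1)."""
    indices = sample_centroid_indices(len(points), k, seed)
    return [RationalCentroid(points[i], 1) for i in indices], indices


def score(y: Point, c: RationalCentroid) -> int:
    """Integer score s(y,c) = sum(x^2 - 2 w x y); d2 = sum(y^2) + s / w^2."""
    if len(y) != len(c.numerators):
        raise ConfigurationError("dimension mismatch between point and centroid")
    w = c.denominator
    return sum(x * x - 2 * w * x * yi for x, yi in zip(c.numerators, y))


def closer_or_equal(y: Point, c: RationalCentroid, c2: RationalCentroid) -> int:
    """1 iff d2(y, c) <= d2(y, c2), in exact integer arithmetic."""
    lhs = c2.denominator ** 2 * score(y, c)
    rhs = c.denominator ** 2 * score(y, c2)
    return int(lhs <= rhs)


def assign(points: list[Point], centroids: list[RationalCentroid]) -> np.ndarray:
    """Membership matrix: product-of-comparisons form with lowest-index ties.

    Raw M_ij = prod_j' xi(i,j,j') marks every minimising centroid; the
    uniqueness pass M_ij <- M_ij * prod_{j'<j} (1 - M_ij') then keeps only
    the lowest-indexed one, so each row sums to exactly 1.
    """
    k = len(centroids)
    members = np.zeros((len(points), k), dtype=np.int64)
    for i, y in enumerate(points):
        scores = [score(y, c) for c in centroids]
        w2 = [c.denominator ** 2 for c in centroids]
        raw = []
        for j in range(k):
            bit = 1
            for j2 in range(k):
                if j2 == j:
                    continue
                bit *= int(w2[j2] * scores[j] <= w2[j] * scores[j2])
            raw.append(bit)
        none_before = 1
        for j in range(k):
            members[i, j] = raw[j] * none_before
            none_before *= 1 - members[i, j]
    return members


def update_centroids(points: list[Point], members: np.ndarray,
                     old: list[RationalCentroid]) -> list[RationalCentroid]:
    """Division-free update: new centroid = mean of cluster + old centroid.

    With n_j = sum_i M_ij:  x' = w * sum_i M_ij y(i) + x,  w' = w (n_j + 1).
    An empty cluster (n_j = 0) keeps its centroid exactly.  Fractions are
    reduced by their gcd, which the secure path cannot do; the value x'/w'
    is identical either way.
    """
    if not np.array_equal(members.sum(axis=1), np.ones(len(points), dtype=np.int64)):
        raise InvariantViolationError("membership row sums must all be 1")
    m = len(points[0])
    new = []
    for j, c in enumerate(old):
        n_j = int(members[:, j].sum())
        sums = [0] * m
        for i, y in enumerate(points):
            if members[i, j]:
                for l in range(m):
                    sums[l] += y[l]
        w = c.denominator
        numer = tuple(w * sums[l] + c.numerators[l] for l in range(m))
        new.append(RationalCentroid(numer, w * (n_j + 1)).reduced())
    return new


def _update_strict(points: list[Point], members: np.ndarray,
                   old: list[RationalCentroid]) -> list[RationalCentroid]:
    """Textbook Lloyd update: plain cluster means, empty clusters frozen."""
    m = len(points[0])
    new = []
    for j, c in enumerate(old):
        n_j = int(members[:, j].sum())
        if n_j == 0:
            new.append(c)
            continue
        sums = [0] * m
        for i, y in enumerate(points):
            if members[i, j]:
                for l in range(m):
                    sums[l] += y[l]
        new.append(RationalCentroid(tuple(sums), n_j).reduced())
    return new


def kmeans(points: list[Point], config: KMeansConfig,
           initial_indices: tuple[int, ...] | None = None) -> KMeansResult:
    """Fixed-iteration k-means; returns membership and convergence only.

    ``converged`` is 1 iff the last two assignment matrices are identical
    (necessarily 0 when only one iteration was run, since there is nothing
    to compare against).
    """
    if config.k > len(points):
        raise ConfigurationError(f"k={config.k} exceeds Nn={len(points)}")
    if initial_indices is None:
        centroids, indices = init_centroids(points, config.k, config.seed)
    else:
        indices = tuple(initial_indices)
        centroids = [RationalCentroid(points[i], 1) for i in indices]

    update = update_centroids if config.mode == "division_free" else _update_strict
    prev = None
    members = None
    for _ in range(config.iterations):
        prev = members
        members = assign(points, centroids)
        centroids = update(points, members, centroids)
    converged = int(prev is not None and np.array_equal(members, prev))
    return KMeansResult(membership=members, converged=converged,
                        initial_indices=indices)
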