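"""Rank transformation and nearest-neighbour geometry on the discrete torus.

Paired observations (x_k, y_k) are rank-transformed (ties broken at random)
into two paired permutations of {0..n-1}.  The n points z_k = (x_k, y_k) then
live on an n x n torus with the Chebyshev (maximum-coordinate) metric, where
each horizontal and each vertical grid line carries exactly one point.  Under
independence the configuration is a uniformly random permutation matrix, which
is what makes the nearest-neighbour distance law exactly computable
(:mod:`nnindep.exact_distribution`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PermutationPair",
    "NNProfile",
    "rank_to_permutation",
    "torus_chebyshev_distance",
    "max_distance",
    "nn_distance_profile",
]


def rank_to_permutation(values, tie_seed: int = 0) -> np.ndarray:
    """Return 0-based ranks of ``values`` with ties broken uniformly at random.

    The exact distance distribution requires genuine permutations, so tied
    observations must be separated; ``tie_seed`` makes the tie-break
    reproducible.  Raises ``ValueError`` naming the first offending index if
    any value is not finite.

    >>> rank_to_permutation([2.5, 1.1, 3.3]).tolist()
    [1, 0, 2]
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("values must be one-dimensional")
    n = arr.size
    if n < 2:
        raise ValueError("need at least two values to rank")
    bad = np.flatnonzero(~np.isfinite(arr))
    if bad.size:
        raise ValueError(
            f"non-finite value at index {bad[0]} (value={arr[bad[0]]!r})"
        )
    rng = np.random.default_rng(tie_seed)
    # random jitter key only breaks ties; stable sort keeps order otherwise
    order = np.lexsort((rng.random(n), arr))
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    return ranks


def torus_chebyshev_distance(p, q, n: int) -> int:
    """Chebyshev distance between lattice points ``p`` and ``q`` on the n-torus.

    d(p, q) = max(delta(p0,q0), delta(p1,q1)) with
    delta(u, v) = min(|u-v|, n-|u-v|).
    """
    (a, b), (c, e) = p, q
    for coord in (a, b, c, e):
        if not 0 <= coord < n:
            raise ValueError(f"coordinate {coord} out of range for n={n}")
    da = abs(a - c)
    db = abs(b - e)
    return max(min(da, n - da), min(db, n - db))


def max_distance(n: int) -> int:
    """Largest attainable torus Chebyshev distance: floor(n/2)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return n // 2


@dataclass(frozen=True)
class PermutationPair:
    """A rank-transformed bivariate sample: two paired permutations of {0..n-1}."""

    n: int
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.x, dtype=np.int64)
        y = np.asarray(self.y, dtype=np.int64)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.shape != (self.n,) or y.shape != (self.n,):
            raise ValueError("x and y must both have length n")
        full = np.arange(self.n)
        if not (np.array_equal(np.sort(x), full) and np.array_equal(np.sort(y), full)):
            raise ValueError("x and y must each be a permutation of 0..n-1")

    @classmethod
    def from_data(cls, x, y, tie_seed: int = 0) -> "PermutationPair":
        """Rank-transform raw paired observations into a PermutationPair."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("x and y must have equal length")
        return cls(
            n=x.size,
            x=rank_to_permutation(x, tie_seed=tie_seed),
            y=rank_to_permutation(y, tie_seed=tie_seed + 1),
        )

    @classmethod
    def random(cls, n: int, seed=None) -> "PermutationPair":
        """A sample from the null model: both permutations uniform, independent."""
        rng = np.random.default_rng(seed)
        return cls(n=n, x=rng.permutation(n), y=rng.permutation(n))

    def distance_matrix(self) -> np.ndarray:
        """All pairwise torus Chebyshev distances (n x n, zero diagonal)."""
        dx = np.abs(self.x[:, None] - self.x[None, :])
        dy = np.abs(self.y[:, None] - self.y[None, :])
        np.minimum(dx, self.n - dx, out=dx)
        np.minimum(dy, self.n - dy, out=dy)
        return np.maximum(dx, dy)


@dataclass(frozen=True)
class NNProfile:
    """Per point, the nondecreasing sequence of its 1st..i_max-th NN distances.

    ``d[k, i-1]`` is the distance of the ith nearest neighbour of point k.
    Rows satisfy 1 <= d[k,0] <= ... <= d[k,i_max-1] <= floor(n/2), and no
    distance occurs more than four times in a row (at most four points can sit
    exactly at any given distance).
    """

    n: int
    i_max: int
    d: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.d, dtype=np.int64)
        object.__setattr__(self, "d", d)
        if d.shape != (self.n, self.i_max):
            raise ValueError("profile must have shape (n, i_max)")


def nn_distance_profile(sample: PermutationPair, i_max: int) -> NNProfile:
    """Sorted torus-Chebyshev distances from each point to its i_max nearest
    neighbours."""
    n = sample.n
    if not 1 <= i_max <= n - 1:
        raise ValueError(f"i_max must be in [1, {n - 1}], got {i_max}")
    dm = sample.distance_matrix()
    dm = np.sort(dm, axis=1)
    return NNProfile(n=n, i_max=i_max, d=dm[:, 1 : i_max + 1])
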