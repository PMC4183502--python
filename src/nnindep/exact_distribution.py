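"""Exact law of the ith nearest-neighbour torus distances of a random
permutation matrix.

Model: n points, one per row and one per column of an n x n torus, drawn
uniformly from all (n-1)! configurations once a reference point is fixed at
the origin (the metric is translation invariant, so this is without loss).
Let D_1 <= D_2 <= ... <= D_{n-1} be the sorted Chebyshev distances from the
reference point to the others.  This module computes, exactly:

* joint probabilities P(D_1=d_1, ..., D_i=d_i)  (``prob_joint``),
* the CDFs F_i(d) = P(D_i <= d) by direct configuration counting
  (``prob_survival``),
* marginals and conditionals, and the entropy of each marginal.

Counting strategy.  Fix the target distance d and write m = n-1,
a(d) = min(2d, m) for the number of rows (equivalently columns) within
distance d of the origin.  A distance prefix with s points strictly inside
distance d and e points exactly at distance d decomposes the torus into
regions: the inner square (side a(d-1)), the border region R of cells exactly
at distance d, the side strips (new rows/columns crossed with the inner
square), and the outside.  Placements factorize:

    count(prefix) = [prod over inner rings v < d of N_R(mult_v, s_v, v)]
                    * sum_{e >= c} N_R(e, s, d) * (m - a(d))!^2 / (m - 2 a(d) + s + e)!

where N_R(e, s, d) counts admissible placements of e points exactly at
distance d given s points strictly inside (``region_r_combinations``), and c
is the multiplicity of d at the end of the prefix.  The border region holds
at most 4 points (2 border rows and 2 border columns; a single row and column
when d = n/2 with n even, where R degenerates to a pair of lines and the same
sum applies with one border line per axis).  All heavy factorial arithmetic
is done with log-gamma; an exact big-integer path (``count_admissible``) is
the slow verification route, and ``brute_force_distribution`` enumerates all
(n-1)! configurations outright for small n as the independent oracle.

Entropy uses the natural logarithm throughout.
"""

from __future__ import annotations

import itertools
import json
import math
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.special import gammaln, logsumexp

from .core_geometry import max_distance

__all__ = [
    "RegionDecomposition",
    "ExactDistribution",
    "region_r_combinations",
    "count_admissible",
    "prob_joint",
    "prob_survival",
    "prob_conditional",
    "conditional_distribution",
    "prob_marginal",
    "marginal_distribution",
    "marginal_entropies",
    "MarginalTails",
    "get_marginal_tails",
    "entropy",
    "default_i_max",
    "brute_force_distribution",
    "BruteForceLaw",
    "monte_carlo_frequency",
    "ConditionalTableCache",
    "get_cache",
]

_NEG_INF = -np.inf


def _side(n: int, d: int) -> int:
    """Rows (= columns) within torus distance d of the origin, origin's own
    row/column excluded: a(d) = min(2d, n-1)."""
    if d <= 0:
        return 0
    return min(2 * d, n - 1)


def _logfact(k):
    return gammaln(np.asarray(k, dtype=float) + 1.0)


# ---------------------------------------------------------------------------
# Region decomposition and border-region counts (the Table-1 analogue)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionDecomposition:
    """Geometry of the counting problem at target distance ``d``.

    ``s`` points lie strictly inside distance d, ``e`` exactly at distance d.
    Derived fields: ``side`` = a(d); ``inner_side`` = a(d-1); ``border_lines``
    = number of border rows (= border columns), 2 in general and 1 when
    d = n/2 with n even (``degenerate``: R collapses to one horizontal and one
    vertical line); ``free_inner`` = inner rows (= columns) not used by the s
    inside points.
    """

    n: int
    d: int
    s: int
    e: int
    side: int = field(init=False)
    inner_side: int = field(init=False)
    border_lines: int = field(init=False)
    free_inner: int = field(init=False)
    outside_rows: int = field(init=False)
    degenerate: bool = field(init=False)

    def __post_init__(self):
        n, d = self.n, self.d
        if not 1 <= d <= max_distance(n):
            raise ValueError(f"d={d} out of range for n={n}")
        if self.s < 0 or self.e < 0:
            raise ValueError("s and e must be nonnegative")
        a = _side(n, d)
        a_in = _side(n, d - 1)
        object.__setattr__(self, "side", a)
        object.__setattr__(self, "inner_side", a_in)
        object.__setattr__(self, "border_lines", a - a_in)
        object.__setattr__(self, "free_inner", a_in - self.s)
        object.__setattr__(self, "outside_rows", (n - 1) - a)
        object.__setattr__(self, "degenerate", a - a_in == 1)


def _perm_int(f: int, k: int) -> int:
    if k < 0 or f < k:
        return 0
    out = 1
    for j in range(k):
        out *= f - j
    return out


def region_r_combinations(e: int, s: int, context: RegionDecomposition) -> int:
    """Admissible placements of ``e`` points exactly at distance d, given ``s``
    points strictly inside.

    A point at distance exactly d occupies either a border row (paired with a
    free column within distance d), a border column (paired with a free inner
    row), or a corner cell (border row and border column).  Summing over the
    split (k1, k2, k3) = (border-row points, corners, border-column points)
    with t border lines per axis and f free inner rows/columns:

        N_R = sum C(t,k2)^2 k2! * C(t-k2,k1) P(f,k1) * C(t-k2,k3) P(f,k3)

    Returns 0 for inadmissible (e, s) combinations (never raises for them).
    """
    t = context.border_lines
    f = context.free_inner
    if e < 0 or e > 2 * t or f < 0:
        return 0
    total = 0
    for k2 in range(0, min(t, e) + 1):
        for k1 in range(0, min(t - k2, e - k2) + 1):
            k3 = e - k2 - k1
            if not 0 <= k3 <= t - k2:
                continue
            total += (
                math.comb(t, k2) ** 2
                * math.factorial(k2)
                * math.comb(t - k2, k1)
                * _perm_int(f, k1)
                * math.comb(t - k2, k3)
                * _perm_int(f, k3)
            )
    return total


def _nr_int(n: int, d: int, s: int, e: int) -> int:
    return region_r_combinations(e, s, RegionDecomposition(n=n, d=d, s=s, e=e))


def _comb_small(t: np.ndarray, k: int) -> np.ndarray:
    """C(t, k) for k <= 2, elementwise, 0 where t < k."""
    if k == 0:
        return np.ones_like(t, dtype=float)
    if k == 1:
        return np.maximum(t, 0).astype(float)
    return np.maximum(t, 0).astype(float) * np.maximum(t - 1, 0) / 2.0


def _nr_vec(n: int, d_arr: np.ndarray, s: int, e: int) -> np.ndarray:
    """Vectorized border-region counts N_R(e, s, d) over an array of d values.

    Counts are bounded by ~64 n^2, exactly representable in doubles.
    """
    return _nr_all(n, d_arr, s)[e]


def _nr_all(n: int, d_arr: np.ndarray, s: int) -> np.ndarray:
    """Border-region counts N_R(e, s, d) for e = 1..4 at once; row e holds e.

    Shares the (t, f) geometry across e; the (k1, k2, k3) decomposition of
    :func:`region_r_combinations` is unrolled (t <= 2, so each k is <= 2).
    """
    a_in = np.where(d_arr <= 1, 0, np.minimum(2 * (d_arr - 1), n - 1))
    t = np.minimum(2 * d_arr, n - 1) - a_in
    f = a_in - s
    f1 = np.maximum(f, 0).astype(float)
    P = (np.ones_like(f1), f1, f1 * np.maximum(f - 1, 0))
    out = np.zeros((5, d_arr.size))
    for k2 in (0, 1, 2):
        c2 = _comb_small(t, k2) ** 2 * math.factorial(k2)
        tk = t - k2
        comb_tk = (np.ones_like(f1), np.maximum(tk, 0).astype(float),
                   np.maximum(tk, 0) * np.maximum(tk - 1, 0) / 2.0)
        for k1 in (0, 1, 2):
            left = c2 * comb_tk[k1] * P[k1]
            for k3 in (0, 1, 2):
                e = k1 + k2 + k3
                if e == 0 or e > 4:
                    continue
                out[e] += left * comb_tk[k3] * P[k3]
    out[:, f < 0] = 0.0
    return out


_LF_REGISTRY: dict[int, np.ndarray] = {}


def _lf_table(n: int) -> np.ndarray:
    """Cached log-factorial table 0..2n."""
    lf = _LF_REGISTRY.get(n)
    if lf is None:
        lf = _LF_REGISTRY[n] = gammaln(np.arange(2 * n + 2, dtype=float) + 1.0)
    return lf


def _log_out_vec(n: int, d_arr: np.ndarray, occupied: np.ndarray) -> np.ndarray:
    """log of (m-a)!^2 / (m-2a+occupied)!: placements of the remaining points
    strictly outside distance d, given ``occupied`` = s+e points within."""
    m = n - 1
    lf = _lf_table(n)
    a = np.minimum(2 * d_arr, m)
    r = (m - 2 * a + occupied).astype(int)
    out = 2.0 * lf[m - a] - lf[np.maximum(r, 0)]
    return np.where(r >= 0, out, _NEG_INF)


# ---------------------------------------------------------------------------
# Joint law of a distance prefix
# ---------------------------------------------------------------------------


def _prefix_stats(prefix) -> tuple[list[int], int, int, int]:
    prefix = [int(p) for p in prefix]
    if not prefix:
        return prefix, 0, 0, 0
    if any(prefix[i] > prefix[i + 1] for i in range(len(prefix) - 1)):
        return prefix, -1, -1, -1
    d = prefix[-1]
    c = sum(1 for p in prefix if p == d)
    return prefix, d, c, len(prefix) - c


def count_admissible(d_prefix, n: int) -> int:
    """Number of configurations whose first len(prefix) NN distances equal the
    prefix exactly (exact big-integer arithmetic; reference point fixed).

    Returns 0 for inadmissible prefixes (decreasing, out of range, or more
    than four equal entries in a run).
    """
    m = n - 1
    prefix, d, c, s = _prefix_stats(d_prefix)
    if not prefix:
        return math.factorial(m)
    if d < 0 or c > 4:
        return 0
    if any(p < 1 or p > max_distance(n) for p in prefix):
        return 0
    acc = 1
    sv = 0
    for v, mult in sorted(Counter(p for p in prefix if p < d).items()):
        acc *= _nr_int(n, v, sv, mult)
        sv += mult
    a = _side(n, d)
    total = 0
    for e in range(c, 5):
        r = m - 2 * a + s + e
        if r < 0:
            continue
        total += (
            _nr_int(n, d, s, e)
            * math.factorial(m - a) ** 2
            // math.factorial(r)
        )
    return acc * total


def _log_count_admissible(d_prefix, n: int) -> float:
    """Log-space twin of :func:`count_admissible` (log-gamma arithmetic; no
    intermediate overflow for large n)."""
    m = n - 1
    prefix, d, c, s = _prefix_stats(d_prefix)
    if not prefix:
        return float(_logfact(m))
    if d < 0 or c > 4 or any(p < 1 or p > max_distance(n) for p in prefix):
        return _NEG_INF
    log_acc = 0.0
    sv = 0
    for v, mult in sorted(Counter(p for p in prefix if p < d).items()):
        nr = _nr_int(n, v, sv, mult)
        if nr == 0:
            return _NEG_INF
        log_acc += math.log(nr)
        sv += mult
    darr = np.array([d])
    terms = []
    for e in range(c, 5):
        nr = _nr_vec(n, darr, s, e)[0]
        lo = _log_out_vec(n, darr, np.array([s + e], dtype=float))[0]
        if nr > 0 and lo > _NEG_INF:
            terms.append(math.log(nr) + lo)
    if not terms:
        return _NEG_INF
    return log_acc + logsumexp(terms)


def prob_joint(d_prefix, n: int) -> float:
    """P(D_1=d_1, ..., D_i=d_i) = count_admissible / (n-1)!, via log space."""
    lc = _log_count_admissible(d_prefix, n)
    return 0.0 if lc == _NEG_INF else float(np.exp(lc - _logfact(n - 1)))


# ---------------------------------------------------------------------------
# Survival / CDF, marginals, entropy
# ---------------------------------------------------------------------------


def _log_within_counts(n: int, d: int) -> np.ndarray:
    """log P(exactly j points within distance d), j = 0..n-1.

    Exactly j points inside the a x a block of a random permutation matrix:
    C(a,j)^2 j! (m-a)!^2 / (m-2a+j)! configurations out of m!.
    """
    m = n - 1
    a = _side(n, d)
    j = np.arange(m + 1, dtype=float)
    jc = np.minimum(j, a)
    r = m - 2 * a + j
    with np.errstate(invalid="ignore"):
        val = (
            2.0 * (_logfact(a) - _logfact(jc) - _logfact(np.maximum(a - j, 0)))
            + _logfact(j)
            + 2.0 * _logfact(m - a)
            - _logfact(np.maximum(r, 0))
            - _logfact(m)
        )
    val = np.where((r < 0) | (j > a), _NEG_INF, val)
    return val


def prob_survival(d: int, i: int, n: int) -> float:
    """F_i(d) = P(D_i <= d) = P(at least i points within distance d)."""
    if not 1 <= i <= n - 1:
        raise ValueError(f"i must be in [1, {n - 1}]")
    if d >= max_distance(n):
        return 1.0
    if d < 1:
        return 0.0
    logw = _log_within_counts(n, d)
    return float(np.exp(logsumexp(logw[i:])))


def _marginal_matrix(n: int) -> np.ndarray:
    """P[i, d] = P(D_i = d) for i = 1..n-1, d = 1..floor(n/2) (0-padded)."""
    m = n - 1
    dmax = max_distance(n)
    W = np.zeros((m + 1, dmax + 1))
    for d in range(1, dmax + 1):
        W[:, d] = np.exp(_log_within_counts(n, d))
    F = W[::-1].cumsum(axis=0)[::-1]  # F[i, d] = P(>= i points within d)
    P = np.diff(F, axis=1)
    return np.maximum(P, 0.0)


def prob_marginal(i: int, d: int, n: int) -> float:
    """Marginal P(D_i = d), from differences of the exact CDF."""
    if not 1 <= i <= n - 1:
        raise ValueError(f"i must be in [1, {n - 1}]")
    if not 1 <= d <= max_distance(n):
        return 0.0
    return prob_survival(d, i, n) - prob_survival(d - 1, i, n)


def prob_marginal_from_joint(i: int, d: int, n: int) -> float:
    """Marginal P(D_i = d) by summing joint prefix probabilities.

    Exponential in i; a cross-check route for small n only.
    """
    total = 0.0
    dmax = max_distance(n)

    def rec(prefix, pos):
        nonlocal total
        if pos == i:
            if prefix[-1] == d:
                total += prob_joint(prefix, n)
            return
        lo = prefix[-1] if prefix else 1
        for nxt in range(lo, (d if pos < i - 1 else d) + 1):
            if nxt > dmax:
                break
            rec(prefix + [nxt], pos + 1)

    rec([], 0)
    return total


@dataclass(frozen=True)
class ExactDistribution:
    """A probability table over integer distances, kept in log space.

    ``conditioning`` records the distance history the table is conditioned on
    (empty for marginals).  ``support`` and ``logp`` are aligned arrays; only
    distances with finite log-probability belong to the support proper.
    """

    n: int
    i: int
    conditioning: tuple
    support: np.ndarray
    logp: np.ndarray

    @property
    def probs(self) -> np.ndarray:
        return np.exp(self.logp)

    def prob(self, d: int) -> float:
        idx = np.flatnonzero(self.support == d)
        return float(np.exp(self.logp[idx[0]])) if idx.size else 0.0

    def cdf(self, d: int) -> float:
        mask = self.support <= d
        return float(np.exp(logsumexp(self.logp[mask]))) if mask.any() else 0.0

    def entropy(self) -> float:
        return entropy(self)


def entropy(dist: ExactDistribution) -> float:
    """Shannon entropy of the table in nats (natural log)."""
    p = dist.probs
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def marginal_distribution(i: int, n: int) -> ExactDistribution:
    if not 1 <= i <= n - 1:
        raise ValueError(f"i must be in [1, {n - 1}]")
    P = _marginal_matrix(n)
    dmax = max_distance(n)
    support = np.arange(1, dmax + 1)
    p = P[i, :]
    with np.errstate(divide="ignore"):
        logp = np.log(p)
    return ExactDistribution(n=n, i=i, conditioning=(), support=support, logp=logp)


def marginal_entropies(n: int) -> np.ndarray:
    """H(D_i) for i = 1..n-1, in nats."""
    P = _marginal_matrix(n)[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * np.log(P), 0.0)
    return -terms.sum(axis=1)


class MarginalTails:
    """Log-space tail probabilities of every marginal D_i law for one n.

    ``log_le[i, d]`` = log P(D_i <= d) and ``log_ge[i, d]`` = log P(D_i >= d),
    both tails including the atom at d.  Assembled from the survival
    formulation (P(D_i <= d) = P(at least i points within distance d)), which
    stays accurate in log space even for astronomically small tails -- the
    regime the extreme-path test lives in.
    """

    def __init__(self, n: int):
        self.n = n
        m = n - 1
        dmax = max_distance(n)
        logw = np.full((m + 1, dmax + 1), _NEG_INF)
        logw[0, 0] = 0.0  # zero points within distance 0, surely
        for d in range(1, dmax + 1):
            logw[:, d] = _log_within_counts(n, d)
        # P(D_i <= d) = sum_{j >= i} W(j, d);  P(D_i >= d) = sum_{j < i} W(j, d-1)
        rev = np.logaddexp.accumulate(logw[::-1], axis=0)[::-1]
        fwd = np.logaddexp.accumulate(logw, axis=0)
        self.log_le = np.minimum(rev, 0.0)          # index [i, d]
        self.log_ge = np.minimum(fwd[:, :], 0.0)    # index [i, d] via [i-1, d-1]

    def log_two_sided(self, i, d):
        """log q for observations d of D_i (vectorized; i, d broadcastable)."""
        i = np.asarray(i)
        d = np.asarray(d)
        lo = self.log_le[i, d]
        hi = self.log_ge[i - 1, d - 1]
        return np.minimum(0.0, math.log(2.0) + np.minimum(lo, hi))


_TAILS_REGISTRY: dict[int, MarginalTails] = {}


def get_marginal_tails(n: int) -> MarginalTails:
    tails = _TAILS_REGISTRY.get(n)
    if tails is None:
        tails = _TAILS_REGISTRY[n] = MarginalTails(n)
    return tails


import functools


@functools.lru_cache(maxsize=None)
def default_i_max(n: int) -> int:
    """Advised number of neighbour distances to use in the tests.

    The marginal entropy H(D_i) rises over the first couple of neighbours,
    then decays towards zero before fluctuating upwards again close to
    i = n-1, where the fixed maximal distance floor(n/2) induces strong
    downstream constraints.  Distances beyond the point where the entropy
    starts increasing again carry little usable information, so the default
    is the first local minimum of the entropy sequence after its global peak.
    Callers may override with any i_max <= n-1.
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    H = marginal_entropies(n)
    peak = int(np.argmax(H))
    for i in range(peak, len(H) - 1):
        if H[i + 1] > H[i] + 1e-9:
            return i + 1  # 1-based neighbour index
    return len(H)


# ---------------------------------------------------------------------------
# Conditionals
# ---------------------------------------------------------------------------


def _conditional_logp(n: int, s: int, dp: int, cp: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional law of the next distance given the relevant history summary.

    The history enters only through (s, dp, cp): s distances strictly below
    the last value dp, which occurs cp times at the end (cp <= 4 always, since
    the border region holds at most 4 points) -- this is exactly the 4th-order
    Markov property of the distance sequence.  ``cp = 0`` (with s = 0, dp = 0)
    yields the unconditional law of D_1.

    Returns (support, logp) with support = dp..floor(n/2) (1..dmax for D_1).
    """
    m = n - 1
    dmax = max_distance(n)

    def ring_terms(e_lo: int) -> list[float]:
        darr = np.array([dp])
        out = []
        for e in range(e_lo, 5):
            nr = _nr_int(n, dp, s, e)
            lo = _log_out_vec(n, darr, np.array([float(s + e)]))[0]
            if nr > 0 and np.isfinite(lo):
                out.append(math.log(nr) + lo)
        return out

    if cp == 0:
        logden = float(_lf_table(n)[m])
        log_ring = 0.0
        s2 = 0
        lo_d = 1
    else:
        terms = ring_terms(cp)
        if not terms:
            raise ValueError(
                f"conditioning history (s={s}, d={dp}, run={cp}) has probability zero"
            )
        logden = float(logsumexp(terms))
        nr_ring = _nr_int(n, dp, s, cp)
        log_ring = math.log(nr_ring) if nr_ring > 0 else _NEG_INF
        s2 = s + cp
        lo_d = dp

    support = np.arange(lo_d, dmax + 1)
    logp = np.full(support.shape, _NEG_INF)

    if cp > 0:
        # staying at the same distance: at least cp+1 points on the ring
        terms = ring_terms(cp + 1)
        if terms:
            logp[0] = logsumexp(terms) - logden

    darr = support[1:] if cp > 0 else support
    if darr.size and np.isfinite(log_ring):
        nr = _nr_all(n, darr, s2)[1:5]
        lo = np.empty((4, darr.size))
        for e2 in range(1, 5):
            lo[e2 - 1] = _log_out_vec(n, darr, float(s2 + e2))
        # logsumexp over e2 of log(nr) + lo, with nr possibly zero
        mx = np.where(nr > 0, lo, _NEG_INF).max(axis=0)
        ok = np.isfinite(mx)
        vals = np.full(darr.size, _NEG_INF)
        with np.errstate(invalid="ignore"):
            body = (nr[:, ok] * np.exp(lo[:, ok] - mx[ok])).sum(axis=0)
        vals[ok] = np.log(body) + mx[ok] + log_ring - logden
        if cp > 0:
            logp[1:] = vals
        else:
            logp[:] = vals
    return support, logp


def _history_summary(history) -> tuple[int, int, int]:
    """(s, dp, cp) for a nonempty history; validates monotonicity and run caps."""
    h = [int(v) for v in history]
    if any(h[i] > h[i + 1] for i in range(len(h) - 1)):
        raise ValueError("history must be nondecreasing")
    dp = h[-1]
    cp = 0
    for v in reversed(h):
        if v == dp:
            cp += 1
        else:
            break
    if cp > 4:
        raise ValueError(
            "conditioning history has probability zero (more than 4 equal distances)"
        )
    return len(h) - cp, dp, cp


def conditional_distribution(history, n: int, i: int | None = None) -> ExactDistribution:
    """Law of D_{i+1} given D_1..D_i = history (empty history: law of D_1).

    The conditional depends on the history only through its last min(4, len)
    entries (4th-order Markov chain); internally it is summarized by
    (s, dp, cp).  A zero-probability history raises ``ValueError``.
    """
    h = tuple(int(v) for v in history)
    if h and not all(1 <= v <= max_distance(n) for v in h):
        raise ValueError("history values out of range")
    if h:
        s, dp, cp = _history_summary(h)
        if count_admissible(list(h), n) == 0:
            raise ValueError("conditioning history has probability zero")
    else:
        s, dp, cp = 0, 0, 0
    support, logp = _conditional_logp(n, s, dp, cp)
    return ExactDistribution(
        n=n, i=(len(h) + 1 if i is None else i), conditioning=h,
        support=support, logp=logp,
    )


def prob_conditional(d_next: int, history, n: int) -> float:
    """P(D_{i+1} = d_next | D_1..D_i = history)."""
    return conditional_distribution(history, n).prob(int(d_next))


# ---------------------------------------------------------------------------
# Oracles: exhaustive enumeration and Monte Carlo
# ---------------------------------------------------------------------------


@dataclass
class BruteForceLaw:
    """Exact joint law of (D_1..D_{n-1}) from exhaustive enumeration.

    ``law`` maps each full sorted distance sequence to its rational
    probability (denominator (n-1)!).
    """

    n: int
    law: dict

    def prefix_probability(self, prefix) -> Fraction:
        prefix = tuple(int(p) for p in prefix)
        k = len(prefix)
        return sum(
            (p for seq, p in self.law.items() if seq[:k] == prefix),
            Fraction(0),
        )

    def marginal(self, i: int) -> dict:
        out = {}
        for seq, p in self.law.items():
            out[seq[i - 1]] = out.get(seq[i - 1], Fraction(0)) + p
        return out

    def conditional(self, history) -> dict:
        """Exact conditional law of the next distance given a full history."""
        history = tuple(int(p) for p in history)
        k = len(history)
        num = {}
        den = Fraction(0)
        for seq, p in self.law.items():
            if seq[:k] == history:
                den += p
                num[seq[k]] = num.get(seq[k], Fraction(0)) + p
        if den == 0:
            raise ValueError("history has probability zero")
        return {d: p / den for d, p in sorted(num.items())}

    def histories(self, length: int):
        """All positive-probability histories of the given length."""
        return sorted({seq[:length] for seq in self.law})

    def max_points_at_any_distance(self) -> int:
        """Longest run of equal entries over all sequences = the most points
        observed exactly at one distance from the reference point."""
        best = 0
        for seq in self.law:
            run = 1
            for u, v in zip(seq, seq[1:]):
                run = run + 1 if u == v else 1
                best = max(best, run)
            best = max(best, run if len(seq) == 1 else best)
        return best


def brute_force_distribution(n: int) -> BruteForceLaw:
    """Enumerate all (n-1)! configurations with the reference at the origin."""
    if n > 9:
        raise ValueError(
            "enumeration of (n-1)! configurations is infeasible for n > 9; "
            "use monte_carlo_frequency instead"
        )
    if n < 2:
        raise ValueError("n must be >= 2")
    m = n - 1
    counts = Counter()
    rows = range(1, n)
    for cols in itertools.permutations(rows):
        ds = sorted(
            max(min(r, n - r), min(c, n - c)) for r, c in zip(rows, cols)
        )
        counts[tuple(ds)] += 1
    fact = math.factorial(m)
    return BruteForceLaw(n=n, law={k: Fraction(v, fact) for k, v in counts.items()})


def monte_carlo_frequency(
    n: int, i: int, reps: int, seed: int, chunk: int = 20000
) -> dict:
    """Empirical frequencies of D_i over ``reps`` random configurations.

    Vectorized: the x-permutation is fixed to the identity (distances from the
    reference point only depend on the relative configuration) and the
    y-permutation is drawn uniformly.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not 1 <= i <= n - 1:
        raise ValueError(f"i must be in [1, {n - 1}]")
    rng = np.random.default_rng(seed)
    k = np.arange(1, n)
    dx = np.minimum(k, n - k)
    counts = np.zeros(max_distance(n) + 1, dtype=np.int64)
    done = 0
    while done < reps:
        b = min(chunk, reps - done)
        y = np.argsort(rng.random((b, n)), axis=1)
        dy = np.abs(y[:, 1:] - y[:, :1])
        np.minimum(dy, n - dy, out=dy)
        D = np.maximum(dx[None, :], dy)
        di = np.partition(D, i - 1, axis=1)[:, i - 1]
        counts += np.bincount(di, minlength=counts.size)
        done += b
    return {d: counts[d] / reps for d in range(1, counts.size) if counts[d] > 0}


# ---------------------------------------------------------------------------
# Conditional-table cache
# ---------------------------------------------------------------------------

_CACHE_FORMAT_VERSION = 1


class ConditionalTableCache:
    """Lazy cache of conditional tables for one sample size.

    Tables are keyed by the Markov summary (s, dp, cp); the key (0, 0, 0)
    holds the unconditional law of D_1.  Each entry stores log-probabilities
    over support dp..floor(n/2) together with log-CDFs from both ends (used
    by the discrete two-sided p-value).  Caching is transparent: entries are
    recomputed identically when the cache is cold.

    ``save``/``load`` give an optional on-disk form: a JSON object
    ``{"format_version": 1, "n": n, "tables": {"s,dp,cp": [logp, ...]}}``.
    """

    def __init__(self, n: int):
        self.n = n
        self._tables: dict = {}

    def get(self, s: int, dp: int, cp: int):
        key = (s, dp, cp)
        tbl = self._tables.get(key)
        if tbl is None:
            support, logp = _conditional_logp(self.n, s, dp, cp)
            probs = np.exp(logp)
            log_le = np.logaddexp.accumulate(logp)
            log_ge = np.logaddexp.accumulate(logp[::-1])[::-1]
            tbl = (support, logp, probs, np.minimum(log_le, 0.0), np.minimum(log_ge, 0.0))
            self._tables[key] = tbl
        return tbl

    def save(self, path) -> None:
        data = {
            "format_version": _CACHE_FORMAT_VERSION,
            "n": self.n,
            "tables": {
                f"{s},{dp},{cp}": logp.tolist()
                for (s, dp, cp), (_, logp, *_rest) in self._tables.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(data, fh)

    @classmethod
    def load(cls, path) -> "ConditionalTableCache":
        with open(path) as fh:
            data = json.load(fh)
        if data.get("format_version") != _CACHE_FORMAT_VERSION:
            raise ValueError("unsupported cache format version")
        cache = cls(int(data["n"]))
        dmax = max_distance(cache.n)
        for key, logp_list in data["tables"].items():
            s, dp, cp = (int(v) for v in key.split(","))
            logp = np.asarray(logp_list, dtype=float)
            support = np.arange(dp if cp else 1, dmax + 1)
            probs = np.exp(logp)
            log_le = np.logaddexp.accumulate(logp)
            log_ge = np.logaddexp.accumulate(logp[::-1])[::-1]
            cache._tables[(s, dp, cp)] = (
                support, logp, probs, np.minimum(log_le, 0.0), np.minimum(log_ge, 0.0)
            )
        return cache


_REGISTRY: dict[int, ConditionalTableCache] = {}


def get_cache(n: int) -> ConditionalTableCache:
    """Process-wide cache registry, one cache per sample size."""
    cache = _REGISTRY.get(n)
    if cache is None:
        cache = _REGISTRY[n] = ConditionalTableCache(n)
    return cache
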