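"""MI-calibrated benchmark framework for independence tests.

Dependence strength is made comparable across wildly different shapes
(lines, curves, circles, patchwork copulas) by calibrating every benchmark
distribution to a prescribed mutual information (MI, natural log).  For
functional dependencies Y = f(X) + noise the joint density is discretized on
a fine quadratic grid, its MI is computed in closed form on the grid, and the
Gaussian noise level sigma is found by bisection so the grid MI hits the
target.  Patchwork copulas provide a non-functional dependence with uniform
marginals and an exact closed-form MI.

The power protocol follows the empirical-cutoff design: a reference ensemble
of independent samples fixes the (1 - alpha) cutoff of each method's
statistic, and power is the fraction of dependent test samples beyond it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, pearsonr, rankdata

from ._functional_forms import ALL_KINDS, CIRCLE_RADIUS, FUNCTIONAL_KINDS, FUNCTIONS
from .core_geometry import PermutationPair, nn_distance_profile
from .exact_distribution import default_i_max, get_cache, get_marginal_tails
from .independence_tests import chisq_statistic, extreme_test

__all__ = [
    "DependenceSpec",
    "GridDensity",
    "PatchworkCopula",
    "PowerResult",
    "MethodUnavailableError",
    "sample_functional",
    "grid_density",
    "mutual_information_grid",
    "calibrate_sigma",
    "patchwork_build",
    "patchwork_search",
    "patchwork_sample",
    "project_to_torus",
    "evaluate_method",
    "estimate_power",
    "roc_points",
    "distance_correlation",
    "hoeffding_d",
    "METHODS",
]


class MethodUnavailableError(RuntimeError):
    """Raised when an optional wrapped method's backend is not installed."""


# ---------------------------------------------------------------------------
# Dependence specifications and sampling
# ---------------------------------------------------------------------------


@dataclass
class PatchworkCopula:
    """Piecewise-constant copula on an unevenly spaced g x g grid.

    Cell (i, j) carries probability ``p[i, j]`` and occupies the rectangle
    [A_{i-1}, A_i] x [B_{j-1}, B_j], where the breakpoints A and B are the
    cumulative row sums ``a`` and column sums ``b``.  With that choice both
    marginals are exactly uniform, and

        MI = sum_{ij} p_ij log(p_ij / (a_i b_j)).
    """

    g: int
    p: np.ndarray
    a: np.ndarray = field(init=False)
    b: np.ndarray = field(init=False)
    x_breaks: np.ndarray = field(init=False)
    y_breaks: np.ndarray = field(init=False)
    mi: float = field(init=False)

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        if p.shape != (self.g, self.g):
            raise ValueError("weights must be a g x g matrix")
        if (p < 0).any():
            raise ValueError("weights must be nonnegative")
        if not math.isclose(p.sum(), 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError("weights must sum to 1 (use patchwork_build)")
        self.p = p
        self.a = p.sum(axis=1)
        self.b = p.sum(axis=0)
        self.x_breaks = np.r_[0.0, np.cumsum(self.a)]
        self.y_breaks = np.r_[0.0, np.cumsum(self.b)]
        ab = np.outer(self.a, self.b)
        mask = p > 0
        self.mi = float(np.sum(p[mask] * np.log(p[mask] / ab[mask])))


@dataclass
class DependenceSpec:
    """One benchmark dependence: a shape plus its calibrated strength.

    Functional kinds carry a noise level ``sigma``; the patchwork kind carries
    a copula.  ``target_mi`` records the MI the parameters were calibrated to.
    ``geometry`` marks whether downstream NN computations should treat the
    sample as toroidal (the NN tests always use the torus metric on ranks;
    the flag documents the benchmark condition).
    """

    kind: str
    sigma: float | None = None
    copula: PatchworkCopula | None = None
    target_mi: float = 0.0
    geometry: str = "euclidean"

    def __post_init__(self):
        if self.kind not in ALL_KINDS:
            raise ValueError(f"unknown dependence kind {self.kind!r}")
        if self.kind == "patchwork":
            if self.copula is None or self.sigma is not None:
                raise ValueError("patchwork kind requires copula and no sigma")
        else:
            if self.sigma is None or self.copula is not None:
                raise ValueError(f"kind {self.kind!r} requires sigma and no copula")
        if self.geometry not in ("euclidean", "torus"):
            raise ValueError("geometry must be 'euclidean' or 'torus'")


def sample_functional(spec: DependenceSpec, n_points: int, seed) -> tuple[np.ndarray, np.ndarray]:
    """Draw a sample from a functional dependence.

    X ~ U(0,1) i.i.d. and Y = f(X) + eps with eps ~ N(0, sigma^2); the circle
    is parameterized by a uniform angle with isotropic Gaussian noise on both
    coordinates (Y is not a function of X there).
    """
    if spec.kind == "patchwork":
        raise ValueError("use patchwork_sample for the patchwork kind")
    rng = np.random.default_rng(seed)
    if spec.kind == "circle":
        theta = rng.uniform(0.0, 2.0 * np.pi, n_points)
        x = CIRCLE_RADIUS * np.cos(theta) + spec.sigma * rng.standard_normal(n_points)
        y = CIRCLE_RADIUS * np.sin(theta) + spec.sigma * rng.standard_normal(n_points)
        return x, y
    x = rng.uniform(0.0, 1.0, n_points)
    y = FUNCTIONS[spec.kind](x) + spec.sigma * rng.standard_normal(n_points)
    return x, y


def sample_dependence(spec: DependenceSpec, n_points: int, seed):
    """Sample from any benchmark dependence (functional or patchwork)."""
    if spec.kind == "patchwork":
        return patchwork_sample(spec.copula, n_points, seed)
    return sample_functional(spec, n_points, seed)


# ---------------------------------------------------------------------------
# Grid densities and mutual information
# ---------------------------------------------------------------------------


@dataclass
class GridDensity:
    """Piecewise-constant approximation of a joint density on an m x m grid."""

    m: int
    q: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray

    @property
    def marginal_x(self) -> np.ndarray:
        return self.q.sum(axis=1)

    @property
    def marginal_y(self) -> np.ndarray:
        return self.q.sum(axis=0)


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(8)


def grid_density(spec: DependenceSpec, m: int = 300) -> GridDensity:
    """Discretize the model density of a dependence on an m x m quadratic grid.

    Functional kinds: for each x-cell the Gaussian kernel is integrated across
    the y-cells at 8 Gauss-Legendre nodes per cell.  Circle kind: the angle is
    integrated by midpoint quadrature (4096 nodes); x and y are conditionally
    independent given the angle.  The y-range covers the function range plus
    6 sigma, so the truncated mass is negligible; cells are renormalized to
    sum to exactly 1.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    sigma = spec.sigma
    if sigma is None or sigma <= 0:
        raise ValueError("grid_density requires sigma > 0")
    if spec.kind == "circle":
        lo, hi = -CIRCLE_RADIUS - 6 * sigma, CIRCLE_RADIUS + 6 * sigma
        x_edges = np.linspace(lo, hi, m + 1)
        y_edges = x_edges.copy()
        theta = (np.arange(4096) + 0.5) * (2 * np.pi / 4096)
        cx = CIRCLE_RADIUS * np.cos(theta)
        cy = CIRCLE_RADIUS * np.sin(theta)
        ax = np.diff(norm.cdf((x_edges[None, :] - cx[:, None]) / sigma), axis=1)
        ay = np.diff(norm.cdf((y_edges[None, :] - cy[:, None]) / sigma), axis=1)
        q = ax.T @ ay / theta.size
    elif spec.kind in FUNCTIONAL_KINDS:
        f = FUNCTIONS[spec.kind]
        x_edges = np.linspace(0.0, 1.0, m + 1)
        fx_probe = f(np.linspace(0.0, 1.0, 4 * m + 1))
        lo, hi = fx_probe.min() - 6 * sigma, fx_probe.max() + 6 * sigma
        y_edges = np.linspace(lo, hi, m + 1)
        # Gauss-Legendre nodes within each x cell
        mid = (x_edges[:-1] + x_edges[1:]) / 2.0
        half = (x_edges[1] - x_edges[0]) / 2.0
        nodes = mid[:, None] + half * _GL_NODES[None, :]      # (m, 8)
        fx = f(nodes)
        z = (y_edges[None, None, :] - fx[:, :, None]) / sigma  # (m, 8, m+1)
        cdf = norm.cdf(z)
        cell = np.diff(cdf, axis=2)                            # (m, 8, m)
        q = np.tensordot(cell, _GL_WEIGHTS, axes=([1], [0])) / 2.0 / m
    else:
        raise ValueError("grid_density applies to functional kinds only")
    q = np.maximum(q, 0.0)
    q /= q.sum()
    return GridDensity(m=m, q=q, x_edges=x_edges, y_edges=y_edges)


def independent_grid_density(m: int = 300) -> GridDensity:
    """Product (independent) density on the unit square; MI is exactly 0."""
    edges = np.linspace(0.0, 1.0, m + 1)
    return GridDensity(m=m, q=np.full((m, m), 1.0 / (m * m)),
                       x_edges=edges, y_edges=edges)


def mutual_information_grid(density: GridDensity) -> float:
    """MI (nats) of a grid density: sum q log(q / (q_x q_y)) over q > 0."""
    q = density.q
    qx = density.marginal_x
    qy = density.marginal_y
    mask = q > 0
    outer = np.outer(qx, qy)
    return float(np.sum(q[mask] * np.log(q[mask] / outer[mask])))


def _mi_of_sigma(kind: str, sigma: float, m: int) -> float:
    return mutual_information_grid(
        grid_density(DependenceSpec(kind=kind, sigma=sigma), m=m)
    )


def calibrate_sigma(
    kind: str,
    target_mi: float,
    tol: float | None = None,
    m: int = 300,
    max_iter: int = 80,
) -> float:
    """Noise level sigma whose grid MI matches ``target_mi`` within ``tol``.

    Grid MI decreases monotonically in sigma, so plain bisection applies.  The
    bracket starts at [sigma/2, sigma*2] around 0.25 and is expanded
    geometrically until it straddles the target.  Unattainable targets (above
    the MI of the least-noise bracket endpoint reachable before the expansion
    cap) raise ``ValueError``.
    """
    if target_mi <= 0:
        raise ValueError("target_mi must be > 0")
    if kind not in FUNCTIONAL_KINDS and kind != "circle":
        raise ValueError(f"cannot calibrate sigma for kind {kind!r}")
    if tol is None:
        tol = max(1e-4, 0.01 * target_mi)
    lo, hi = 0.25, 0.5
    mi_lo = _mi_of_sigma(kind, lo, m)
    for _ in range(40):
        if mi_lo > target_mi:
            break
        lo /= 2.0
        mi_lo = _mi_of_sigma(kind, lo, m)
    else:
        raise ValueError(f"target MI {target_mi} unattainable for kind {kind!r}")
    mi_hi = _mi_of_sigma(kind, hi, m)
    for _ in range(40):
        if mi_hi < target_mi:
            break
        hi *= 2.0
        mi_hi = _mi_of_sigma(kind, hi, m)
    else:
        raise ValueError(f"target MI {target_mi} unattainable for kind {kind!r}")
    for _ in range(max_iter):
        mid = math.sqrt(lo * hi)  # geometric bisection: sigma spans decades
        mi_mid = _mi_of_sigma(kind, mid, m)
        if abs(mi_mid - target_mi) <= tol:
            return mid
        if mi_mid > target_mi:
            lo = mid
        else:
            hi = mid
    raise ValueError(
        f"sigma calibration did not converge for kind={kind!r}, target={target_mi}"
    )


# ---------------------------------------------------------------------------
# Patchwork copulas
# ---------------------------------------------------------------------------


def patchwork_build(weights, normalize: bool = True) -> PatchworkCopula:
    """Build a patchwork copula from a nonnegative g x g weight matrix."""
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weights must be a square matrix")
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must not all be zero")
    if normalize:
        w = w / total
    return PatchworkCopula(g=w.shape[0], p=w)


def patchwork_search(
    g: int,
    target_mi: float,
    tol: float = 0.005,
    seed: int = 0,
    max_proposals: int = 100_000,
) -> PatchworkCopula:
    """Random search for a patchwork copula with MI close to ``target_mi``.

    Proposals are i.i.d. U(0,1) weights raised to a concentration exponent and
    normalized; the exponent doubles whenever a batch of proposals undershoots
    the target (more concentrated weights give larger MI, up to the log(g)
    bound attained only by permutation-supported copulas).  Deterministic
    under ``seed``; raises with the best-found MI if the cap is exhausted.
    """
    if target_mi < 0:
        raise ValueError("target_mi must be >= 0")
    if target_mi > math.log(g) + 1e-12:
        raise ValueError(f"target MI {target_mi} exceeds the bound log({g})")
    rng = np.random.default_rng(seed)
    kappa = 1.0
    best = None
    best_err = np.inf
    batch = 200
    proposals = 0
    while proposals < max_proposals:
        reached = -np.inf
        for _ in range(batch):
            cop = patchwork_build(rng.uniform(size=(g, g)) ** kappa)
            proposals += 1
            err = abs(cop.mi - target_mi)
            if err < best_err:
                best, best_err = cop, err
            if err <= tol:
                return cop
            reached = max(reached, cop.mi)
        if reached < target_mi:
            kappa *= 2.0
    raise ValueError(
        f"no copula within tol={tol} of MI={target_mi} after {max_proposals} "
        f"proposals; best found MI={best.mi:.5f}"
    )


def patchwork_sample(copula: PatchworkCopula, n_points: int, seed) -> tuple[np.ndarray, np.ndarray]:
    """Sample a patchwork copula: pick a rectangle by its weight, then a
    uniform point inside it."""
    rng = np.random.default_rng(seed)
    g = copula.g
    flat = rng.choice(g * g, size=n_points, p=copula.p.ravel())
    i, j = np.divmod(flat, g)
    u = rng.uniform(size=n_points)
    v = rng.uniform(size=n_points)
    x = copula.x_breaks[i] + u * (copula.x_breaks[i + 1] - copula.x_breaks[i])
    y = copula.y_breaks[j] + v * (copula.y_breaks[j + 1] - copula.y_breaks[j])
    return x, y


def patchwork_grid_density(copula: PatchworkCopula, m: int = 300) -> GridDensity:
    """Embed a patchwork copula as a GridDensity.

    The grid edges are the union of a regular m-grid and the copula's
    breakpoints, so every grid cell lies inside a single constant-density
    rectangle and cell mass is the exact integral of the copula density.
    Refining a partition within constant-density regions leaves MI unchanged,
    so the grid MI of the embedding equals the closed form to float precision.
    """
    x_edges = np.union1d(np.linspace(0.0, 1.0, m + 1), copula.x_breaks)
    y_edges = np.union1d(np.linspace(0.0, 1.0, m + 1), copula.y_breaks)

    def overlaps(edges, breaks):
        lo = np.maximum(edges[:-1][:, None], breaks[:-1][None, :])
        hi = np.minimum(edges[1:][:, None], breaks[1:][None, :])
        return np.maximum(hi - lo, 0.0)

    ox = overlaps(x_edges, copula.x_breaks)
    oy = overlaps(y_edges, copula.y_breaks)
    widths = np.diff(copula.x_breaks)
    heights = np.diff(copula.y_breaks)
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = np.where(
            copula.p > 0, copula.p / np.outer(widths, heights), 0.0
        )
    q = ox @ dens @ oy.T
    q /= q.sum()
    return GridDensity(m=m, q=q, x_edges=x_edges, y_edges=y_edges)


# ---------------------------------------------------------------------------
# Torus projection marker
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TorusSample:
    """Paired data marked for toroidal nearest-neighbour geometry.

    The NN-based tests always work on the rank torus; the marker records the
    benchmark condition.  Wrapped (non-NN) methods receive the untransformed
    coordinates -- adapting their internals to the torus is out of scope, and
    this asymmetry is a documented limitation of the benchmark.
    """

    x: np.ndarray
    y: np.ndarray
    geometry: str = "torus"


def project_to_torus(x, y) -> TorusSample:
    """Mark unit-square data for toroidal geometry downstream."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return TorusSample(x=x, y=y)


# ---------------------------------------------------------------------------
# Wrapped dependence measures and the novel tests, behind one interface
# ---------------------------------------------------------------------------


def distance_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Distance correlation (biased V-statistic form, Euclidean distances).

    dCor^2 = V^2(x, y) / sqrt(V^2(x) V^2(y)) with V^2 the mean product of
    double-centered distance matrices; zero iff independent in the population.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    def centered(v):
        d = np.abs(v[:, None] - v[None, :])
        return d - d.mean(axis=0) - d.mean(axis=1)[:, None] + d.mean()

    A = centered(x)
    B = centered(y)
    vxy = (A * B).mean()
    vxx = (A * A).mean()
    vyy = (B * B).mean()
    denom = math.sqrt(vxx * vyy)
    return 0.0 if denom == 0 else math.sqrt(max(vxy, 0.0) / denom)


def hoeffding_d(x: np.ndarray, y: np.ndarray) -> float:
    """Hoeffding's D statistic from the classical rank formula.

    D = 30 ((n-2)(n-3) D1 + D2 - 2(n-2) D3) / (n(n-1)(n-2)(n-3)(n-4)) with
    D1 = sum (Q-1)(Q-2), D2 = sum (R-1)(R-2)(S-1)(S-2),
    D3 = sum (R-2)(S-2)(Q-1), where R, S are the marginal ranks and Q the
    bivariate rank (number of points strictly below in both coordinates, plus
    ties counted half, plus one).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 5:
        raise ValueError("Hoeffding's D needs at least 5 points")
    R = rankdata(x)
    S = rankdata(y)
    lx = x[:, None] < x[None, :]
    ly = y[:, None] < y[None, :]
    ex = x[:, None] == x[None, :]
    ey = y[:, None] == y[None, :]
    Q = 1.0 + (lx & ly).sum(axis=0)
    Q += 0.25 * ((ex & ey).sum(axis=0) - 1)
    Q += 0.5 * ((ex & ly).sum(axis=0) + (lx & ey).sum(axis=0))
    d1 = np.sum((Q - 1) * (Q - 2))
    d2 = np.sum((R - 1) * (R - 2) * (S - 1) * (S - 2))
    d3 = np.sum((R - 2) * (S - 2) * (Q - 1))
    return float(
        30.0
        * ((n - 2) * (n - 3) * d1 + d2 - 2 * (n - 2) * d3)
        / (n * (n - 1) * (n - 2) * (n - 3) * (n - 4))
    )


def _kraskov_mi(x, y, n_neighbors: int = 6) -> float:
    from sklearn.feature_selection import mutual_info_regression

    return float(
        mutual_info_regression(
            np.asarray(x, dtype=float).reshape(-1, 1),
            np.asarray(y, dtype=float),
            n_neighbors=n_neighbors,
            random_state=0,
        )[0]
    )


def _mic(x, y) -> float:
    try:
        from minepy import MINE
    except ImportError as exc:  # pragma: no cover - optional backend
        raise MethodUnavailableError(
            "method 'mic' requires the optional minepy package"
        ) from exc
    mine = MINE(alpha=0.6, c=15)
    mine.compute_score(np.asarray(x, float), np.asarray(y, float))
    return float(mine.mic())


def _novel_statistic(x, y, which: str, i_max: int | None = None, tie_seed: int = 0):
    pair = PermutationPair.from_data(x, y, tie_seed=tie_seed)
    n = pair.n
    im = min(i_max if i_max is not None else default_i_max(n), n - 1)
    profile = nn_distance_profile(pair, im)
    if which == "chisq":
        return chisq_statistic(profile, get_cache(n))[0]
    return extreme_test(profile, tails=get_marginal_tails(n)).E


METHODS = ("pearson", "dcor", "hoeffd", "kraskov_mi", "mic", "novel_chisq", "novel_ext")


def evaluate_method(name: str, x, y, options: dict | None = None) -> float:
    """Evaluate one dependence measure; larger output = more dependence.

    Pearson reports |r|; dcor the distance correlation; hoeffd Hoeffding's D;
    kraskov_mi the KSG estimator (scikit-learn backend); mic the maximal
    information coefficient (optional minepy backend, raises
    MethodUnavailableError when absent); novel_chisq / novel_ext the package's
    NN-distance statistics.
    """
    options = options or {}
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("evaluate_method requires complete paired data")
    if name == "pearson":
        return abs(float(pearsonr(x, y)[0]))
    if name == "dcor":
        return distance_correlation(x, y)
    if name == "hoeffd":
        return hoeffding_d(x, y)
    if name == "kraskov_mi":
        return _kraskov_mi(x, y, n_neighbors=options.get("n_neighbors", 6))
    if name == "mic":
        return _mic(x, y)
    if name in ("novel_chisq", "novel_ext"):
        return _novel_statistic(
            x, y, which="chisq" if name == "novel_chisq" else "ext",
            i_max=options.get("i_max"), tie_seed=options.get("tie_seed", 0),
        )
    raise ValueError(f"unknown method {name!r}")


# ---------------------------------------------------------------------------
# Power and ROC harness
# ---------------------------------------------------------------------------


@dataclass
class PowerResult:
    method: str
    spec: DependenceSpec
    n_points: int
    n_test: int
    n_ref: int
    alpha: float
    power: float
    cutoff: float
    seeds: dict = field(default_factory=dict)


def _method_stats(method, xs, ys, options) -> np.ndarray:
    return np.array([evaluate_method(method, x, y, options) for x, y in zip(xs, ys)])


def _ensembles(spec, n_points, n_test, n_ref, seed):
    """Disjoint seed streams for the reference and test ensembles."""
    ss = np.random.SeedSequence(seed)
    ref_seeds, test_seeds = ss.spawn(2)
    ref = [
        tuple(np.random.default_rng(s).uniform(size=(2, n_points)))
        for s in ref_seeds.spawn(n_ref)
    ]
    test = [
        sample_dependence(spec, n_points, s) for s in test_seeds.spawn(n_test)
    ]
    return ref, test


def estimate_power(
    method: str,
    spec: DependenceSpec,
    n_points: int,
    n_test: int,
    n_ref: int,
    alpha: float = 0.05,
    seed: int = 0,
    options: dict | None = None,
) -> PowerResult:
    """Empirical power of a method on one dependence at one MI.

    The cutoff is the ceil((1-alpha) n_ref)-th order statistic of the method's
    statistic over ``n_ref`` independent reference samples; power is the
    fraction of ``n_test`` dependent samples with a statistic beyond it.
    """
    if n_test < 20 or n_ref < 20:
        raise ValueError("n_test and n_ref must be >= 20")
    ref, test = _ensembles(spec, n_points, n_test, n_ref, seed)
    ref_stats = _method_stats(method, [r[0] for r in ref], [r[1] for r in ref], options)
    test_stats = _method_stats(method, [t[0] for t in test], [t[1] for t in test], options)
    k = math.ceil((1.0 - alpha) * n_ref)
    cutoff = float(np.sort(ref_stats)[k - 1])
    power = float(np.mean(test_stats > cutoff))
    return PowerResult(
        method=method, spec=spec, n_points=n_points, n_test=n_test,
        n_ref=n_ref, alpha=alpha, power=power, cutoff=cutoff,
        seeds={"root": seed},
    )


def roc_points(
    method: str,
    spec: DependenceSpec,
    n_points: int,
    n_test: int,
    n_ref: int,
    seed: int = 0,
    options: dict | None = None,
) -> list[tuple[float, float]]:
    """Receiver operating curve from pooled reference/test statistics."""
    from sklearn.metrics import roc_curve

    ref, test = _ensembles(spec, n_points, n_test, n_ref, seed)
    ref_stats = _method_stats(method, [r[0] for r in ref], [r[1] for r in ref], options)
    test_stats = _method_stats(method, [t[0] for t in test], [t[1] for t in test], options)
    labels = np.r_[np.zeros(n_ref), np.ones(n_test)]
    fpr, tpr, _ = roc_curve(labels, np.r_[ref_stats, test_stats])
    return list(zip(fpr.tolist(), tpr.tolist()))
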