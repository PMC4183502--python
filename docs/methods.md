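# Methods

## Model

Paired observations (x_k, y_k), k = 1..n, are rank-transformed with random
tie-breaking, giving two paired permutations of {0..n-1}. The n points
z_k = (x_k, y_k) then occupy an n x n lattice with exactly one point per row
and per column. Under the null hypothesis of independence every one of the
(n-1)! configurations (reference point fixed) is equally likely. The lattice
is treated as a torus with the Chebyshev metric

    d(z, z') = max( delta(x, x'), delta(y, y') ),
    delta(u, v) = min(|u - v|, n - |u - v|),

because the torus makes the metric translation invariant: the distance law
from any reference point is the same, so one exact computation serves all n
points. This biases results for data on a plane (border points acquire
wrap-around neighbours); the bias is smallest for close neighbours, which is
one reason to cap the neighbour index i (below). Let D_1 <= ... <= D_{n-1}
denote the sorted distances from the reference point to the others.

## Exact distance law by configuration counting

Write m = n-1 and a(d) = min(2d, m) for the number of rows (equivalently
columns) within distance d of the origin. Key facts:

* A point at distance exactly d has a coordinate residue of +-d, so at most
  2 border rows and 2 border columns carry such points: **at most 4 points sit
  at any exact distance** (2 when d = n/2 with even n, where the border
  degenerates to a single row and column — the formulas branch on parity
  only through a(d) and the border-line count t = a(d) - a(d-1)).
* The number of configurations with exactly j points within distance d is
  C(a,j)^2 j! (m-a)!^2 / (m-2a+j)! — choose the j occupied rows and columns
  inside the a x a block and a bijection, place the a-j remaining inside rows
  on outside columns, and let the outside rows fill the rest. This yields the
  CDF F_i(d) = P(D_i <= d) = P(at least i points within d) directly, and
  marginals as differences.
* A full prefix event {D_1=d_1, ..., D_i=d_i} factorizes over "rings":
  count = [prod over distinct inner values v: N_R(mult_v, s_v, v)] x
  sum_{e >= c} N_R(e, s, d) (m-a(d))!^2 / (m-2a(d)+s+e)!, where s points lie
  strictly inside the final distance d, c is the multiplicity of d in the
  prefix (the sum over e >= c accounts for further points at exactly d beyond
  the ith), and N_R(e, s, v) counts placements of e points exactly at
  distance v given s points strictly inside: summing over corner points (k2),
  border-row points (k1) and border-column points (k3) with k1+k2+k3 = e,

      N_R = sum C(t,k2)^2 k2! * C(t-k2,k1) P(f,k1) * C(t-k2,k3) P(f,k3),

  with t border lines per axis and f = a(v-1) - s free inner rows/columns.

Conditionals follow as count ratios. Because at most 4 points share a
distance, the conditional law of D_{i+1} given the whole history depends only
on (i, last value, trailing run length): the distance sequence is a 4th-order
Markov chain. The package verifies all of this against an independent oracle:
exhaustive enumeration of all (n-1)! configurations for n <= 9 (exact
rational arithmetic) and Monte-Carlo frequencies for larger n.

Numerics: counts are evaluated in log space with log-gamma (no overflow for
n up to a few thousand; a sample of a few hundred points is the practical
regime); `count_admissible` retains exact big-integer arithmetic as a slow
verification path. Conditional tables are cached per sample size, keyed by
the Markov summary (s, dp, cp); caching is transparent and an optional
JSON on-disk form is provided (`ConditionalTableCache.save/load`, format
version 1).

## How many neighbours to use (i_max)

The marginal entropy H(D_i) (natural log everywhere) rises slightly over the
first two or three neighbours, then decays towards zero before fluctuating
upwards again near i = n-1, where the bounded maximal distance floor(n/2)
imposes strong downstream constraints. Distances beyond the point where the
entropy starts rising again carry little information, so `default_i_max(n)`
returns the first local minimum of the entropy sequence **after its global
peak** (the literal first local minimum would be i = 1 because of the small
initial rise). For n = 320 this gives i_max = 247. The cap is a caller
option everywhere.

## The two tests

**Distributional (chi-squared) test.** For each neighbour index i, the null
mixture pbar(d) = (1/n) sum_k P(D_i = d | last-4 history of point k) is
compared with the empirical frequency of the observed d_i(z_k) by Pearson's
statistic. Adjacent distance cells are pooled until every cell has expected
count n*pbar >= 5 (Cochran's rule; `min_expected=0` disables pooling): the
exact support always contains cells of negligible probability, and without
pooling a single observation in such a cell dominates the statistic. The
per-i p-value uses the chi-squared upper tail with (cells - 1) degrees of
freedom; these p-values are only approximately uniform under the null (the n
distance observations are mutually dependent), which is harmless because
significance is always assessed by empirical calibration. The aggregate
statistic is S = -min_i pval_i.

**Extreme-path (location) test.** For every point and neighbour index,
q[k,i] = min(1, 2 min(P(D_i <= d), P(D_i >= d))) is the two-sided discrete
p-value of the observed distance under the exact marginal law of D_i, both
tails including the observed atom (so q > 0 always). Tails are computed in
log space from the survival formula, so the astronomically small values that
strongly dependent samples produce stay finite and ordered. Per-i summaries
are the minima over points; the aggregate is Fisher's combination

    E = - sum_{i=1..i_max} log( min_k q[k,i] ),

which uses the whole neighbour sequence simultaneously. Among the
aggregations examined (single minimum, per-point minima, Stouffer, sums of
path log-likelihoods, one-sided variants), Fisher's combination over per-i
minima had the best power on the benchmark dependencies while remaining a
direct function of the per-i minima; the choice is immaterial for test level
because of calibration.

**Calibration.** Both aggregates have intractable null laws, so rejection
thresholds and p-values are empirical: B independent permutation pairs give
the statistic's null sample; the cutoff is the ceil((1-alpha) B)-th order
statistic, and p-values use the rank-based (r+1)/(B+1) correction (never
exactly zero). `test_independence` wires ranks -> profile -> statistic ->
calibration and records every seed.

## Benchmark construction

Functional dependencies on the unit interval: X ~ U(0,1),
Y = f(X) + N(0, sigma^2), with f one of linear x, quadratic 4(x-1/2)^2,
cubic 128(x-1/3)^3 - 48(x-1/3)^2 - 12(x-1/3), sine sin(4 pi x) (period 0.5),
fourth root x^(1/4), binary step 1{x > 1/2}; the circle is parameterized by a
uniform angle with isotropic Gaussian noise on both coordinates (Y is not a
function of X there). The shape constants are frozen in
`nnindep/_functional_forms.py`.

Dependence strength is the mutual information (nats) of a piecewise-constant
discretization of the model density on an m x m grid (default m = 300; the
linear-kind MI changes by < 0.1% between m = 200 and m = 400). The grid
covers the full support (function range +- 6 sigma; truncated mass < 1e-8),
Gaussian cell masses are integrated with 8-point Gauss-Legendre quadrature
per x-cell (4096 midpoint angles for the circle). The grid MI agrees with
the Kraskov-Stoegbauer-Grassberger estimator on large samples (e.g. circle
sigma = 0.4635: grid 0.0301, KSG 0.031). `calibrate_sigma` finds sigma for a
target MI by geometric bisection (MI is monotone decreasing in sigma);
default tolerance max(1e-4, 1% of the target).

Patchwork copulas: a g x g matrix of nonnegative weights p_ij (normalized to
sum 1) with row sums a_i and column sums b_j defines rectangles
[A_{i-1},A_i] x [B_{j-1},B_j] from the cumulative sums; cell (i,j) gets mass
p_ij spread uniformly. Both marginals are exactly uniform and
MI = sum p_ij log(p_ij / (a_i b_j)). `patchwork_search` draws U(0,1)^kappa
weights, doubling the concentration exponent kappa whenever a batch of
proposals cannot reach the target MI (bounded by log g), and accepts the
first proposal within tolerance (default 0.005, cap 1e5 proposals).

Power protocol: a reference ensemble of independent samples fixes the
(1-alpha) empirical cutoff of each method's statistic; power is the fraction
of dependent test samples beyond it. Reference and test ensembles use
disjoint spawned seed streams. ROC curves pool both ensembles and sweep the
threshold (scikit-learn's roc_curve). Wrapped comparators: Pearson |r|,
distance correlation (biased V-statistic, implemented here), Hoeffding's D
(classical rank formula, implemented here), the KSG mutual-information
estimator (scikit-learn, k = 6), and MIC (optional minepy backend; absent
backends raise MethodUnavailableError, never a silent fallback). The torus
geometry flag affects only the NN-based tests, which always operate on the
rank torus; adapting the comparators' internals to toroidal geometry is out
of scope and a documented asymmetry of the benchmark.

## What the generator does and does not emulate

The synthetic benchmark realizes exactly the stated shapes with homoscedastic
Gaussian noise and exact MI calibration. It does not emulate heteroscedastic
noise, heavy-tailed marginals, tied or discrete data (ties are broken
randomly by the rank transform, as the exact law requires), or
boundary effects of planar (non-toroidal) data. Passing tests therefore
demonstrate correctness of the exact law and calibrated behaviour of the
tests under the model, not performance on any particular real data set.

## Scaled-down validation sizes

The packaged checks use problem sizes chosen so the whole suite runs on a
single CPU in minutes: exhaustive enumeration up to n = 8, Monte-Carlo
validation with 10^5 configurations at n in {20, 50}, null calibration with
200 reference + 200 fresh samples at n = 100, and circle power with 100
test + 100 reference samples of n = 320 at MI targets {0.01, 0.02, 0.03,
0.05}. The benchmark command supports the full 500+500-sample protocol over
the complete MI grid for longer runs. Two statistical fine points: (i) the
null-calibration band is the exact beta-binomial band of the two-stage
protocol (the cutoff is itself an order statistic, which widens the rejection
count's distribution beyond binomial); (ii) power plateaus are judged against
Monte-Carlo noise — an MI target counts as reaching the maximum when its
power estimate is within the 95% two-proportion margin of the maximum
estimate.

## Known limitations

* The chi-squared per-i p-values are heuristic (dependent observations); use
  the calibrated aggregate, not the raw per-i values, for inference.
* The extreme test's E is +inf when a two-sided tail underflows even in log
  space composition (never observed in practice; log-space tails reach
  ~1e-300000 before that).
* Planar data incur toroidal wrap-around bias; restrict to moderate i (the
  default cap helps) or expect reduced power, not level violations — the
  null calibration uses the same geometry.
* `brute_force_distribution` is factorial: n <= 9.
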