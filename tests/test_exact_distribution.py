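import math
from fractions import Fraction

import numpy as np
import pytest

from nnindep.core_geometry import max_distance
from nnindep.exact_distribution import (
    ConditionalTableCache,
    RegionDecomposition,
    brute_force_distribution,
    conditional_distribution,
    count_admissible,
    default_i_max,
    entropy,
    get_cache,
    marginal_distribution,
    marginal_entropies,
    get_marginal_tails,
    monte_carlo_frequency,
    prob_conditional,
    prob_joint,
    prob_marginal,
    prob_marginal_from_joint,
    prob_survival,
    region_r_combinations,
)


def _border_placements(n, d, s, e):
    """Independent brute-force count of placements of e points exactly at
    distance d, with s inside points occupying the first s inner rows/columns
    (which ones is irrelevant by symmetry)."""
    import itertools

    def resid(u):
        return min(u, n - u)

    inner_rows = [r for r in range(1, n) if resid(r) <= d - 1]
    used = set(inner_rows[:s])
    cells = [
        (r, c)
        for r in range(1, n)
        for c in range(1, n)
        if max(resid(r), resid(c)) == d
        and r not in used
        and c not in used
    ]
    count = 0
    for combo in itertools.combinations(cells, e):
        rows = {r for r, _ in combo}
        cols = {c for _, c in combo}
        if len(rows) == e and len(cols) == e:
            count += 1
    return count


class TestRegionR:
    @pytest.mark.parametrize("n,d", [(6, 1), (6, 2), (6, 3), (7, 2), (7, 3), (8, 4)])
    def test_counts_match_border_enumeration(self, n, d):
        a_in = max(0, min(2 * (d - 1), n - 1))
        for s in range(0, a_in + 1):
            for e in range(1, 5):
                ctx = RegionDecomposition(n=n, d=d, s=s, e=e)
                assert region_r_combinations(e, s, ctx) == _border_placements(n, d, s, e)

    def test_more_than_four_border_points_impossible(self):
        ctx = RegionDecomposition(n=20, d=3, s=0, e=5)
        assert region_r_combinations(5, 0, ctx) == 0

    def test_degenerate_flag_at_even_antipode(self):
        assert RegionDecomposition(n=8, d=4, s=0, e=1).degenerate
        assert not RegionDecomposition(n=8, d=3, s=0, e=1).degenerate


class TestCountAdmissible:
    def test_n4_examples(self):
        assert count_admissible([1], 4) == 6
        assert count_admissible([1, 1], 4) == 2
        assert count_admissible([1, 2], 4) == 4

    def test_inadmissible_prefixes(self):
        assert count_admissible([2, 1], 6) == 0          # decreasing
        assert count_admissible([1] * 5, 12) == 0         # run longer than 4
        assert count_admissible([4], 6) == 0              # beyond max distance

    def test_empty_prefix_counts_everything(self):
        assert count_admissible([], 6) == math.factorial(5)


class TestJointLaw:
    def test_n3_and_n4_probabilities(self):
        assert prob_joint([1, 1], 3) == pytest.approx(1.0, abs=1e-14)
        assert prob_joint([1, 1], 4) == pytest.approx(1 / 3, abs=1e-14)
        assert prob_joint([1, 2], 4) == pytest.approx(2 / 3, abs=1e-14)

    @pytest.mark.parametrize("n", [5, 6])
    def test_total_probability_over_full_sequences(self, n, bf_laws):
        total = sum(prob_joint(list(seq), n) for seq in bf_laws[n].law)
        assert total == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("n", [5, 6, 7])
    def test_matches_enumeration_exactly(self, n, bf_laws):
        bf = bf_laws[n]
        prefixes = {seq[:L] for seq in bf.law for L in range(1, n)}
        for p in prefixes:
            truth = float(bf.prefix_probability(p))
            assert prob_joint(list(p), n) == pytest.approx(truth, abs=1e-12)

    def test_exact_integer_and_log_paths_agree(self, bf_laws):
        n = 8
        for seq in list(bf_laws[n].law)[:40]:
            for L in (1, 3, 7):
                exact = Fraction(count_admissible(list(seq[:L]), n), math.factorial(n - 1))
                assert prob_joint(list(seq[:L]), n) == pytest.approx(float(exact), abs=1e-13)


class TestSurvivalAndMarginal:
    def test_cdf_reaches_one_at_max_distance(self):
        for n in (4, 9, 20):
            for i in (1, 2, n - 1):
                assert prob_survival(max_distance(n), i, n) == 1.0

    def test_n4_first_neighbour_always_at_distance_one(self):
        assert prob_survival(1, 1, 4) == pytest.approx(1.0, abs=1e-14)

    def test_cdf_matches_enumeration(self, bf_laws):
        n = 6
        bf = bf_laws[n]
        for i in range(1, n):
            marg = bf.marginal(i)
            for d in range(1, max_distance(n) + 1):
                truth = float(sum(p for v, p in marg.items() if v <= d))
                assert prob_survival(d, i, n) == pytest.approx(truth, abs=1e-12)

    def test_n4_n3_marginals(self):
        assert prob_marginal(2, 1, 4) == pytest.approx(1 / 3, abs=1e-14)
        assert prob_marginal(2, 2, 4) == pytest.approx(2 / 3, abs=1e-14)
        assert prob_marginal(3, 2, 4) == pytest.approx(1.0, abs=1e-14)
        assert prob_marginal(1, 1, 3) == pytest.approx(1.0, abs=1e-14)

    @pytest.mark.parametrize("n", [5, 17, 50])
    def test_marginals_normalized(self, n):
        for i in (1, 2, n // 2, n - 1):
            total = sum(prob_marginal(i, d, n) for d in range(1, max_distance(n) + 1))
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_two_marginal_routes_agree(self):
        # survival differences vs summation of joint prefixes
        n = 7
        for i in (1, 2, 3):
            for d in range(1, max_distance(n) + 1):
                assert prob_marginal(i, d, n) == pytest.approx(
                    prob_marginal_from_joint(i, d, n), abs=1e-10
                )

    def test_marginal_tails_match_survival(self):
        n = 30
        tails = get_marginal_tails(n)
        for i in (1, 5, 20):
            for d in (1, 5, 10, 15):
                assert np.exp(tails.log_le[i, d]) == pytest.approx(
                    prob_survival(d, i, n), abs=1e-12
                )
                ge = 1.0 - prob_survival(d - 1, i, n)
                assert np.exp(tails.log_ge[i - 1, d - 1]) == pytest.approx(ge, abs=1e-12)


class TestConditional:
    def test_n4_example(self):
        assert prob_conditional(2, [1], 4) == pytest.approx(2 / 3, abs=1e-14)

    def test_distances_cannot_decrease(self):
        dist = conditional_distribution([2, 2], 9)
        assert dist.prob(1) == 0.0

    def test_tables_sum_to_one(self):
        for n in (8, 13, 24):
            for hist in ([1], [1, 1], [2, 3], [1, 2, 2]):
                dist = conditional_distribution(hist, n)
                assert np.exp(dist.logp).sum() == pytest.approx(1.0, abs=1e-10)

    def test_zero_probability_history_rejected(self):
        with pytest.raises(ValueError, match="probability zero"):
            conditional_distribution([1, 1, 1, 1, 1], 20)

    def test_matches_enumeration(self, bf_laws):
        n = 7
        bf = bf_laws[n]
        for L in range(1, n - 1):
            for h in bf.histories(L):
                truth = bf.conditional(h)
                dist = conditional_distribution(h, n)
                for d in dist.support:
                    assert dist.prob(int(d)) == pytest.approx(
                        float(truth.get(int(d), Fraction(0))), abs=1e-12
                    )

    def test_chain_rule(self, bf_laws):
        n = 7
        for seq in list(bf_laws[n].law)[:25]:
            prod = 1.0
            for L in range(1, 5):
                prod *= prob_conditional(seq[L - 1], list(seq[: L - 1]), n)
            assert prod == pytest.approx(prob_joint(list(seq[:4]), n), abs=1e-12)

    def test_markov_last_four_suffices(self, bf_laws):
        # light version at n=7; the n=8 exhaustive check lives in acceptance.
        # Same-length histories sharing their last four entries must have
        # identical conditional next-distance laws.
        n = 7
        bf = bf_laws[n]
        for L in (4, 5):
            groups = {}
            for h in bf.histories(L):
                groups.setdefault(h[-4:], []).append(h)
            for suffix, hs in groups.items():
                laws = [bf.conditional(h) for h in hs if len(h) < n - 1]
                for other in laws[1:]:
                    assert other == laws[0]

    def test_numerically_stable_at_large_n(self):
        n = 2000
        dist = conditional_distribution([3, 5, 5], n)
        p = np.exp(dist.logp)
        assert np.isfinite(dist.logp[p > 0]).all()
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        marg = marginal_distribution(4, n)
        assert marg.probs.sum() == pytest.approx(1.0, abs=1e-9)


class TestEntropyAndIMax:
    def test_point_mass_zero(self):
        dist = marginal_distribution(2, 3)  # D_2 on the 3-torus is surely 1
        assert entropy(dist) == pytest.approx(0.0, abs=1e-14)

    def test_uniform_log_m(self):
        from nnindep.exact_distribution import ExactDistribution

        m = 7
        dist = ExactDistribution(
            n=100, i=1, conditioning=(),
            support=np.arange(1, m + 1), logp=np.full(m, -np.log(m)),
        )
        assert entropy(dist) == pytest.approx(np.log(m), abs=1e-12)

    def test_entropy_tail_nonmonotone_at_n320(self):
        H = marginal_entropies(320)
        im = default_i_max(320)
        assert im < 319  # well below n-1: the tail entropies rise again
        peak = int(np.argmax(H))
        assert (np.diff(H[peak:im]) <= 1e-9).all()  # nonincreasing up to i_max
        assert H[im] > H[im - 1]  # and then it rises: first local minimum
        # non-monotone tail behaviour near the maximal index
        tail = H[250:319]
        assert (np.diff(tail) > 1e-6).any()

    def test_default_i_max_range(self):
        for n in (4, 10, 50):
            v = default_i_max(n)
            assert 1 <= v <= n - 1


class TestOracles:
    def test_bruteforce_total_mass_and_small_laws(self, bf_laws):
        assert bf_laws[3].law == {(1, 1): Fraction(1)}
        assert bf_laws[4].marginal(1) == {1: Fraction(1)}
        assert bf_laws[4].marginal(2) == {1: Fraction(1, 3), 2: Fraction(2, 3)}
        for n, bf in bf_laws.items():
            assert sum(bf.law.values()) == 1

    def test_bruteforce_rejects_large_n(self):
        with pytest.raises(ValueError, match="monte_carlo"):
            brute_force_distribution(10)

    def test_monte_carlo_reproducible_and_normalized(self):
        a = monte_carlo_frequency(12, 2, reps=2000, seed=3)
        b = monte_carlo_frequency(12, 2, reps=2000, seed=3)
        assert a == b
        assert sum(a.values()) == pytest.approx(1.0, abs=1e-12)

    def test_monte_carlo_matches_marginal(self):
        n, i, reps = 20, 3, 30000
        freq = monte_carlo_frequency(n, i, reps=reps, seed=11)
        for d in range(1, max_distance(n) + 1):
            p = prob_marginal(i, d, n)
            se = math.sqrt(max(p * (1 - p), 1e-12) / reps)
            assert abs(freq.get(d, 0.0) - p) < 4 * se + 1e-9


class TestConditionalCache:
    def test_cache_transparent(self):
        cold = ConditionalTableCache(15)
        warm = get_cache(15)
        for key in [(0, 0, 0), (0, 2, 1), (1, 3, 2)]:
            a = cold.get(*key)
            b = warm.get(*key)
            b2 = warm.get(*key)  # cached second read
            assert np.array_equal(a[0], b[0])
            assert np.allclose(a[1], b[1], atol=0, equal_nan=True)
            assert b2 is b

    def test_save_load_roundtrip(self, tmp_path):
        cache = ConditionalTableCache(12)
        cache.get(0, 0, 0)
        cache.get(1, 2, 1)
        path = tmp_path / "tables.json"
        cache.save(path)
        loaded = ConditionalTableCache.load(path)
        assert loaded.n == 12
        for key, (sup, logp, *_) in cache._tables.items():
            sup2, logp2, *_ = loaded._tables[key]
            assert np.array_equal(sup, sup2)
            assert np.allclose(logp, logp2, equal_nan=True)
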