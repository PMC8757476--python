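import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats as sps

from fmtengraft.stats import (ContingencyTable, GroupSummary,
                              anova_oneway_summary, dunn_posttest,
                              fisher_exact, kruskal_wallis, mann_whitney_u,
                              t_test_summary, tukey_hsd)


def raw_with_summary(rng, n, mean, sd):
    """Construct raw data whose sample mean and sd match exactly."""
    x = rng.standard_normal(n)
    x = (x - x.mean()) / x.std(ddof=1)
    return x * sd + mean


class TestAnovaFromSummaries:
    def test_equals_raw_data_anova(self):
        rng = np.random.default_rng(0)
        specs = [(8, 1.2, 0.7), (12, -0.3, 1.5), (6, 2.0, 0.4)]
        raw = [raw_with_summary(rng, *s) for s in specs]
        groups = [GroupSummary(f"g{i}", *s) for i, s in enumerate(specs)]
        f_sum, p_sum = anova_oneway_summary(groups)
        f_raw, p_raw = sps.f_oneway(*raw)
        assert f_sum == pytest.approx(f_raw, abs=1e-10)
        assert p_sum == pytest.approx(p_raw, abs=1e-10)

    def test_identical_means_give_null(self):
        groups = [GroupSummary(l, 5, 1.0, 0.5) for l in "abc"]
        f, p = anova_oneway_summary(groups)
        assert f == 0.0 and p == 1.0

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            GroupSummary("tiny", 1, 0.0, 1.0)


class TestTTestFromSummaries:
    def test_matches_scipy_from_stats(self):
        a = GroupSummary("a", 9, 1.4, 0.8)
        b = GroupSummary("b", 14, 0.9, 1.1)
        for variant, equal_var in (("pooled", True), ("welch", False)):
            t, p = t_test_summary(a, b, variant)
            t_ref, p_ref = sps.ttest_ind_from_stats(
                a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=equal_var)
            assert t == pytest.approx(t_ref, abs=1e-12)
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_identical_summaries_null(self):
        a = GroupSummary("a", 5, 2.0, 1.0)
        assert t_test_summary(a, a) == (0.0, pytest.approx(1.0))

    def test_zero_variance_equal_means_flagged_as_null(self):
        a = GroupSummary("a", 5, 2.0, 0.0)
        b = GroupSummary("b", 7, 2.0, 0.0)
        assert t_test_summary(a, b) == (0.0, 1.0)


class TestKruskalWallis:
    def test_identical_multisets_null(self):
        g = [1.0, 2.0, 3.0]
        h, p = kruskal_wallis([g, g, g])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_exact_permutation_matches_brute_force(self):
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        h, p = kruskal_wallis(groups, exact_max_n=9)
        # independent oracle: scipy H over every multiset-distinct assignment
        pooled = np.array([v for g in groups for v in g], dtype=float)
        h_obs = sps.kruskal(*groups).statistic
        count = total = 0
        for combo1 in itertools.combinations(range(9), 3):
            rest = [i for i in range(9) if i not in combo1]
            for combo2 in itertools.combinations(rest, 3):
                combo3 = [i for i in rest if i not in combo2]
                parts = [pooled[list(combo1)], pooled[list(combo2)],
                         pooled[combo3]]
                if sps.kruskal(*parts).statistic >= h_obs - 1e-12:
                    count += 1
                total += 1
        assert total == 1680
        assert p == pytest.approx(count / total)
        assert h == pytest.approx(7.2)

    def test_two_groups_approaches_mann_whitney(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 40), rng.normal(0.5, 1, 40)
        _, p_kw = kruskal_wallis([a, b])
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
        assert p_kw == pytest.approx(res.pvalue, rel=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])


class TestDunnPosttest:
    def test_identical_groups_all_null(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = dunn_posttest([g, g, g])
        for z, p in res.values():
            assert z == pytest.approx(0.0, abs=1e-12)
            assert p == pytest.approx(1.0)

    def test_z_magnitudes_track_rank_gaps(self):
        groups = [list(range(1, 6)), list(range(11, 16)), list(range(21, 26))]
        res = dunn_posttest(groups, labels=["lo", "mid", "hi"])
        assert abs(res[("lo", "hi")][0]) > abs(res[("lo", "mid")][0])
        assert abs(res[("lo", "hi")][0]) > abs(res[("mid", "hi")][0])
        assert res[("lo", "mid")][0] < 0  # lower ranks in the first group

    def test_two_identical_of_three_groups(self):
        g = [3.0, 1.0, 2.0]
        res = dunn_posttest([g, list(g), [10.0, 11.0, 12.0]],
                            labels=["a", "b", "c"])
        assert res[("a", "b")][0] == pytest.approx(0.0, abs=1e-12)
        assert res[("a", "b")][1] == pytest.approx(1.0)

    def test_bonferroni_scales_p(self):
        groups = [[1, 2, 3], [2, 3, 4], [8, 9, 10]]
        plain = dunn_posttest(groups)
        adj = dunn_posttest(groups, adjust="bonferroni")
        for pair in plain:
            assert adj[pair][1] == pytest.approx(min(1.0, plain[pair][1] * 3))

    def test_needs_three_groups(self):
        with pytest.raises(ValueError):
            dunn_posttest([[1, 2], [3, 4]])


class TestMannWhitney:
    def test_identical_multisets_near_one(self):
        u, p = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert p > 0.9

    def test_exact_small_sample(self):
        # complete separation of 3 vs 3: 2 of 20 orderings per tail
        _, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_normal_approximation_close_to_exact_at_n8(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 8)
        b = rng.normal(0.8, 1, 8)
        _, p_exact = mann_whitney_u(list(a), list(b))
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic")
        assert abs(p_exact - res.pvalue) < 0.01


def fisher_oracle_rational(cells):
    """Freeman-Halton by exact rational enumeration (independent route)."""
    arr = np.asarray(cells, dtype=int)
    rows, cols = arr.sum(axis=1), arr.sum(axis=0)
    n = arr.sum()

    def prob(t):
        num = Fraction(1)
        for r in rows:
            num *= math.factorial(int(r))
        for c in cols:
            num *= math.factorial(int(c))
        den = Fraction(math.factorial(int(n)))
        for x in np.asarray(t).flat:
            den *= math.factorial(int(x))
        return num / den

    p_obs = prob(arr)
    total = Fraction(0)
    ranges = [range(min(int(rows[0]), int(c)) + 1) for c in cols]
    # enumerate all tables with matching margins (small n only)
    def rec(i, built):
        nonlocal total
        if i == len(rows) - 1:
            last = cols - np.sum(built, axis=0) if built else cols
            if (last >= 0).all():
                t = np.vstack(built + [last]) if built else last[None]
                if prob(t) <= p_obs:
                    total += prob(t)
            return
        r = int(rows[i])
        rem_cols = cols - (np.sum(built, axis=0) if built else 0)
        for combo in itertools.product(*[range(min(r, int(c)) + 1) for c in rem_cols]):
            if sum(combo) == r:
                rec(i + 1, built + [np.array(combo)])
    rec(0, [])
    return float(total)


class TestFisherExact:
    def test_proportional_rows_independent(self):
        assert fisher_exact([[2, 4], [3, 6]]) == pytest.approx(1.0)
        assert fisher_exact([[1, 2, 3], [2, 4, 6]]) == pytest.approx(1.0)

    def test_2x2_matches_scipy_convention(self):
        table = [[10, 2], [3, 9]]
        assert fisher_exact(table) == pytest.approx(
            sps.fisher_exact(table)[1])

    def test_rxc_matches_rational_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(15):
            shape = rng.choice([2, 3]), rng.choice([2, 3, 4])
            cells = rng.integers(0, 4, size=shape)
            if cells.sum() == 0 or (cells.sum(0) == 0).any() \
                    or (cells.sum(1) == 0).any() or cells.shape == (2, 2):
                continue
            assert fisher_exact(cells) == pytest.approx(
                fisher_oracle_rational(cells), abs=1e-9)

    def test_monte_carlo_close_to_exact(self):
        cells = [[2, 4, 4], [6, 5, 3]]
        exact = fisher_exact(cells)
        mc = fisher_exact(cells, max_tables=1, monte_carlo=20000, seed=0)
        assert abs(mc - exact) < 0.02

    def test_oversized_margins_without_mc_raise(self):
        big = np.full((4, 4), 50)
        with pytest.raises(ValueError, match="monte_carlo"):
            fisher_exact(big, max_tables=10)

    def test_validation(self):
        with pytest.raises(ValueError):
            ContingencyTable.from_array([[1, -1], [0, 2]])
        with pytest.raises(ValueError):
            ContingencyTable.from_array([[1, 2]])


class TestTukeyHsd:
    def test_identical_groups_null(self):
        g = [1.0, 2.0, 3.0, 4.0]
        for p in tukey_hsd([g, list(g), list(g)]).values():
            assert p == pytest.approx(1.0)

    def test_outlying_group_has_smallest_p(self):
        groups = [[1, 2, 3], [1.5, 2.5, 3.5], [40, 41, 42]]
        res = tukey_hsd(groups, labels=["a", "b", "c"])
        assert res[("a", "c")] < res[("a", "b")]
        assert res[("b", "c")] < res[("a", "b")]

    def test_two_groups_reduce_to_pooled_t(self):
        g1 = [1.0, 2.0, 3.5, 2.2]
        g2 = [2.9, 3.8, 4.4, 5.0]
        p_tukey = tukey_hsd([g1, g2])[("group0", "group1")]
        _, p_t = t_test_summary(GroupSummary.from_values("a", g1),
                                GroupSummary.from_values("b", g2))
        assert p_tukey == pytest.approx(p_t, abs=1e-9)
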