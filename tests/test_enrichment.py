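import itertools

import numpy as np
import pytest
from scipy import stats

from aggregome.enrichment import (
    ContingencyTable2x2,
    build_membership_table,
    chi_square,
    dunn_posthoc,
    kruskal_wallis,
    ttest_bonferroni,
    wilcoxon_signed_rank,
)


def _chi2_closed_form(a, b, c, d):
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


class TestMembershipTable:
    def test_counting(self):
        t = build_membership_table({"A", "B"}, {"A"}, {"C", "D"})
        assert (t.a, t.b, t.c, t.d) == (1, 1, 0, 2)

    def test_universal_annotation(self):
        t = build_membership_table({"A"}, {"A", "B", "C"}, {"B", "C"})
        assert t.b == 0 and t.d == 0

    def test_empty_annotation(self):
        t = build_membership_table({"A"}, set(), {"B"})
        assert t.a == 0 and t.c == 0

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            build_membership_table({"A"}, set(), {"A", "B"})


class TestChiSquare:
    def test_closed_form_value(self):
        res = chi_square(ContingencyTable2x2(10, 90, 30, 70))
        assert res["statistic"] == pytest.approx(12.5, abs=1e-9)
        assert res["df"] == 1

    def test_equal_proportions(self):
        res = chi_square(ContingencyTable2x2(20, 80, 20, 80))
        assert res["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_row_swap_symmetry(self):
        one = chi_square(ContingencyTable2x2(7, 13, 21, 9))
        two = chi_square(ContingencyTable2x2(21, 9, 7, 13))
        assert one["statistic"] == pytest.approx(two["statistic"])

    def test_zero_margin_recommends_exact_test(self):
        with pytest.raises(ValueError, match="exact"):
            chi_square(ContingencyTable2x2(0, 5, 0, 7))

    def test_matches_closed_form_on_random_tables(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(1, 200, size=4)
            res = chi_square(ContingencyTable2x2(int(a), int(b), int(c), int(d)))
            assert res["statistic"] == pytest.approx(
                _chi2_closed_form(a, b, c, d), abs=1e-9, rel=1e-9
            )

    def test_null_p_values_calibrated(self, rng):
        # random annotation of fixed size over a fixed fraction/background
        # split.  The exact null of a 2x2 table is discrete, so uniformity
        # is checked at a replicate count below the KS resolution of that
        # discreteness, together with the rejection rate at alpha = 0.05.
        ps = []
        universe = np.arange(4000)
        for _ in range(1000):
            members = set(rng.choice(universe, size=800, replace=False).tolist())
            a = sum(1 for i in range(1000) if i in members)
            c = len(members) - a
            ps.append(chi_square(ContingencyTable2x2(a, 1000 - a, c, 3000 - c))["p"])
        ps = np.asarray(ps)
        for alpha in (0.01, 0.05, 0.1, 0.2):
            tol = 3 * np.sqrt(alpha * (1 - alpha) / ps.size) + 0.01
            assert np.mean(ps < alpha) == pytest.approx(alpha, abs=tol)


def _kw_bruteforce(groups):
    values = np.concatenate(list(groups.values()))
    ranks = stats.rankdata(values)
    n = values.size
    out = 0.0
    start = 0
    for vals in groups.values():
        ri = ranks[start : start + len(vals)].mean()
        out += len(vals) * (ri - (n + 1) / 2) ** 2
        start += len(vals)
    h = 12.0 / (n * (n + 1)) * out
    _, t = np.unique(values, return_counts=True)
    correction = 1.0 - np.sum(t**3 - t) / (n**3 - n)
    return h / correction


class TestKruskalWallis:
    def test_identical_observations(self):
        res = kruskal_wallis({"a": [2, 2], "b": [2, 2, 2]})
        assert res["H"] == 0.0 and res["p"] == 1.0

    def test_matches_manual_ranks(self):
        groups = {"lo": [1.0, 2.0, 3.0], "hi": [4.0, 5.0, 6.0]}
        res = kruskal_wallis(groups)
        assert res["H"] == pytest.approx(_kw_bruteforce(groups), abs=1e-12)

    def test_group_order_invariance(self, rng):
        groups = {k: rng.normal(size=7).tolist() for k in "abc"}
        h1 = kruskal_wallis(groups)["H"]
        h2 = kruskal_wallis(dict(reversed(groups.items())))["H"]
        assert h1 == pytest.approx(h2)

    def test_ties_against_bruteforce(self, rng):
        groups = {k: rng.integers(0, 4, size=10).astype(float).tolist() for k in "abc"}
        assert kruskal_wallis(groups)["H"] == pytest.approx(_kw_bruteforce(groups), abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis({"a": [1.0], "b": []})


class TestDunn:
    def test_two_groups_no_adjustment(self):
        out = dunn_posthoc({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert len(out) == 1
        assert out.loc[0, "p_adjusted"] == pytest.approx(out.loc[0, "p_raw"])

    def test_identical_groups_zero_z(self):
        out = dunn_posthoc({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        np.testing.assert_allclose(out["z"], 0.0)

    def test_hand_computed_three_groups(self):
        groups = {"a": [1.0, 2.0], "b": [3.0, 4.0], "c": [5.0, 6.0]}
        # pooled ranks 1..6, no ties: mean ranks 1.5, 3.5, 5.5
        # var = (N(N+1)/12)(1/2 + 1/2) = 3.5; z_ab = -2/sqrt(3.5)
        out = dunn_posthoc(groups).set_index(["group_a", "group_b"])
        assert out.loc[("a", "b"), "z"] == pytest.approx(-2 / np.sqrt(3.5))
        assert out.loc[("a", "c"), "z"] == pytest.approx(-4 / np.sqrt(3.5))
        expected_p = 2 * stats.norm.sf(2 / np.sqrt(3.5))
        assert out.loc[("a", "b"), "p_adjusted"] == pytest.approx(min(1, 3 * expected_p))

    def test_adjusted_at_least_raw_and_bounded(self, rng):
        groups = {k: rng.normal(size=9).tolist() for k in "abcd"}
        out = dunn_posthoc(groups)
        assert ((out["p_adjusted"] >= out["p_raw"] - 1e-15) & (out["p_adjusted"] <= 1)).all()


def _wilcoxon_enumeration(a, b):
    """Oracle: exact distribution by brute force over all sign vectors."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    stats_all = [
        np.sum(ranks[np.array(signs, dtype=bool)]) if any(signs) else 0.0
        for signs in itertools.product([0, 1], repeat=n)
    ]
    stats_all = np.array(stats_all)
    p_le = np.mean(stats_all <= w_obs + 1e-12)
    p_ge = np.mean(stats_all >= w_obs - 1e-12)
    return w_obs, min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxon:
    def test_identical_pairs(self):
        with pytest.warns(UserWarning):
            res = wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])
        assert res["p"] == 1.0

    def test_five_positive_differences(self):
        res = wilcoxon_signed_rank([2, 3, 4, 5, 6], [1, 2, 3, 4, 5])
        assert res["p"] == pytest.approx(2 / 32)

    def test_matches_enumeration_oracle(self, rng):
        for n in range(2, 11):
            for _ in range(5):
                a = rng.integers(0, 6, size=n).astype(float)
                b = rng.integers(0, 6, size=n).astype(float)
                if np.all(a == b):
                    continue
                w, p = _wilcoxon_enumeration(a, b)
                res = wilcoxon_signed_rank(a, b)
                assert res["statistic"] == pytest.approx(w)
                assert res["p"] == pytest.approx(p, abs=1e-12)

    def test_normal_approximation_for_large_n(self, rng):
        a = rng.normal(0.5, 1, 60)
        b = rng.normal(0.0, 1, 60)
        res = wilcoxon_signed_rank(a, b)
        ref = stats.wilcoxon(a, b, correction=False, mode="approx")
        assert res["p"] == pytest.approx(ref.pvalue, rel=1e-9)


class TestTTestBonferroni:
    def test_single_comparison_unadjusted(self, rng):
        groups = {"a": rng.normal(size=5), "b": rng.normal(1, 1, 5)}
        out = ttest_bonferroni(groups, [("a", "b")])
        assert out.loc[0, "p_adjusted"] == pytest.approx(out.loc[0, "p_raw"])

    def test_clipping(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [1.5, 2.5, 3.5], "c": [1.0, 2.0, 4.0]}
        out = ttest_bonferroni(groups, [("a", "b"), ("a", "c"), ("b", "c")])
        assert (out["p_adjusted"] <= 1.0).all()

    def test_identical_groups(self):
        out = ttest_bonferroni({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}, [("a", "b")])
        assert out.loc[0, "t"] == 0.0 and out.loc[0, "p_raw"] == 1.0
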