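"""The inferential primitives against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from icbkit import stats as ics


def _brute_force_mwu_p(a, b):
    """Exact two-sided p (2 * lower-tail of U) by enumerating every
    group labelling."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}

    def u1_of(idx):
        r1 = sum(ranks[pooled[i]] for i in idx)
        return r1 - n1 * (n1 + 1) / 2

    obs = u1_of(range(n1))
    obs_min = min(obs, n1 * len(b) - obs)
    total = lower = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if u1_of(idx) <= obs_min:
            lower += 1
    return min(1.0, 2 * lower / total)


class TestMannWhitney:
    def test_separated_samples_exact_p(self):
        res = ics.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.pvalue == pytest.approx(0.1)
        assert res.extra["method"] == "exact"

    def test_identical_samples_p_one(self):
        res = ics.mann_whitney_u([5, 5, 5], [5, 5, 5])
        assert res.pvalue == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=5)
        b = rng.normal(size=6)
        res = ics.mann_whitney_u(a, b, mode="exact")
        assert res.pvalue == pytest.approx(_brute_force_mwu_p(a, b), abs=1e-12)

    def test_approx_close_to_exact(self):
        rng = np.random.default_rng(7)
        gaps = []
        for _ in range(100):
            a = rng.normal(size=8)
            b = rng.normal(size=8)
            pe = ics.mann_whitney_u(a, b, mode="exact").pvalue
            pa = ics.mann_whitney_u(a, b, mode="approx").pvalue
            gaps.append(abs(pe - pa))
        assert np.mean(gaps) < 0.01
        assert max(gaps) < 0.03

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=7)
        b = rng.normal(size=9) + 0.5
        p1 = ics.mann_whitney_u(a, b).pvalue
        p2 = ics.mann_whitney_u(np.exp(a), np.exp(b)).pvalue
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestTwoFactorAnova:
    @staticmethod
    def _statsmodels_type3(y, fa, fb):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        df = pd.DataFrame({"y": y, "A": fa, "B": fb})
        fit = smf.ols("y ~ C(A, Sum)*C(B, Sum)", df).fit()
        return sm.stats.anova_lm(fit, typ=3)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_type3_oracle_unbalanced(self, seed):
        rng = np.random.default_rng(seed)
        n = 46
        fa = rng.choice(["saline", "LD24", "R2.5", "combo"], n)
        fb = rng.choice(["sham", "lesion"], n)
        y = rng.normal(size=n) + (fb == "lesion") * 0.7
        res = ics.two_factor_anova(y, fa, fb)
        tab = self._statsmodels_type3(y, fa, fb)
        pairs = {
            "A": "C(A, Sum)",
            "B": "C(B, Sum)",
            "A:B": "C(A, Sum):C(B, Sum)",
        }
        for key, row in pairs.items():
            assert res[key].statistic == pytest.approx(tab.loc[row, "F"], rel=1e-8)
            assert res[key].pvalue == pytest.approx(tab.loc[row, "PR(>F)"], rel=1e-8)

    def test_flat_data_f_near_zero(self):
        fa = ["a", "a", "b", "b"] * 4
        fb = ["x", "y"] * 8
        y = np.ones(16) + np.tile([0, 1e-9], 8)
        res = ics.two_factor_anova(y, fa, fb)
        assert res["A"].pvalue > 0.9
        assert res["B"].pvalue >= 0.0

    def test_additive_data_no_interaction(self):
        fa = np.repeat(["a", "b"], 8)
        fb = np.tile(["x", "y"], 8)
        y = (fa == "b") * 2.0 + (fb == "y") * 3.0
        res = ics.two_factor_anova(y, fa, fb)
        assert res["A:B"].statistic == pytest.approx(0.0, abs=1e-18)

    def test_empty_cell_named(self):
        fa = ["a", "a", "b", "b"]
        fb = ["x", "y", "x", "x"]
        with pytest.raises(ValueError, match="A='b', B='y'"):
            ics.two_factor_anova([1.0, 2.0, 3.0, 4.0], fa, fb)


class TestTukey:
    def test_matches_statsmodels(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(3)
        y = rng.normal(size=48)
        g = rng.choice(list("abcd"), 48)
        mine = ics.tukey_hsd(y, g)
        ref = pairwise_tukeyhsd(y, g)
        assert np.allclose(mine["p_adj"].to_numpy(), ref.pvalues, atol=1e-6)

    def test_identical_groups_p_near_one(self):
        y = np.concatenate([np.arange(8.0), np.arange(8.0)])
        g = ["a"] * 8 + ["b"] * 8
        assert ics.tukey_hsd(y, g)["p_adj"].iloc[0] > 0.999

    def test_shifted_group_flagged(self):
        rng = np.random.default_rng(4)
        flagged = 0
        for _ in range(20):
            y = rng.normal(size=40)
            y[:10] += 5.0  # one group shifted by 5 sigma
            g = np.repeat(list("abcd"), 10)
            tab = ics.tukey_hsd(y, g)
            involves_a = (tab["group1"] == "a") | (tab["group2"] == "a")
            if (tab.loc[involves_a, "p_adj"] < 0.05).all() and (
                tab.loc[~involves_a, "p_adj"] > 0.05
            ).all():
                flagged += 1
        assert flagged >= 18

    def test_pooling_rule_branch(self):
        rng = np.random.default_rng(5)
        tr = np.repeat(["a", "b", "c", "d"], 12)
        le = np.tile(["sham", "les"], 24)
        y = rng.normal(size=48) + (tr == "b") * 3.0
        res = ics.posthoc_with_pooling(y, tr, le)
        assert res["pooled"] is True
        assert set(res["contrasts"]) == {"pooled"}
        y2 = y + (le == "les") * 4.0
        res2 = ics.posthoc_with_pooling(y2, tr, le)
        assert res2["pooled"] is False
        assert set(res2["contrasts"]) == {"les", "sham"}


class TestKruskalDunn:
    def test_matches_scipy_with_ties(self):
        from scipy.stats import kruskal

        rng = np.random.default_rng(6)
        groups = [np.round(rng.normal(size=n), 1) for n in (7, 9, 8)]
        mine = ics.kruskal_wallis(groups)
        ref = kruskal(*groups)
        assert mine.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert mine.pvalue == pytest.approx(ref.pvalue, rel=1e-10)

    def test_all_equal_data(self):
        res = ics.kruskal_wallis([[2.0, 2.0], [2.0, 2.0], [2.0]])
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_dunn_z_hand_computed(self):
        # groups {1,2}, {3,4}: mean ranks 1.5 and 3.5, no ties
        tab = ics.dunn_posthoc([[1, 2], [3, 4]], adjust="none")
        n = 4
        se = np.sqrt(n * (n + 1) / 12 * (1 / 2 + 1 / 2))
        assert tab["z"].iloc[0] == pytest.approx(-2.0 / se)

    def test_dunn_shifted_group_smallest_p(self):
        rng = np.random.default_rng(8)
        groups = [rng.normal(size=12), rng.normal(size=12), rng.normal(size=12) + 4]
        tab = ics.dunn_posthoc(groups, labels=["a", "b", "c"])
        worst = tab.sort_values("p_adj").iloc[-1]
        assert {worst["group1"], worst["group2"]} == {"a", "b"}


class TestBenjaminiHochberg:
    def test_step_up_by_hand(self):
        cutoff, mask = ics.bh_adjust([0.001, 0.02, 0.03, 0.5], alpha=0.05)
        assert cutoff == pytest.approx(0.03)
        assert mask.tolist() == [True, True, True, False]

    def test_all_ones_no_rejections(self):
        cutoff, mask = ics.bh_adjust(np.ones(10), alpha=0.05)
        assert cutoff == 0.0 and not mask.any()

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=60) ** 3
        _, mask = ics.bh_adjust(p, 0.05)
        ref = multipletests(p, 0.05, "fdr_bh")[0]
        assert (mask == ref).all()
        q = ics.bh_qvalues(p)
        ref_q = multipletests(p, 0.05, "fdr_bh")[1]
        assert np.allclose(q, ref_q)

    def test_null_uniform_fdr_controlled(self):
        rng = np.random.default_rng(9)
        fdrs = []
        for _ in range(200):
            p = rng.uniform(size=100)
            _, mask = ics.bh_adjust(p, alpha=0.1)
            fdrs.append(mask.mean())
        assert np.mean(fdrs) <= 0.1

    @given(st.integers(0, 500))
    @settings(max_examples=25, deadline=None)
    def test_rejections_shrink_with_alpha(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=30) ** 2
        _, strict = ics.bh_adjust(p, 0.01)
        _, lax = ics.bh_adjust(p, 0.10)
        assert strict.sum() <= lax.sum()


def test_order_invariance(rng):
    a = rng.normal(size=15)
    b = rng.normal(size=12)
    perm = rng.permutation(15)
    assert ics.mann_whitney_u(a, b).pvalue == pytest.approx(
        ics.mann_whitney_u(a[perm], b).pvalue
    )
    g = [a, b]
    assert ics.kruskal_wallis(g).pvalue == pytest.approx(
        ics.kruskal_wallis([a[perm], b]).pvalue
    )
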