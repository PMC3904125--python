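import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as sps

from peristartle import stats as st
from peristartle.errors import DegenerateDataError, InputError


# --- independent oracles ----------------------------------------------

def brute_force_mwu_p(a, b):
    """Two-sided exact Mann-Whitney p from first principles: enumerate
    every assignment of the pooled values to groups of sizes (n_a, n_b)
    and count pairwise wins (ties worth 1/2)."""
    def u_stat(x, y):
        return sum(1.0 if xi > yi else (0.5 if xi == yi else 0.0)
                   for xi in x for yi in y)

    pooled = list(a) + list(b)
    n, n1 = len(pooled), len(a)
    u_obs = u_stat(a, b)
    us = []
    for idx in itertools.combinations(range(n), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(n) if i not in idx]
        us.append(u_stat(ga, gb))
    us = np.array(us)
    p = 2 * min((us <= u_obs + 1e-9).mean(), (us >= u_obs - 1e-9).mean())
    return min(1.0, p)


def rm_anova_F_by_hand(matrix):
    """Within-subject one-way ANOVA F from explicit sums of squares."""
    m = np.asarray(matrix, float)
    n, k = m.shape
    grand = m.mean()
    ss_time = n * ((m.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((m.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((m - grand) ** 2).sum()
    ss_err = ss_tot - ss_time - ss_subj
    return (ss_time / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))


def mixed_interaction_F_by_hand(labels, matrix):
    """Balanced mixed-design interaction F from cell-mean sums of squares."""
    m = np.asarray(matrix, float)
    labels = np.asarray(labels)
    levels = sorted(set(labels.tolist()))
    n, k = m.shape
    grand = m.mean()
    t_means = m.mean(axis=0)
    ss_inter = 0.0
    for g in levels:
        rows = m[labels == g]
        g_mean = rows.mean()
        for j in range(k):
            cell = rows[:, j].mean()
            ss_inter += rows.shape[0] * (cell - g_mean - t_means[j] + grand) ** 2
    # within-subject error: subject-by-time residual within groups
    ss_err = 0.0
    for g in levels:
        rows = m[labels == g]
        subj = rows.mean(axis=1, keepdims=True)
        cell = rows.mean(axis=0, keepdims=True)
        g_mean = rows.mean()
        resid = rows - subj - cell + g_mean
        ss_err += (resid ** 2).sum()
    df_inter = (len(levels) - 1) * (k - 1)
    df_err = (k - 1) * (n - len(levels))
    return (ss_inter / df_inter) / (ss_err / df_err)


# --- normality gate ----------------------------------------------------

class TestNormalityGate:
    def test_gaussian_samples_usually_pass(self):
        rng = np.random.default_rng(0)
        hits = sum(
            st.normality_gate(rng.normal(0, 1, 19), rng.normal(0, 1, 19)) == "gaussian"
            for _ in range(1000))
        # nominal pass rate is 0.95^2 = 0.9025; allow 3 sigma of binomial noise
        assert hits >= 875

    def test_outlier_mass_fails(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 19)
        b = np.concatenate([rng.normal(0, 1, 14), rng.normal(0, 1, 5) + 10])
        assert st.normality_gate(a, b) == "non_gaussian"

    def test_constant_sample_degenerate(self):
        assert st.normality_gate(np.ones(10), np.random.default_rng(2).normal(size=10)) \
            == "non_gaussian"

    def test_small_sample_rejected(self):
        with pytest.raises(InputError):
            st.normality_gate([1, 2], [1, 2, 3])


# --- two-sample dispatch ----------------------------------------------

class TestIndependentTwoSample:
    def test_identical_samples(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = st.independent_two_sample(a, a)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_zero_pooled_variance(self):
        res = st.independent_two_sample([2.0, 2.0], [2.0, 2.0])
        assert res.p == 1.0

    def test_constant_vs_shifted_falls_back_to_mwu(self):
        res = st.independent_two_sample([1.0, 1.0, 1.0], [2.0, 2.0, 2.0], policy="auto")
        assert res.test.startswith("mwu")
        assert res.p < 0.2

    def test_small_sample_exact_example(self):
        res = st.independent_two_sample([1, 2], [3, 4], policy="mwu")
        assert res.test == "mwu_exact"
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(2 / 6)

    def test_t_branch_df(self):
        rng = np.random.default_rng(3)
        res = st.independent_two_sample(rng.normal(0, 1, 19), rng.normal(0, 1, 19),
                                        policy="t")
        assert res.df == (36,)

    def test_power_at_one_pooled_sd_shift(self):
        # classic benchmark: d = 1.0 at n = 19 + 19 gives ~85% power
        rng = np.random.default_rng(4)
        rejections = 0
        sims = 2000
        for _ in range(sims):
            a = rng.normal(0, 1, 19)
            b = rng.normal(1, 1, 19)
            if st.independent_two_sample(a, b).p < 0.05:
                rejections += 1
        assert 0.80 <= rejections / sims <= 0.90


class TestMannWhitney:
    @pytest.mark.parametrize("n1,n2", [(2, 2), (3, 3), (4, 4), (5, 5), (3, 5), (4, 6)])
    def test_exact_matches_brute_force(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(5):
            a = rng.integers(0, 6, n1).astype(float)  # ties likely
            b = rng.integers(0, 6, n2).astype(float)
            res = st.mann_whitney_exact(a, b)
            assert res.p == pytest.approx(brute_force_mwu_p(a, b))

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            a = rng.normal(0, 1, 5)
            b = rng.normal(0.5, 1, 6)
            res = st.mann_whitney_exact(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert res.p == pytest.approx(ref.pvalue)

    def test_z_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            a = rng.integers(0, 10, 19).astype(float)
            b = rng.integers(2, 12, 19).astype(float)
            res = st.mann_whitney_z(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method="asymptotic", use_continuity=True)
            assert res.p == pytest.approx(ref.pvalue, rel=1e-9)


# --- paired t ----------------------------------------------------------

class TestPairedT:
    def test_no_change(self):
        before = [1.0, 2.0, 3.0]
        res = st.paired_t(before, before)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_constant_nonzero_shift_degenerate(self):
        with pytest.raises(DegenerateDataError):
            st.paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(11)
        before = rng.normal(10, 2, 19)
        after = before + rng.normal(-0.5, 1, 19)
        res = st.paired_t(before, after)
        d = after - before
        t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        assert res.statistic == pytest.approx(t_ref)
        assert res.df == (18,)


# --- ANOVAs ------------------------------------------------------------

class TestRmAnova:
    def test_zero_time_effect(self):
        m = np.tile(np.arange(5.0)[:, None], (1, 3))  # subjects differ, time flat
        res = st.one_way_rm_anova(m)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_df_for_19_by_3(self):
        rng = np.random.default_rng(12)
        res = st.one_way_rm_anova(rng.normal(size=(19, 3)))
        assert res.df == (2.0, 36.0)

    def test_matches_hand_sums_of_squares(self):
        rng = np.random.default_rng(13)
        m = rng.normal(10, 3, size=(4, 3))
        res = st.one_way_rm_anova(m)
        assert res.statistic == pytest.approx(rm_anova_F_by_hand(m), rel=1e-9)

    def test_missing_cells_rejected(self):
        m = np.ones((4, 3))
        m[1, 2] = np.nan
        with pytest.raises(InputError):
            st.one_way_rm_anova(m)

    def test_gg_correction_available(self):
        rng = np.random.default_rng(14)
        res = st.one_way_rm_anova(rng.normal(size=(10, 3)), correction="gg")
        assert res.test == "rm_anova_gg"
        assert 0 <= res.p <= 1


class TestMixedAnova:
    def test_noise_free_null_is_all_zero(self):
        labels = ["a"] * 3 + ["b"] * 3
        m = np.ones((6, 3))
        res = st.mixed_anova_simple_effects(labels, m)
        for key in ("between", "within", "interaction"):
            assert res[key].statistic == 0.0 and res[key].p == 1.0
        for r in res["simple_effects"].values():
            assert r.statistic == 0.0

    def test_dfs_for_5_plus_5_by_3(self):
        rng = np.random.default_rng(15)
        labels = ["ptsd"] * 5 + ["res"] * 5
        res = st.mixed_anova_simple_effects(labels, rng.normal(size=(10, 3)))
        assert res["interaction"].df == (2.0, 16.0)
        for r in res["simple_effects"].values():
            assert r.df == (1.0, 8.0)

    def test_interaction_matches_hand_cell_means(self):
        rng = np.random.default_rng(16)
        labels = ["a"] * 3 + ["b"] * 3
        m = rng.normal(size=(6, 2))
        res = st.mixed_anova_simple_effects(labels, m)
        assert res["interaction"].statistic == pytest.approx(
            mixed_interaction_F_by_hand(labels, m), rel=1e-6)

    def test_unbalanced_groups_supported(self):
        rng = np.random.default_rng(17)
        labels = ["a"] * 4 + ["b"] * 6
        res = st.mixed_anova_simple_effects(labels, rng.normal(size=(10, 3)))
        assert res["interaction"].df[0] == 2.0
        for r in res["simple_effects"].values():
            assert r.df == (1.0, 8.0)


# --- Spearman ----------------------------------------------------------

class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert st.spearman(x, x ** 3).statistic == pytest.approx(1.0)
        assert st.spearman(x, -x).statistic == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        res = st.spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.statistic == pytest.approx(0.8)

    def test_equals_pearson_on_ranks(self):
        rng = np.random.default_rng(18)
        x = rng.integers(0, 8, 25).astype(float)
        y = rng.integers(0, 8, 25).astype(float)
        ref = sps.pearsonr(sps.rankdata(x), sps.rankdata(y)).statistic
        assert st.spearman(x, y).statistic == pytest.approx(ref, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            st.spearman([1, 1, 1], [1, 2, 3])

    @settings(derandomize=True, deadline=None, max_examples=25)
    @given(hst.integers(min_value=0, max_value=10**6))
    def test_invariant_to_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        base = st.spearman(x, y).statistic
        assert st.spearman(np.exp(x), y ** 3).statistic == pytest.approx(base)
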