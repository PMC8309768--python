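from itertools import combinations, product

import numpy as np
import pytest
import scipy.stats as sps

from zfsentinel.core_io import DataError
from zfsentinel.group_stats import (
    DegenerateDataError,
    SummaryStats,
    kruskal_wallis,
    paired_wilcoxon,
    ratio_anova_tukey,
    shape_manova,
    summarize,
    welch_t,
    welch_t_from_summary,
)


class TestWelchT:
    def test_identical_samples_give_t_zero_p_one(self):
        r = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_large_shift_with_tiny_variance_is_significant(self):
        r = welch_t([1, 2, 3], [11, 12, 13])
        assert abs(r.statistic) > 10
        assert r.p_value < 0.001
        assert r.effect_direction == "b > a"

    def test_antisymmetric_in_sample_order(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 2, 10)
        r1, r2 = welch_t(a, b), welch_t(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_invariant_under_shared_shift_and_scale(self, rng):
        a, b = rng.normal(0, 1, 7), rng.normal(1, 1.5, 9)
        r1 = welch_t(a, b)
        r2 = welch_t(3.5 * a - 20, 3.5 * b - 20)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_zero_variance_in_both_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            welch_t([1.0, 1.0, 1.0], [2.0, 2.0])


class TestWelchTFromSummary:
    def test_equal_summaries_give_zero(self):
        s = SummaryStats(5.0, 1.0, 12)
        assert welch_t_from_summary(s, s).statistic == 0.0

    def test_consistent_with_raw_data_welch(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1.4, 12)
        r_raw = welch_t(a, b)
        r_sum = welch_t_from_summary(summarize(a), summarize(b))
        assert r_sum.statistic == pytest.approx(r_raw.statistic)
        assert r_sum.extras["df_welch"] == pytest.approx(r_raw.df)
        assert r_sum.p_value == pytest.approx(r_raw.p_value)


def hand_pillai_balanced_2x2(Y, pop, sex):
    """Pillai's trace per term by direct scatter-matrix arithmetic for a
    balanced 2x2 design (independent oracle: group-mean formulas)."""
    Y = np.asarray(Y, float)
    pop = np.asarray(pop)
    sex = np.asarray(sex)
    grand = Y.mean(axis=0)
    levels_p, levels_s = sorted(set(pop)), sorted(set(sex))
    # error scatter: within-cell
    E = np.zeros((Y.shape[1], Y.shape[1]))
    for p in levels_p:
        for s in levels_s:
            cell = Y[(pop == p) & (sex == s)]
            d = cell - cell.mean(axis=0)
            E += d.T @ d
    out = {}
    # main effects from marginal means, interaction from cell means
    H_A = np.zeros_like(E)
    for p in levels_p:
        m = Y[pop == p].mean(axis=0) - grand
        H_A += (pop == p).sum() * np.outer(m, m)
    H_B = np.zeros_like(E)
    for s in levels_s:
        m = Y[sex == s].mean(axis=0) - grand
        H_B += (sex == s).sum() * np.outer(m, m)
    H_cells = np.zeros_like(E)
    for p in levels_p:
        for s in levels_s:
            cell = Y[(pop == p) & (sex == s)]
            m = cell.mean(axis=0) - grand
            H_cells += len(cell) * np.outer(m, m)
    H_AB = H_cells - H_A - H_B
    for name, H in (("Population", H_A), ("Sex", H_B), ("Population:Sex", H_AB)):
        out[name] = np.trace(H @ np.linalg.inv(H + E))
    return out


class TestShapeManova:
    def test_pillai_matches_direct_scatter_arithmetic(self, rng):
        """Balanced 2x2, 3 obs/cell, 2 responses: model-comparison Pillai
        equals the classical scatter-matrix formulas to 1e-12."""
        pop = np.repeat(["s1", "s2"], 6)
        sex = np.tile(np.repeat(["f", "m"], 3), 2)
        Y = rng.normal(0, 1, size=(12, 2))
        res = shape_manova(Y, pop, sex)
        oracle = hand_pillai_balanced_2x2(Y, pop, sex)
        for term in oracle:
            assert res[term].statistic == pytest.approx(oracle[term], abs=1e-12)

    def test_matches_statsmodels_manova(self, rng):
        import pandas as pd
        from statsmodels.multivariate.manova import MANOVA

        pop = np.repeat(["s1", "s2"], 10)
        sex = np.tile(np.repeat(["f", "m"], 5), 2)
        Y = rng.normal(0, 1, size=(20, 3))
        Y[pop == "s2"] += 0.8
        res = shape_manova(Y, pop, sex)
        df = pd.DataFrame(Y, columns=["y1", "y2", "y3"])
        df["pop"], df["sex"] = pop, sex
        # sum-to-zero coding makes statsmodels' partial (Type III) test
        # equal to Type II on this balanced design
        mv = MANOVA.from_formula(
            "y1 + y2 + y3 ~ C(pop, Sum) * C(sex, Sum)", data=df
        ).mv_test()
        sm_pillai = mv.results["C(pop, Sum)"]["stat"].loc["Pillai's trace", "Value"]
        assert res["Population"].statistic == pytest.approx(float(sm_pillai), abs=1e-10)

    def test_strong_population_shift_detected(self, rng):
        pop = np.repeat(["s1", "s2"], 30)
        sex = np.tile(["f", "m"], 30)
        Y = rng.normal(0, 1, size=(60, 4))
        Y[pop == "s2"] += 2.0
        res = shape_manova(Y, pop, sex)
        assert res["Population"].p_value < 0.001
        assert res["Sex"].p_value > 0.001

    def test_singular_scatter_advises_dimension_reduction(self, rng):
        pop = np.repeat(["s1", "s2"], 3)
        sex = np.tile(["f", "m"], 3)
        Y = rng.normal(0, 1, size=(6, 10))
        with pytest.raises(DataError, match="fewer PC axes"):
            shape_manova(Y, pop, sex)


def hand_anova_balanced_2x2(y, pop, sex):
    """Classical balanced two-way ANOVA F ratios from the textbook sum
    of squares decomposition (independent oracle)."""
    y = np.asarray(y, float)
    grand = y.mean()
    levels_p, levels_s = sorted(set(pop)), sorted(set(sex))
    n_cell = len(y) // 4
    ss_a = sum((y[pop == p].mean() - grand) ** 2 * (pop == p).sum() for p in levels_p)
    ss_b = sum((y[sex == s].mean() - grand) ** 2 * (sex == s).sum() for s in levels_s)
    ss_cells = sum(
        (y[(pop == p) & (sex == s)].mean() - grand) ** 2 * n_cell
        for p in levels_p
        for s in levels_s
    )
    ss_ab = ss_cells - ss_a - ss_b
    ss_e = sum(
        ((y[(pop == p) & (sex == s)] - y[(pop == p) & (sex == s)].mean()) ** 2).sum()
        for p in levels_p
        for s in levels_s
    )
    df_e = len(y) - 4
    return {
        "Population": (ss_a / 1) / (ss_e / df_e),
        "Sex": (ss_b / 1) / (ss_e / df_e),
        "Population:Sex": (ss_ab / 1) / (ss_e / df_e),
    }


class TestRatioAnovaTukey:
    def test_balanced_2x2_matches_hand_ss_decomposition(self, rng):
        pop = np.repeat(["s1", "s2"], 10)
        sex = np.tile(np.repeat(["f", "m"], 5), 2)
        y = rng.normal(1.5, 0.2, 20) + 0.3 * (pop == "s2") - 0.2 * (sex == "m")
        res, _ = ratio_anova_tukey(y, pop, sex)
        oracle = hand_anova_balanced_2x2(y, pop, sex)
        for term in oracle:
            assert res[term].statistic == pytest.approx(oracle[term], abs=1e-10)

    def test_planted_interaction_detected_with_power(self):
        """One depressed cell (-0.3) at n=30/cell: interaction found at
        alpha=0.05 in well over 80% of replicates."""
        rng = np.random.default_rng(7)
        pop = np.repeat(["s1", "s2"], 60)
        sex = np.tile(np.repeat(["f", "m"], 30), 2)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            y = rng.normal(1.5, 0.2, 120)
            y[(pop == "s2") & (sex == "m")] -= 0.3
            res, _ = ratio_anova_tukey(y, pop, sex)
            hits += res["Population:Sex"].p_value < 0.05
        assert hits / n_rep > 0.8

    def test_empty_cell_is_named(self):
        pop = ["s1", "s1", "s2", "s2"]
        sex = ["f", "m", "m", "m"]
        with pytest.raises(DataError, match="s2.*f"):
            ratio_anova_tukey([1.0, 2.0, 3.0, 4.0], pop, sex)

    def test_tukey_flags_separated_cell(self, rng):
        pop = np.repeat(["s1", "s2"], 40)
        sex = np.tile(np.repeat(["f", "m"], 20), 2)
        y = rng.normal(1.5, 0.1, 80)
        y[(pop == "s2") & (sex == "m")] -= 1.0
        _, tukey = ratio_anova_tukey(y, pop, sex)
        flagged = {
            frozenset((r.group1, r.group2)) for r in tukey.itertuples() if r.reject
        }
        assert all(
            frozenset(("s2:m", other)) in flagged for other in ("s1:f", "s1:m", "s2:f")
        )


def enumerate_wilcoxon(diffs, alternative="two-sided"):
    """Full 2^n sign-assignment enumeration oracle."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    n = len(d)
    w_obs = ranks[d > 0].sum()
    ws = np.array(
        [sum(r for r, s in zip(ranks, signs) if s) for signs in product([0, 1], repeat=n)]
    )
    total = ranks.sum()
    if alternative == "greater":
        return (ws >= w_obs - 1e-9).mean()
    if alternative == "less":
        return (ws <= w_obs + 1e-9).mean()
    p_le = (ws <= w_obs + 1e-9).mean()
    p_ge = (ws >= w_obs - 1e-9).mean()
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestPairedWilcoxon:
    def test_all_positive_unit_shift_one_sided_exact(self):
        ant = np.arange(10, dtype=float)
        post = ant + 1.0
        r = paired_wilcoxon(post, ant, alternative="greater")
        assert r.p_value == pytest.approx(1.0 / 1024.0)
        assert r.extras["method"] == "exact"

    def test_antisymmetric_differences_sit_at_null_center(self):
        ant = np.zeros(8)
        post = np.array([1.0, -1.5, 2.0, -2.5, 3.0, -3.5, 4.0, -4.0])
        r = paired_wilcoxon(post, ant)
        total = 8 * 9 / 2
        assert abs(r.statistic - total / 2) <= 2.0

    @pytest.mark.parametrize("trial", range(5))
    def test_exact_p_equals_full_sign_enumeration(self, trial):
        rng = np.random.default_rng(100 + trial)
        ant = rng.normal(0, 1, 8)
        post = ant + rng.normal(0.3, 1, 8)
        r = paired_wilcoxon(post, ant)
        assert r.p_value == pytest.approx(enumerate_wilcoxon(post - ant), abs=1e-12)

    def test_exact_handles_ties(self):
        ant = np.zeros(8)
        post = np.array([1.0, 1.0, -1.0, 2.0, 2.0, -2.0, 3.0, 3.0])
        r = paired_wilcoxon(post, ant)
        assert r.extras["method"] == "exact"
        assert r.p_value == pytest.approx(enumerate_wilcoxon(post - ant), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self, rng):
        ant = rng.normal(0, 1, 12)
        post = ant + rng.normal(0.5, 1, 12)
        r = paired_wilcoxon(post, ant)
        ref = sps.wilcoxon(post, ant, mode="exact", alternative="two-sided")
        assert r.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        ant = rng.uniform(1, 2, 10)
        post = ant * rng.uniform(1.0, 1.5, 10)
        r1 = paired_wilcoxon(post, ant)
        r2 = paired_wilcoxon(np.log(post), np.log(ant))
        # log preserves the sign and order of paired differences here
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_all_zero_differences_degenerate(self):
        x = np.ones(6)
        with pytest.raises(DegenerateDataError):
            paired_wilcoxon(x, x)

    def test_normal_approximation_close_to_exact_at_moderate_n(self, rng):
        ant = rng.normal(0, 1, 20)
        post = ant + rng.normal(0.4, 1, 20)
        r_exact = paired_wilcoxon(post, ant, exact_n_max=25)
        r_norm = paired_wilcoxon(post, ant, exact_n_max=5)
        assert r_norm.p_value == pytest.approx(r_exact.p_value, abs=0.01)


def hand_kruskal_tie_corrected(values, groups):
    """Tie-corrected H from the textbook formula (independent oracle)."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    n = len(values)
    ranks = sps.rankdata(values)
    H = 12.0 / (n * (n + 1)) * sum(
        (ranks[groups == g].sum()) ** 2 / (groups == g).sum() for g in set(groups)
    ) - 3 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    correction = 1 - np.sum(counts**3 - counts) / (n**3 - n)
    return H / correction


class TestKruskalWallis:
    def test_maximal_rank_separation_attains_enumeration_maximum(self):
        r = kruskal_wallis([1, 2, 3, 10, 11, 12], ["a"] * 3 + ["b"] * 3)
        # enumerate every assignment of ranks 1..6 to group a (choose 3)
        hs = []
        ranks = np.arange(1, 7)
        for idx in combinations(range(6), 3):
            ra = ranks[list(idx)].sum()
            rb = ranks.sum() - ra
            hs.append(12 / (6 * 7) * (ra**2 / 3 + rb**2 / 3) - 3 * 7)
        assert r.statistic == pytest.approx(max(hs))

    def test_tie_corrected_hand_example(self):
        values = [1.0, 2.0, 2.0, 3.0, 3.0, 5.0]
        groups = ["a", "a", "b", "b", "c", "c"]
        r = kruskal_wallis(values, groups)
        assert r.statistic == pytest.approx(hand_kruskal_tie_corrected(values, groups), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        v = rng.uniform(0.5, 4, 15)
        g = rng.choice(["a", "b", "c"], 15)
        r1 = kruskal_wallis(v, g)
        r2 = kruskal_wallis(np.exp(v), g)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_identical_values_degenerate(self):
        with pytest.raises(DegenerateDataError):
            kruskal_wallis([2.0] * 6, ["a", "a", "a", "b", "b", "b"])

    def test_separated_groups_significant(self):
        r = kruskal_wallis(
            list(range(10)) + list(range(100, 110)), ["a"] * 10 + ["b"] * 10
        )
        assert r.p_value < 0.001
        assert r.effect_direction == "largest median: b"
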