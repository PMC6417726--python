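"""Unit and property tests for the shared statistical primitives."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cuticula.stats import (
    DegenerateDataError,
    anova_tukey,
    bh_adjust,
    compact_letter_display,
    conover_iman,
    kruskal_conover,
    pearson,
    shapiro_wilk,
    students_t,
    two_proportion_z,
)


def hand_pearson(x, y):
    """Independent product-moment oracle: explicit sums, no numpy stats."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r = sxy / math.sqrt(sxx * syy)
    t = r * math.sqrt((n - 2) / (1 - r * r))
    from scipy.stats import t as tdist

    return r, 2 * tdist.sf(abs(t), n - 2)


class TestPearson:
    def test_perfect_positive_and_negative(self):
        x = [1.0, 2.0, 5.0, 7.0]
        assert pearson(x, x).r == pytest.approx(1.0)
        assert pearson(x, [-v for v in x]).r == pytest.approx(-1.0)

    def test_matches_hand_computed_product_moment(self):
        x = list(range(1, 10))
        y = [2, 1, 4, 3, 6, 5, 8, 7, 9]
        res = pearson(x, y)
        r_ref, p_ref = hand_pearson(x, y)
        assert res.r == pytest.approx(r_ref, abs=1e-12)
        assert res.p == pytest.approx(p_ref, abs=1e-12)
        assert res.n == 9

    def test_zero_variance_raises_not_nan(self):
        with pytest.raises(DegenerateDataError):
            pearson([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [3, 4])

    @settings(deadline=None, max_examples=30)
    @given(
        st.lists(st.floats(-50, 50), min_size=4, max_size=12),
        st.floats(0.1, 5),
        st.floats(-10, 10),
    )
    def test_symmetry_and_positive_affine_invariance(self, x, a, b):
        rng = np.random.default_rng(0)
        y = list(rng.normal(0, 1, len(x)))
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        fwd = pearson(x, y)
        rev = pearson(y, x)
        assert fwd.r == pytest.approx(rev.r, abs=1e-12)
        scaled = pearson([a * v + b for v in x], y)
        assert scaled.r == pytest.approx(fwd.r, rel=1e-9, abs=1e-9)


class TestTwoProportionZ:
    def test_equal_proportions_give_zero(self):
        z, p = two_proportion_z(30, 100, 60, 200)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_pooled_formula_oracle(self):
        k1, n1, k2, n2 = 30, 100, 50, 100
        pooled = (k1 + k2) / (n1 + n2)
        se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
        z_ref = (k1 / n1 - k2 / n2) / se
        from scipy.stats import norm

        p_ref = 2 * norm.sf(abs(z_ref))
        z, p = two_proportion_z(k1, n1, k2, n2)
        assert z == pytest.approx(z_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-12)

    def test_degenerate_pooled_proportion_raises(self):
        with pytest.raises(DegenerateDataError):
            two_proportion_z(0, 50, 0, 80)
        with pytest.raises(DegenerateDataError):
            two_proportion_z(50, 50, 80, 80)

    def test_small_counts_agree_with_binomial_null_simulation(self):
        # simulated two-binomial null: p-value is the null probability of a
        # difference at least as large as observed
        k1, n1, k2, n2 = 12, 40, 22, 45
        _, p = two_proportion_z(k1, n1, k2, n2)
        rng = np.random.default_rng(7)
        pooled = (k1 + k2) / (n1 + n2)
        reps = 40_000
        d1 = rng.binomial(n1, pooled, reps) / n1
        d2 = rng.binomial(n2, pooled, reps) / n2
        obs = abs(k1 / n1 - k2 / n2)
        p_mc = np.mean(np.abs(d1 - d2) >= obs - 1e-12)
        assert p == pytest.approx(p_mc, abs=0.04)

    def test_type_one_error_rate_calibrated(self):
        # equal-proportion simulation: rejection rate at alpha=0.05 near 0.05
        rng = np.random.default_rng(11)
        reps = 10_000
        n = 200
        k1 = rng.binomial(n, 0.3, reps)
        k2 = rng.binomial(n, 0.3, reps)
        rejected = 0
        for a, b in zip(k1, k2):
            try:
                _, p = two_proportion_z(int(a), n, int(b), n)
            except DegenerateDataError:
                continue
            rejected += p < 0.05
        rate = rejected / reps
        assert abs(rate - 0.05) < 0.015


class TestBhAdjust:
    def test_all_equal_pvalues_unchanged(self):
        q = bh_adjust([0.2, 0.2, 0.2])
        assert np.allclose(q, 0.2)

    def test_step_up_hand_example(self):
        # p_(i) * m / i then cumulative minimum from the largest rank down
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_never_decreases_and_never_exceeds_one(self, pvals):
        q = bh_adjust(pvals)
        assert np.all(q >= np.asarray(pvals) - 1e-12)
        assert np.all(q <= 1.0 + 1e-12)


class TestSmallTests:
    def test_students_t_identical_samples(self):
        t, p = students_t([1.0, 2.0, 3.0], [3.0, 1.0, 2.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_shapiro_wilk_constant_raises(self):
        with pytest.raises(DegenerateDataError):
            shapiro_wilk([2.0, 2.0, 2.0, 2.0])

    def test_shapiro_wilk_rejects_exponential(self):
        rng = np.random.default_rng(3)
        _, p = shapiro_wilk(rng.exponential(1.0, 200))
        assert p < 0.01


class TestCompactLetterDisplay:
    def test_reproduces_significance_matrix_exactly(self):
        # the display's defining contract, over random comparison outcomes
        rng = np.random.default_rng(5)
        for _ in range(50):
            k = int(rng.integers(2, 7))
            sig = rng.random((k, k)) < 0.4
            sig = np.triu(sig, 1)
            sig = sig | sig.T
            groups = [f"G{i}" for i in range(k)]
            letters = compact_letter_display(groups, sig)
            for i, j in itertools.combinations(range(k), 2):
                share = bool(set(letters[groups[i]]) & set(letters[groups[j]]))
                assert share == (not sig[i, j])

    def test_every_group_gets_a_letter(self):
        sig = np.array([[False, True], [True, False]])
        letters = compact_letter_display(["a_grp", "b_grp"], sig)
        assert letters["a_grp"] and letters["b_grp"]
        assert not set(letters["a_grp"]) & set(letters["b_grp"])


class TestAnovaTukey:
    def test_identical_populations_share_one_letter(self, rng):
        groups = [rng.normal(10, 1, 40) for _ in range(3)]
        res = anova_tukey(groups)
        assert len(set(res.letters.values())) == 1

    def test_far_shifted_group_uniquely_lettered(self, rng):
        groups = [rng.normal(10, 1, 15), rng.normal(10, 1, 15), rng.normal(20, 1, 15)]
        res = anova_tukey(groups, labels=["a1", "a2", "far"])
        assert not res.share_letter("far", "a1")
        assert not res.share_letter("far", "a2")
        assert res.share_letter("a1", "a2")

    def test_letters_match_pvalue_matrix(self, rng):
        groups = [rng.normal(m, 2, 12) for m in (0, 1.5, 3.0, 3.1)]
        res = anova_tukey(groups)
        k = len(groups)
        for i, j in itertools.combinations(range(k), 2):
            share = res.share_letter(res.groups[i], res.groups[j])
            assert share == (res.pvalues[i, j] >= res.alpha)

    def test_small_group_raises(self):
        with pytest.raises(ValueError):
            anova_tukey([[1.0], [1.0, 2.0]])


def hand_conover_iman(groups):
    """Independent rank-arithmetic oracle (explicit loops, no scipy post hoc)."""
    pooled = [v for g in groups for v in g]
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    sizes = [len(g) for g in groups]
    n_total = len(pooled)
    k = len(groups)
    bounds = np.cumsum([0] + sizes)
    rank_groups = [ranks[bounds[i]: bounds[i + 1]] for i in range(k)]
    rank_sums = [sum(rg) for rg in rank_groups]
    # tie-corrected Kruskal-Wallis H
    h = (12 / (n_total * (n_total + 1))) * sum(
        rs**2 / n for rs, n in zip(rank_sums, sizes)
    ) - 3 * (n_total + 1)
    tie_counts = {}
    for v in pooled:
        tie_counts[v] = tie_counts.get(v, 0) + 1
    correction = 1 - sum(t**3 - t for t in tie_counts.values()) / (n_total**3 - n_total)
    h /= correction
    s2 = (sum(r * r for r in ranks) - n_total * (n_total + 1) ** 2 / 4) / (n_total - 1)
    scale = s2 * (n_total - 1 - h) / (n_total - k)
    tmat = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i != j:
                se = math.sqrt(scale * (1 / sizes[i] + 1 / sizes[j]))
                tmat[i, j] = (rank_sums[i] / sizes[i] - rank_sums[j] / sizes[j]) / se
    return tmat, h


class TestKruskalConover:
    TOY = [[3.1, 4.2, 2.8, 3.9], [5.5, 6.1, 4.9, 5.8], [8.2, 7.9, 9.1, 8.5]]

    def test_conover_t_matches_hand_rank_arithmetic(self):
        tmat, pmat, h = conover_iman(self.TOY)
        t_ref, h_ref = hand_conover_iman(self.TOY)
        assert h == pytest.approx(h_ref, abs=1e-9)
        assert np.allclose(tmat, t_ref, atol=1e-9)

    def test_identical_groups_share_letter(self, rng):
        groups = [rng.normal(5, 1, 25) for _ in range(3)]
        res = kruskal_conover(groups)
        assert len(set(res.letters.values())) == 1

    def test_monotone_large_shift_all_distinct(self, rng):
        groups = [rng.normal(m, 0.5, 20) for m in (0, 10, 20)]
        res = kruskal_conover(groups)
        assert len(set(res.letters.values())) == 3

    def test_all_tied_raises(self):
        with pytest.raises(DegenerateDataError):
            kruskal_conover([[1.0, 1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])

    def test_bonferroni_never_below_raw(self):
        _, pmat, _ = conover_iman(self.TOY)
        res = kruskal_conover(self.TOY, correction="bonferroni")
        off = ~np.eye(3, dtype=bool)
        assert np.all(res.pvalues[off] >= pmat[off] - 1e-12)
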