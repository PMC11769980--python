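"""Wilcoxon/Mann-Whitney branches and the sequential two-way ANOVA against
independent oracles (full enumeration; explicit least-squares projections)."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cardioresp.stats import anova2, assemble_anova_table, mannwhitney, wilcoxon_signed


def wilcoxon_exact_enumeration(d):
    """Two-sided signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray(d, dtype=float)
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    count = 0
    n = len(d)
    for signs in itertools.product([0, 1], repeat=n):
        w_plus = sum(r for s, r in zip(signs, ranks) if s)
        w = min(w_plus, ranks.sum() - w_plus)
        if w <= w_obs + 1e-12:
            count += 1
    return count / 2**n


def sequential_projection_anova(y, a, b):
    """Type I sums of squares by explicit nested least squares."""
    y = np.asarray(y, dtype=float)
    a = pd.Categorical(a)
    b = pd.Categorical(b)

    def design(terms):
        cols = [np.ones_like(y)]
        if "a" in terms:
            cols += [(a.codes == i).astype(float) for i in range(1, len(a.categories))]
        if "b" in terms:
            cols += [(b.codes == j).astype(float) for j in range(1, len(b.categories))]
        if "ab" in terms:
            for i in range(1, len(a.categories)):
                for j in range(1, len(b.categories)):
                    cols.append(((a.codes == i) & (b.codes == j)).astype(float))
        return np.column_stack(cols)

    def rss(x):
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        r = y - x @ beta
        return float(r @ r)

    rss0 = rss(design([]))
    rss_a = rss(design(["a"]))
    rss_ab = rss(design(["a", "b"]))
    rss_full = rss(design(["a", "b", "ab"]))
    return {
        "A": rss0 - rss_a,
        "B": rss_a - rss_ab,
        "AB": rss_ab - rss_full,
        "error": rss_full,
    }


def _fixed_24_rows():
    rng = np.random.default_rng(99)
    a = np.repeat(["CR6", "CR15"], 12)
    b = np.array(["I", "II", "III", "IV"] * 6)
    # unbalanced response with real effects on both factors
    y = (
        2.0 * (a == "CR6")
        + np.select([b == t for t in ("I", "II", "III", "IV")], [1.0, 0.5, -0.3, -1.2])
        + rng.normal(0, 1.0, 24)
    )
    return y, a, b


class TestWilcoxon:
    def test_five_uniform_signs_exact_p(self):
        # all-positive differences: the most extreme of 2^5 sign patterns,
        # two-sided p = 2/32
        res = wilcoxon_signed([6, 8, 10, 12, 14], [1, 2, 3, 4, 5])
        assert res.p == pytest.approx(0.0625, abs=1e-12)

    def test_identical_pairs_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed([1.0, 2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0, 5.0])

    def test_swap_leaves_magnitude_and_p(self, rng):
        x = rng.normal(0, 1, 15)
        y = x + rng.normal(0.3, 1, 15)
        r1 = wilcoxon_signed(x, y)
        r2 = wilcoxon_signed(y, x)
        assert r1.z == pytest.approx(r2.z)
        assert r1.p == pytest.approx(r2.p)

    def test_exact_branch_matches_enumeration_oracle(self, rng):
        for _ in range(5):
            d = np.round(rng.normal(0.4, 1.0, 9), 3)
            d = d[d != 0][:8]
            res = wilcoxon_signed(d + 100.0, np.full(len(d), 100.0))
            assert res.p == pytest.approx(wilcoxon_exact_enumeration(d), abs=1e-10)

    def test_exact_and_normal_agree_at_switch_point(self, rng):
        # n = 20: the two branches differ by < 0.01 in p on typical data
        for _ in range(5):
            x = rng.normal(0, 1, 20)
            y = x + rng.normal(0.5, 1.2, 20)
            exact = wilcoxon_signed(x, y, exact_n=20)
            approx = wilcoxon_signed(x, y, exact_n=0)
            assert abs(exact.p - approx.p) < 0.01


class TestMannWhitney:
    def test_identical_multisets_give_p_one(self):
        assert mannwhitney([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(1.0, abs=0.01)

    def test_complete_separation_small_samples_exact(self):
        # all 3x3 orderings: U = 0 is 1 of C(6,3) = 20 -> two-sided 2/20
        assert mannwhitney([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1, abs=1e-10)

    def test_monotone_transform_invariance(self, rng):
        a = rng.normal(0, 1, 25)
        b = rng.normal(0.7, 1, 30)
        assert mannwhitney(a, b) == pytest.approx(mannwhitney(np.exp(a), np.exp(b)))

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            mannwhitney([1.0, 2.0], [1.0, 2.0, 3.0])


class TestAnova2:
    def test_matches_projection_oracle(self):
        y, a, b = _fixed_24_rows()
        tab = anova2(y, a, b)
        oracle = sequential_projection_anova(y, a, b)
        for src in ("A", "B", "AB", "error"):
            assert tab.ss[src] == pytest.approx(oracle[src], abs=1e-8)

    def test_decomposition_sums_to_total(self):
        y, a, b = _fixed_24_rows()
        tab = anova2(y, a, b)
        total = float(np.sum((y - y.mean()) ** 2))
        assert tab.ss["total"] == pytest.approx(total, rel=1e-9)
        assert tab.df["total"] == len(y) - 1

    def test_scale_equivariance(self):
        y, a, b = _fixed_24_rows()
        t1 = anova2(y, a, b)
        t2 = anova2(2.0 * y, a, b)
        for src in ("A", "B", "AB", "error"):
            assert t2.ss[src] == pytest.approx(4.0 * t1.ss[src], rel=1e-9)
        for src in ("A", "B", "AB"):
            assert t2.f[src] == pytest.approx(t1.f[src], rel=1e-9)

    def test_single_observation_per_cell_rejected(self):
        a = ["CR6", "CR6", "CR15", "CR15"]
        b = ["I", "II", "I", "II"]
        with pytest.raises(ValueError, match="residual"):
            anova2([1.0, 2.0, 3.0, 4.0], a, b)

    def test_empty_cell_rejected(self):
        a = ["CR6"] * 4 + ["CR15"] * 2
        b = ["I", "I", "II", "II", "I", "I"]
        with pytest.raises(ValueError, match="empty"):
            anova2(np.arange(6.0), a, b)


class TestAssemble:
    def test_finishing_arithmetic(self):
        tab = assemble_anova_table(
            ss={"A": 3253.7438, "B": 141.8665, "AB": 7.2588, "error": 1322.5479},
            dfs={"A": 1, "B": 3, "AB": 3, "error": 358},
        )
        assert tab.f["A"] == pytest.approx(880.7547, rel=1e-4)
        assert tab.ms["error"] == pytest.approx(3.6943, rel=1e-4)
        assert tab.df["total"] == 365

    def test_zero_ss_gives_zero_f(self):
        tab = assemble_anova_table(ss={"A": 0.0, "error": 10.0}, dfs={"A": 1, "error": 20})
        assert tab.f["A"] == 0.0 and tab.p["A"] == pytest.approx(1.0)

    def test_missing_error_row_rejected(self):
        with pytest.raises(ValueError, match="error"):
            assemble_anova_table(ss={"A": 1.0}, dfs={"A": 1})
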