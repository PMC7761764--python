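"""Statistical machinery checked against direct-formula oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from rrnalink.comparative_stats import (
    anova_tukey,
    brownian_covariance,
    kruskal_dunn,
    paired_t_by_category,
    pca,
    pgls_brownian,
    welch_t,
)
from scipy import stats


class TestWelch:
    def test_identical_samples(self):
        res = welch_t([1, 2, 3], [1, 2, 3])
        assert res.t == 0
        assert res.p == pytest.approx(1.0)

    def test_closed_form_oracle(self):
        x, y = np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        t_oracle = (x.mean() - y.mean()) / math.sqrt(vx + vy)
        df_oracle = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
        p_oracle = 2 * stats.t.sf(abs(t_oracle), df_oracle)
        res = welch_t(x, y)
        assert res.t == pytest.approx(t_oracle, rel=1e-12)
        assert res.df == pytest.approx(df_oracle, rel=1e-12)
        assert res.p == pytest.approx(p_oracle, rel=1e-12)

    def test_antisymmetry(self):
        a = welch_t([1, 2, 3], [4, 6, 8])
        b = welch_t([4, 6, 8], [1, 2, 3])
        assert a.t == pytest.approx(-b.t)
        assert a.p == pytest.approx(b.p)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            welch_t([1], [1, 2])
        with pytest.raises(ValueError):
            welch_t([2, 2], [3, 3])


class TestKruskalDunn:
    def test_identical_groups_h_zero(self):
        res = kruskal_dunn([1, 2, 3] * 3, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert res.h_statistic == pytest.approx(0.0, abs=1e-12)

    def test_rank_formula_oracle(self):
        # groups (1,2,3),(4,5,6),(7,8,9): no ties, mean ranks 2, 5, 8
        values = [1, 2, 3, 4, 5, 6, 7, 8, 9]
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        h_oracle = 12 / (9 * 10) * (3 * 2**2 + 3 * 5**2 + 3 * 8**2) - 3 * 10
        res = kruskal_dunn(values, groups)
        assert res.h_statistic == pytest.approx(h_oracle, rel=1e-12)
        # Dunn z for (a, b): (2 - 5) / sqrt((9*10/12) * (1/3 + 1/3))
        z_oracle = (2 - 5) / math.sqrt(9 * 10 / 12 * (2 / 3))
        z_ab = res.dunn.set_index(["group_a", "group_b"]).loc[("a", "b"), "z"]
        assert z_ab == pytest.approx(z_oracle, rel=1e-12)

    def test_shift_invariance(self):
        values = [3.0, 1.5, 2.2, 9.1, 4.4, 5.5, 7.7, 8.8, 6.6]
        groups = ["a", "a", "a", "b", "b", "b", "c", "c", "c"]
        h1 = kruskal_dunn(values, groups).h_statistic
        h2 = kruskal_dunn([v + 100 for v in values], groups).h_statistic
        assert h1 == pytest.approx(h2, rel=1e-12)

    def test_holm_at_least_raw(self):
        res = kruskal_dunn([1, 2, 3, 14, 15, 16, 7, 8, 9], ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert (res.dunn["p_holm"] >= res.dunn["p_raw"] - 1e-15).all()

    def test_two_groups_rejected(self):
        with pytest.raises(ValueError, match="welch"):
            kruskal_dunn([1, 2, 3, 4], ["a", "a", "b", "b"])


class TestAnovaTukey:
    def test_equal_mean_groups(self):
        res = anova_tukey([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)

    def test_sum_of_squares_oracle(self):
        values = np.array([1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 9.0, 12.0, 15.0])
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        samples = [values[:3], values[3:6], values[6:]]
        grand = values.mean()
        ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
        ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
        f_oracle = (ss_between / 2) / (ss_within / 6)
        res = anova_tukey(values, groups)
        assert res.f_statistic == pytest.approx(f_oracle, rel=1e-12)

    def test_degenerate_constant_input(self):
        res = anova_tukey([5.0] * 6, ["a"] * 3 + ["b"] * 3)
        assert res.f_statistic == 0.0
        assert (res.tukey["p_adj"] == 1.0).all()

    def test_relabeling_permutes_pairs_only(self):
        values = [1, 2, 3, 4, 6, 8, 9, 12, 15]
        res1 = anova_tukey(values, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        res2 = anova_tukey(values, ["c"] * 3 + ["a"] * 3 + ["b"] * 3)
        assert res1.f_statistic == pytest.approx(res2.f_statistic)
        p1 = sorted(res1.tukey["p_adj"])
        p2 = sorted(res2.tukey["p_adj"])
        assert p1 == pytest.approx(p2)


class TestPairedT:
    def make_tables(self, pairs):
        phyla = [f"p{i}" for i in range(len(pairs))]
        linked = pd.DataFrame({"K": [a for a, _ in pairs]}, index=phyla)
        unlinked = pd.DataFrame({"K": [b for _, b in pairs]}, index=phyla)
        return linked, unlinked

    def test_identical_means(self):
        out = paired_t_by_category(*self.make_tables([(5, 5), (9, 9), (2, 2)]))
        assert out.loc[0, "t"] == 0
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_difference_formula_oracle(self):
        pairs = [(59, 32), (149, 75), (202, 99)]
        d = np.array([a - b for a, b in pairs], dtype=float)
        t_oracle = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        p_oracle = 2 * stats.t.sf(abs(t_oracle), len(d) - 1)
        out = paired_t_by_category(*self.make_tables(pairs))
        assert out.loc[0, "t"] == pytest.approx(t_oracle, rel=1e-12)
        assert out.loc[0, "p"] == pytest.approx(p_oracle, rel=1e-12)
        # the contrast is roughly a halving of the category counts
        assert out.loc[0, "ratio_unlinked_to_linked"] == pytest.approx(0.5, abs=0.03)

    def test_reversal_flips_sign(self):
        linked, unlinked = self.make_tables([(59, 32), (149, 75), (202, 99)])
        a = paired_t_by_category(linked, unlinked)
        b = paired_t_by_category(unlinked, linked)
        assert a.loc[0, "t"] == pytest.approx(-b.loc[0, "t"])

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            paired_t_by_category(*self.make_tables([(1, 2)]))


class TestPca:
    def test_collinear_data_single_component(self):
        x = np.arange(10.0)
        res = pca(np.column_stack([x, 2 * x + 1]))
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(50, 5)))
        res = pca(X)
        Z = (X - X.mean()) / X.std(ddof=1)
        np.testing.assert_allclose(
            res.scores.to_numpy() @ res.loadings.to_numpy().T, Z.to_numpy(), atol=1e-10
        )

    def test_correlation_eigenvalue_oracle(self):
        X = pd.DataFrame(
            [[1.0, 2.0, 0.5], [2.0, 1.0, 0.7], [3.0, 5.0, 0.2],
             [4.0, 3.0, 0.9], [5.0, 7.0, 0.1], [6.0, 4.0, 0.8]],
            columns=list("abc"),
        )
        eig = np.sort(np.linalg.eigvalsh(np.corrcoef(X.to_numpy().T)))[::-1]
        res = pca(X)
        np.testing.assert_allclose(res.explained_variance, eig, rtol=1e-10)

    def test_constant_column_dropped(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0], "c": [2.0, 1.0, 4.0]})
        with pytest.warns(UserWarning, match="constant"):
            res = pca(X)
        assert list(res.loadings.index) == ["a", "c"]


STAR_TREE = "(A:1.0,B:1.0,C:1.0,D:1.0,E:1.0);"
BALANCED_TREE = "((A:1.0,B:1.0):1.0,(C:1.0,D:1.0):1.0);"


class TestPgls:
    def test_star_tree_equals_ols(self):
        y = pd.Series([1.0, 2.5, 2.0, 4.1, 3.3], index=list("ABCDE"))
        x = pd.Series([0.0, 1.0, 1.0, 2.0, 2.0], index=list("ABCDE"))
        fit = pgls_brownian(STAR_TREE, y, x)
        ols = stats.linregress(x, y)
        assert fit.slope == pytest.approx(ols.slope, rel=1e-10)
        assert fit.intercept == pytest.approx(ols.intercept, rel=1e-10)
        assert fit.slope_se == pytest.approx(ols.stderr, rel=1e-10)

    def test_covariance_matrix_structure(self):
        V = brownian_covariance(BALANCED_TREE, list("ABCD"))
        expected = np.array(
            [[2.0, 1.0, 0.0, 0.0],
             [1.0, 2.0, 0.0, 0.0],
             [0.0, 0.0, 2.0, 1.0],
             [0.0, 0.0, 1.0, 2.0]]
        )
        np.testing.assert_allclose(V, expected)

    def test_four_taxon_matrix_algebra_oracle(self):
        y = pd.Series([0.3, 1.1, 2.0, 2.9], index=list("ABCD"))
        x = pd.Series([0.0, 0.0, 1.0, 1.0], index=list("ABCD"))
        V = brownian_covariance(BALANCED_TREE, list("ABCD"))
        Vi = np.linalg.inv(V)
        X = np.column_stack([np.ones(4), x.to_numpy()])
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y.to_numpy())
        resid = y.to_numpy() - X @ beta
        sigma2 = float(resid @ Vi @ resid) / 2
        se = math.sqrt((sigma2 * np.linalg.inv(X.T @ Vi @ X))[1, 1])
        fit = pgls_brownian(BALANCED_TREE, y, x)
        assert fit.slope == pytest.approx(beta[1], rel=1e-10)
        assert fit.intercept == pytest.approx(beta[0], rel=1e-10)
        assert fit.slope_se == pytest.approx(se, rel=1e-10)
        assert fit.p_value == pytest.approx(2 * stats.t.sf(abs(beta[1] / se), 2), rel=1e-10)

    def test_branch_scale_invariance(self):
        y = pd.Series([0.3, 1.1, 2.0, 2.9], index=list("ABCD"))
        x = pd.Series([0.0, 0.0, 1.0, 1.0], index=list("ABCD"))
        scaled = "((A:3.7,B:3.7):3.7,(C:3.7,D:3.7):3.7);"
        a = pgls_brownian(BALANCED_TREE, y, x)
        b = pgls_brownian(scaled, y, x)
        assert a.slope == pytest.approx(b.slope, rel=1e-10)
        assert a.t_stat == pytest.approx(b.t_stat, rel=1e-10)

    def test_taxa_mismatch_lists_offenders(self):
        y = pd.Series([1.0, 2.0, 3.0], index=["A", "B", "Z"])
        x = pd.Series([0.0, 1.0, 0.0], index=["A", "B", "Z"])
        with pytest.raises(ValueError, match="Z"):
            pgls_brownian(BALANCED_TREE, y, x)
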