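"""Goodness-of-fit tests, two-way ANOVA, and Bonferroni post-hocs."""

import numpy as np
import pandas as pd
import pytest

import mosaicstripes as ms
from mosaicstripes.inference import batch_two_way_anova


def model_comparison_oracle(values, a, b):
    """Independent Type III oracle: full vs reduced least-squares fits
    with sum-to-zero coding, done directly with numpy.
    """
    values = np.asarray(values, dtype=float)
    a_codes = pd.factorize(np.asarray(a))[0]
    b_codes = pd.factorize(np.asarray(b))[0]

    def effcols(codes):
        L = codes.max() + 1
        X = np.zeros((codes.size, L - 1))
        for lvl in range(L - 1):
            X[codes == lvl, lvl] = 1
        X[codes == L - 1] = -1
        return X

    A, B = effcols(a_codes), effcols(b_codes)
    AB = np.einsum("ij,ik->ijk", A, B).reshape(len(values), -1)
    one = np.ones((len(values), 1))

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, values, rcond=None)
        r = values - X @ beta
        return float(r @ r)

    full = np.hstack([one, A, B, AB])
    out = {"residual": rss(full)}
    out["a"] = rss(np.hstack([one, B, AB])) - out["residual"]
    out["b"] = rss(np.hstack([one, A, AB])) - out["residual"]
    out["ab"] = rss(np.hstack([one, A, B])) - out["residual"]
    return out


class TestChiSquareGof:
    def test_het_vs_wt_females_against_1to1(self):
        res = ms.chi_square_gof([50, 88], [1, 1])
        assert round(res.chi2, 2) == 10.46
        assert res.df == 1
        assert res.p_value < 0.01

    def test_males_vs_wt_females_against_2to1(self):
        res = ms.chi_square_gof([81, 88], [2, 1])
        assert round(res.chi2, 2) == 26.70

    def test_males_vs_wt_females_against_1to1(self):
        res = ms.chi_square_gof([81, 88], [1, 1])
        assert round(res.chi2, 3) == 0.290

    def test_perfect_fit_is_exactly_zero(self):
        assert ms.chi_square_gof([70, 70], [1, 1]).chi2 == 0.0

    def test_ratio_scale_invariance(self):
        a = ms.chi_square_gof([30, 50, 20], [1, 2, 1])
        b = ms.chi_square_gof([30, 50, 20], [7, 14, 7])
        assert np.isclose(a.chi2, b.chi2)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ms.chi_square_gof([-1, 5], [1, 1])

    def test_small_expected_counts_warn(self):
        with pytest.warns(UserWarning, match="below 5"):
            ms.chi_square_gof([4, 4], [1, 1])

    def test_genotype_counts_object_accepted(self):
        counts = ms.GenotypeCounts(labels=("a", "b"), observed=np.array([50.0, 88.0]),
                                   expected_ratio=np.array([1.0, 1.0]))
        assert round(ms.chi_square_gof(counts).chi2, 2) == 10.46


class TestDeficiency:
    def test_published_counts_round_to_43(self):
        assert round(ms.deficiency_percent(50, 88)) == 43

    def test_equal_counts_no_deficiency(self):
        assert ms.deficiency_percent(88, 88) == 0.0

    def test_total_loss(self):
        assert ms.deficiency_percent(0, 88) == 100.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ZeroDivisionError):
            ms.deficiency_percent(10, 0)


class TestTwoWayAnova:
    def test_identical_cell_means_give_zero_f(self):
        # every cell holds {4, 6}: all cell means equal, residual variance > 0
        values = [4.0, 6.0] * 4
        a = ["x"] * 4 + ["y"] * 4
        b = ["u", "u", "v", "v"] * 2
        table = ms.two_way_anova(values, a, b)
        assert np.allclose(table.loc[["genotype", "age", "genotype:age"], "F"], 0.0)
        assert np.allclose(table.loc[["genotype", "age", "genotype:age"], "p_value"], 1.0)

    def test_balanced_design_matches_textbook_decomposition(self):
        # closed-form balanced two-way ANOVA: SS from marginal means
        rng = np.random.default_rng(12)
        r = 6
        cells = {("x", "u"): 10.0, ("x", "v"): 12.0,
                 ("y", "u"): 11.0, ("y", "v"): 16.0}
        vals, fa, fb = [], [], []
        for (ai, bi), mu in cells.items():
            vals += list(mu + rng.normal(0, 1, r))
            fa += [ai] * r
            fb += [bi] * r
        vals = np.asarray(vals)
        y = vals.reshape(4, r)
        cell_means = y.mean(axis=1)
        grand = vals.mean()
        a_means = np.array([cell_means[:2].mean(), cell_means[2:].mean()])
        b_means = np.array([cell_means[[0, 2]].mean(), cell_means[[1, 3]].mean()])
        ss_a = 2 * r * ((a_means - grand) ** 2).sum()
        ss_b = 2 * r * ((b_means - grand) ** 2).sum()
        inter = cell_means.reshape(2, 2) - a_means[:, None] - b_means[None, :] + grand
        ss_ab = r * (inter ** 2).sum()

        table = ms.two_way_anova(vals, fa, fb)
        assert np.isclose(table.loc["genotype", "sum_sq"], ss_a)
        assert np.isclose(table.loc["age", "sum_sq"], ss_b)
        assert np.isclose(table.loc["genotype:age", "sum_sq"], ss_ab)

    def test_unbalanced_type3_matches_model_comparison_oracle(self):
        rng = np.random.default_rng(2)
        sizes = {("het", "15"): 8, ("het", "30"): 9,
                 ("wt", "15"): 21, ("wt", "30"): 22}
        vals, fa, fb = [], [], []
        for (g, a), n in sizes.items():
            vals += list(rng.normal(50 + (g == "wt") * 3 + (a == "30") * -2, 5, n))
            fa += [g] * n
            fb += [a] * n
        table = ms.two_way_anova(vals, fa, fb)
        oracle = model_comparison_oracle(vals, fa, fb)
        for term, key in [("genotype", "a"), ("age", "b"), ("genotype:age", "ab")]:
            assert abs(table.loc[term, "sum_sq"] - oracle[key]) \
                <= 1e-8 * abs(oracle[key])
        assert np.isclose(table.loc["Residual", "sum_sq"], oracle["residual"])

    def test_empty_cell_named_in_error(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        fa = ["x", "x", "x", "x", "y", "y"]
        fb = ["u", "u", "v", "v", "u", "u"]  # (y, v) missing
        with pytest.raises(ValueError, match="empty design cell"):
            ms.two_way_anova(vals, fa, fb)

    def test_single_level_factor_rejected(self):
        with pytest.raises(ValueError, match="2 levels"):
            ms.two_way_anova([1.0, 2.0], ["x", "x"], ["u", "v"])

    def test_batch_path_agrees_with_statsmodels_path(self):
        rng = np.random.default_rng(4)
        fa = ["het"] * 10 + ["wt"] * 14
        fb = (["15"] * 5 + ["30"] * 5) + (["15"] * 7 + ["30"] * 7)
        y = rng.normal(0, 1, (24, 5))
        batch = batch_two_way_anova(y, fa, fb)
        for j in range(5):
            table = ms.two_way_anova(y[:, j], fa, fb)
            assert np.isclose(batch["factor_a"]["sum_sq"][j],
                              table.loc["genotype", "sum_sq"])
            assert np.isclose(batch["interaction"]["p_value"][j],
                              table.loc["genotype:age", "p_value"])


class TestBonferroni:
    def test_identical_groups_adjusted_p_is_one(self):
        # every cell holds {4, 5, 6}: all cell means exactly equal
        vals = [4.0, 5.0, 6.0] * 8
        fa = ["x"] * 12 + ["y"] * 12
        fb = (["u"] * 3 + ["v"] * 3) * 4
        res = ms.bonferroni_posthoc(
            vals, fa, fb,
            comparisons=[(("x", "u"), ("y", "u")), (("x", "v"), ("y", "v"))])
        assert all(r.p_adjusted > 0.99 for r in res)

    def test_single_comparison_has_multiplier_one(self):
        rng = np.random.default_rng(8)
        vals = list(rng.normal(0, 1, 20))
        fa = ["x"] * 10 + ["y"] * 10
        fb = ["u", "v"] * 10
        res = ms.bonferroni_posthoc(vals, fa, fb,
                                    comparisons=[(("x", "u"), ("y", "u"))])
        assert np.isclose(res[0].p_adjusted, min(1.0, res[0].p_unadjusted))

    def test_empty_cell_comparison_rejected(self):
        vals = [1.0, 2.0, 3.0, 4.0, 1.5, 2.5, 3.5, 4.5]
        fa = ["x"] * 4 + ["y"] * 4
        fb = ["u", "u", "v", "v"] * 2
        with pytest.raises(ValueError, match="empty cell|empty design cell"):
            ms.bonferroni_posthoc(vals, fa, fb,
                                  comparisons=[(("x", "u"), ("z", "u"))])

    def test_family_wise_error_controlled_under_null(self):
        # 2 comparisons on pure-noise cohorts: FWER at alpha stays <= alpha
        rng = np.random.default_rng(10)
        rejections = 0
        reps = 400
        fa = np.array(["x"] * 20 + ["y"] * 20)
        fb = np.array((["u"] * 10 + ["v"] * 10) * 2)
        comparisons = [(("x", "u"), ("y", "u")), (("x", "v"), ("y", "v"))]
        for _ in range(reps):
            vals = rng.normal(0, 1, 40)
            res = ms.bonferroni_posthoc(vals, fa, fb, comparisons=comparisons)
            rejections += any(r.p_adjusted < 0.05 for r in res)
        fwer = rejections / reps
        assert fwer <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / reps)
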