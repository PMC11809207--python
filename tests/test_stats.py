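"""PCA, confidence ellipses and group-comparison statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitomorph.core import ContractError, ParameterError
from mitomorph.stats import (compare_groups, confidence_ellipse,
                             ellipse_overlap, fit_pca, project, sidak_adjust)


def frame(X, cols=None):
    cols = cols or [f"f{i}" for i in range(X.shape[1])]
    return pd.DataFrame(X, columns=cols), cols


class TestPCA:
    def test_axis_aligned_variances_closed_form(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=400)
        b = rng.normal(size=400)
        a -= a.mean()
        b -= b.mean()
        b -= a * (a @ b) / (a @ a)  # exactly decorrelate
        X = np.column_stack([2.0 * a / a.std(ddof=1), b / b.std(ddof=1)])
        df, cols = frame(X)
        model = fit_pca(df, columns=cols, standardize=False)
        assert model.explained_variance_ratio_[0] == pytest.approx(0.8, abs=1e-12)

    def test_duplicated_rows_identical_scores(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 4))
        X2 = np.vstack([X, X[3]])
        df, cols = frame(X2)
        model = fit_pca(df, columns=cols)
        np.testing.assert_allclose(model.scores_.iloc[3, :4].to_numpy(float),
                                   model.scores_.iloc[-1, :4].to_numpy(float))

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_loadings_orthonormal(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(12, 5))
        df, cols = frame(X)
        model = fit_pca(df, columns=cols)
        k = model.components_.shape[0]
        np.testing.assert_allclose(model.components_ @ model.components_.T,
                                   np.eye(k), atol=1e-8)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 6))
        df, cols = frame(X)
        model = fit_pca(df, columns=cols)
        Z = (X - model.mean_) / model.scale_
        Z_hat = model.scores_[[f"PC{i+1}" for i in range(6)]].to_numpy() \
            @ model.components_
        np.testing.assert_allclose(Z_hat, Z, atol=1e-8)

    def test_constant_column_rejected_when_standardizing(self):
        X = np.random.default_rng(3).normal(size=(8, 3))
        X[:, 1] = 5.0
        df, cols = frame(X)
        with pytest.raises(ContractError):
            fit_pca(df, columns=cols)

    def test_projection_reproduces_training_scores(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(15, 4))
        df, cols = frame(X)
        model = fit_pca(df, columns=cols)
        proj = project(model, df)
        np.testing.assert_allclose(
            proj.to_numpy(float),
            model.scores_[proj.columns].to_numpy(float), atol=1e-10)

    def test_column_mean_projects_to_origin(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(15, 4))
        df, cols = frame(X)
        model = fit_pca(df, columns=cols)
        mean_row = pd.DataFrame([X.mean(axis=0)], columns=cols)
        np.testing.assert_allclose(project(model, mean_row).to_numpy(float),
                                   0.0, atol=1e-10)

    def test_column_mismatch_rejected(self):
        rng = np.random.default_rng(6)
        df, cols = frame(rng.normal(size=(10, 3)))
        model = fit_pca(df, columns=cols)
        with pytest.raises(ContractError):
            project(model, df.rename(columns={cols[0]: "other"}))

    def test_sign_convention_stable_across_fits(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 5))
        df, cols = frame(X)
        m1 = fit_pca(df, columns=cols)
        m2 = fit_pca(df.iloc[::-1].reset_index(drop=True), columns=cols)
        np.testing.assert_allclose(m1.components_, m2.components_, atol=1e-8)


class TestEllipses:
    def test_isotropic_group_circular(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(4000, 2))
        e = confidence_ellipse(pts)["all"]
        assert e.radii[0] == pytest.approx(e.radii[1], rel=0.05)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(300, 2)) @ np.array([[1.5, 0.3], [0.0, 0.7]])
        e1 = confidence_ellipse(pts)["all"]
        e2 = confidence_ellipse(2.0 * pts)["all"]
        np.testing.assert_allclose(e2.radii, 2.0 * e1.radii, rtol=1e-9)

    def test_small_group_skipped_with_warning(self):
        pts = np.zeros((5, 2))
        groups = ["a", "a", "a", "b", "b"]
        with pytest.warns(UserWarning):
            out = confidence_ellipse(pts + np.random.default_rng(2).normal(size=(5, 2)),
                                     groups)
        assert "b" not in out and "a" in out

    def test_coverage_close_to_level(self):
        rng = np.random.default_rng(3)
        pts = rng.multivariate_normal([1, -2], [[2.0, 0.6], [0.6, 1.0]], size=20_000)
        e = confidence_ellipse(pts, level=0.95)["all"]
        assert e.contains(pts).mean() == pytest.approx(0.95, abs=0.01)

    def test_identical_groups_heavily_overlap(self):
        rng = np.random.default_rng(4)
        a = confidence_ellipse(rng.normal(size=(200, 2)))["all"]
        b = confidence_ellipse(rng.normal(size=(200, 2)))["all"]
        assert ellipse_overlap(a, b) > 0.8

    def test_distant_groups_disjoint(self):
        rng = np.random.default_rng(5)
        a = confidence_ellipse(rng.normal(size=(200, 2)))["all"]
        b = confidence_ellipse(rng.normal(size=(200, 2)) + 20.0)["all"]
        assert ellipse_overlap(a, b) == 0.0


class TestComparisons:
    def test_sidak_single_comparison_unchanged(self):
        assert sidak_adjust(0.03, 1) == pytest.approx(0.03)

    def test_sidak_increases_p(self):
        assert sidak_adjust(0.03, 4) > 0.03

    def test_identical_groups_t_zero(self):
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0] * 2,
                           "g": ["a"] * 3 + ["b"] * 3})
        res = compare_groups(df, "v", ["g"], test="t_test")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_two_way_anova_matches_hand_computed_f(self):
        # balanced 2×2, n=2/cell; hand-computed type II sums of squares
        rows = []
        data = {("a", "x"): [1.0, 2.0], ("a", "y"): [2.0, 3.0],
                ("b", "x"): [4.0, 5.0], ("b", "y"): [7.0, 8.0]}
        for (f1, f2), vals in data.items():
            rows += [{"f1": f1, "f2": f2, "v": v} for v in vals]
        df = pd.DataFrame(rows)
        # oracle: SS_A = Σ n_a (mean_a − grand)², MSE from within-cell variance
        grand = df["v"].mean()
        ss_a = sum(len(g) * (g["v"].mean() - grand) ** 2
                   for _, g in df.groupby("f1"))
        sse = sum(((g["v"] - g["v"].mean()) ** 2).sum()
                  for _, g in df.groupby(["f1", "f2"]))
        f_oracle = (ss_a / 1) / (sse / 4)
        res = compare_groups(df, "v", ["f1", "f2"], test="two_way_anova")
        assert res.statistic == pytest.approx(f_oracle, rel=1e-9)
        assert all(c.p_adjusted >= c.p_raw for c in res.contrasts)

    def test_kruskal_with_sidak_posthoc(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({
            "v": np.concatenate([rng.normal(0, 1, 20), rng.normal(3, 1, 20),
                                 rng.normal(0.2, 1, 20)]),
            "g": ["a"] * 20 + ["b"] * 20 + ["c"] * 20})
        res = compare_groups(df, "v", ["g"], test="kruskal")
        assert res.p_value < 0.01
        assert len(res.contrasts) == 3
        for c in res.contrasts:
            assert 0 <= c.p_raw <= c.p_adjusted <= 1

    def test_empty_cell_design_rejected(self):
        # cell (b, y) has no observations
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0, 4.0],
                           "f1": ["a", "a", "b", "b"],
                           "f2": ["x", "y", "x", "x"]})
        with pytest.raises(ParameterError):
            compare_groups(df, "v", ["f1", "f2"], test="two_way_anova")
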