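import numpy as np
import pandas as pd
import pytest
from scipy.stats import ortho_group
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)

from tarsomorph import (
    classify,
    da_project,
    lda_fit,
    pca_covariance,
    rda_fit,
    rda_optimize,
    standardize_table,
)


def frame(arr, prefix="v"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"t{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
    )


@pytest.fixture(scope="module")
def gaussian_groups():
    """Three well-separated 4-D Gaussian clusters, 15 points each."""
    rng = np.random.default_rng(3)
    means = np.array([[0, 0, 0, 0], [6, 0, 0, 0], [0, 6, 0, 0]], dtype=float)
    X = np.vstack([m + rng.standard_normal((15, 4)) for m in means])
    y = pd.Series(np.repeat(["a", "b", "c"], 15))
    df = frame(X)
    y.index = df.index
    return df, y


class TestPCA:
    def test_collinear_points_load_on_single_axis(self):
        t = np.linspace(-2, 2, 9)
        ord_ = pca_covariance(frame(np.column_stack([t, t])))
        assert ord_.variance_fraction[0] == pytest.approx(1.0)

    def test_trace_conservation(self):
        X = frame(np.random.default_rng(0).normal(size=(30, 5)))
        ord_ = pca_covariance(X)
        assert ord_.scores.var(ddof=1).sum() == pytest.approx(
            X.var(ddof=1).sum()
        )

    def test_reconstruction(self):
        X = frame(np.random.default_rng(1).normal(size=(25, 6)))
        ord_ = pca_covariance(X)
        rebuilt = ord_.scores.to_numpy() @ ord_.axes.to_numpy().T + ord_.center.to_numpy()
        np.testing.assert_allclose(rebuilt, X.to_numpy(), atol=1e-8)

    def test_rotation_leaves_eigenvalues_unchanged(self):
        X = np.random.default_rng(2).normal(size=(40, 5))
        Q = ortho_group.rvs(5, random_state=4)
        v1 = pca_covariance(frame(X)).variance_fraction
        v2 = pca_covariance(frame(X @ Q)).variance_fraction
        np.testing.assert_allclose(v1, v2, atol=1e-10)

    def test_sign_convention_largest_coefficient_positive(self):
        X = frame(np.random.default_rng(3).normal(size=(30, 4)))
        axes = pca_covariance(X).axes.to_numpy()
        for j in range(axes.shape[1]):
            assert axes[np.argmax(np.abs(axes[:, j])), j] > 0


class TestLDA:
    def test_two_univariate_groups_recover_separation(self):
        rng = np.random.default_rng(5)
        X = frame(np.concatenate([rng.normal(0, 1, 50), rng.normal(10, 1, 50)])[:, None])
        y = pd.Series(["a"] * 50 + ["b"] * 50, index=X.index)
        ord_, _ = lda_fit(X, y)
        assert ord_.scores.shape[1] == 1
        sep = abs(
            ord_.scores[y == "a"].mean().iloc[0] - ord_.scores[y == "b"].mean().iloc[0]
        )
        # closed-form Fisher oracle in 1-D: mean gap over pooled within-sd
        xa, xb = X.to_numpy()[:50, 0], X.to_numpy()[50:, 0]
        pooled_sd = np.sqrt((xa.var(ddof=1) * 49 + xb.var(ddof=1) * 49) / 98)
        oracle = abs(xa.mean() - xb.mean()) / pooled_sd
        assert sep == pytest.approx(oracle, rel=1e-8)
        assert sep == pytest.approx(10.0, rel=0.2)  # population value

    def test_variance_fractions_sum_to_one(self, gaussian_groups):
        X, y = gaussian_groups
        ord_, _ = lda_fit(X, y)
        assert ord_.scores.shape[1] == 2  # g - 1 axes
        assert ord_.variance_fraction.sum() == pytest.approx(1.0)

    def test_pseudo_inverse_fallback_warns(self):
        rng = np.random.default_rng(6)
        X = frame(rng.normal(size=(8, 10)))  # variables > N - g
        y = pd.Series(["a"] * 4 + ["b"] * 4, index=X.index)
        with pytest.warns(RuntimeWarning, match="pseudo-inverse"):
            lda_fit(X, y)


class TestProjection:
    def test_training_rows_reproduce_fitted_scores(self, gaussian_groups):
        X, y = gaussian_groups
        ord_, _ = lda_fit(X, y)
        np.testing.assert_allclose(
            da_project(ord_, X).to_numpy(), ord_.scores.to_numpy(), atol=1e-10
        )

    def test_point_at_group_mean_projects_to_centroid(self, gaussian_groups):
        X, y = gaussian_groups
        ord_, _ = lda_fit(X, y)
        mean_a = X[y == "a"].mean()
        new = pd.DataFrame([mean_a], index=["fossil"], columns=X.columns)
        centroid = ord_.scores[y == "a"].mean()
        np.testing.assert_allclose(
            da_project(ord_, new).to_numpy()[0], centroid.to_numpy(), atol=1e-10
        )

    def test_matches_manual_matrix_arithmetic(self, gaussian_groups):
        X, y = gaussian_groups
        ord_, _ = lda_fit(X, y)
        new = frame(np.random.default_rng(7).normal(size=(3, 4)))
        manual = (new.to_numpy() - X.to_numpy().mean(axis=0)) @ ord_.axes.to_numpy()
        np.testing.assert_allclose(da_project(ord_, new).to_numpy(), manual, atol=1e-10)


class TestRDA:
    def test_pooled_limit_matches_linear_rule(self, gaussian_groups):
        X, y = gaussian_groups
        model = rda_fit(X, y, gamma=0.0, lam=1.0)
        pooled = model.pooled_cov
        for lb in model.group_labels:
            np.testing.assert_allclose(model.group_covs[lb], pooled, atol=1e-12)
        grid = frame(np.random.default_rng(8).uniform(-3, 9, size=(200, 4)))
        ours, _ = classify(model, grid)
        sk = LinearDiscriminantAnalysis().fit(X.to_numpy(), y.to_numpy())
        assert (ours.to_numpy() == sk.predict(grid.to_numpy())).mean() > 0.99

    def test_quadratic_limit_matches_per_group_rule(self, gaussian_groups):
        X, y = gaussian_groups
        model = rda_fit(X, y, gamma=0.0, lam=0.0)
        grid = frame(np.random.default_rng(9).uniform(-3, 9, size=(200, 4)))
        ours, _ = classify(model, grid)
        sk = QuadraticDiscriminantAnalysis(store_covariance=True).fit(
            X.to_numpy(), y.to_numpy()
        )
        assert (ours.to_numpy() == sk.predict(grid.to_numpy())).mean() > 0.99

    def test_spherical_limit_ranks_by_scaled_distance(self, gaussian_groups):
        X, y = gaussian_groups
        model = rda_fit(X, y, gamma=1.0, lam=0.0, priors="uniform")
        for lb in model.group_labels:
            S = model.group_covs[lb]
            assert np.allclose(S, S[0, 0] * np.eye(S.shape[0]))
        point = frame(np.array([[5.5, 0.5, 0.0, 0.0]]))
        pred, _ = classify(model, point)
        assert pred.iloc[0] == "b"

    def test_posteriors_sum_to_one_and_favor_own_mean(self, gaussian_groups):
        X, y = gaussian_groups
        model = rda_fit(X, y, gamma=0.2, lam=0.5)
        pts = frame(np.random.default_rng(10).normal(size=(20, 4)))
        _, post = classify(model, pts)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-10)
        at_mean = pd.DataFrame(
            [X[y == "b"].mean()], index=["m"], columns=X.columns
        )
        _, post_b = classify(model, at_mean)
        assert post_b.loc["m", "b"] > 0.99

    def test_equidistant_point_splits_posteriors(self):
        rng = np.random.default_rng(11)
        X = frame(np.vstack([rng.normal(-3, 1, (30, 2)), rng.normal(3, 1, (30, 2))]))
        y = pd.Series(["a"] * 30 + ["b"] * 30, index=X.index)
        # symmetrize: mirror group b as the reflection of group a
        Xs = X.copy()
        Xs.iloc[30:] = -X.iloc[:30].to_numpy()
        model = rda_fit(Xs, y, gamma=0.0, lam=1.0, priors="uniform")
        _, post = classify(model, frame(np.zeros((1, 2))))
        np.testing.assert_allclose(post.to_numpy()[0], [0.5, 0.5], atol=1e-10)


class TestRDAOptimize:
    def test_separable_groups_reach_zero_apparent_error(self, gaussian_groups):
        X, y = gaussian_groups
        model = rda_optimize(
            X, y, grid=[(g, l) for g in (0, 0.5, 1) for l in (0, 0.5, 1)],
            folds=3, seed=0,
        )
        assert model.error_estimates["apparent"] == 0.0

    def test_cv_error_tracks_bayes_error(self):
        # two overlapping 1-D Gaussians, means 0 and 2, unit sd: Bayes error
        # = Phi(-1) = 0.1587
        rng = np.random.default_rng(12)
        X = frame(np.concatenate([rng.normal(0, 1, 500), rng.normal(2, 1, 500)])[:, None])
        y = pd.Series(["a"] * 500 + ["b"] * 500, index=X.index)
        model = rda_optimize(X, y, grid=[(0.0, 1.0)], folds=10, seed=1)
        assert model.error_estimates["crossval"] == pytest.approx(0.1587, abs=0.04)

    def test_synthetic_six_groups_high_accuracy(self):
        # group means 4 within-group sds apart: accuracy should exceed 95%
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            means = 4.0 * np.eye(6)
            X = frame(np.vstack([m + rng.standard_normal((20, 6)) for m in means]))
            y = pd.Series(np.repeat(list("abcdef"), 20), index=X.index)
            model = rda_fit(X, y, gamma=0.0, lam=1.0)
            pred, _ = classify(model, X)
            accs.append((pred == y).mean())
        assert np.mean(accs) > 0.95

    def test_deterministic_given_seed(self, gaussian_groups):
        X, y = gaussian_groups
        g = [(0.0, 1.0), (0.5, 0.5), (1.0, 0.0)]
        m1 = rda_optimize(X, y, grid=g, folds=3, seed=5)
        m2 = rda_optimize(X, y, grid=g, folds=3, seed=5)
        assert (m1.gamma, m1.lam) == (m2.gamma, m2.lam)
        assert m1.error_estimates == m2.error_estimates


def test_lda_on_synthetic_study_layout(default_table):
    """End-to-end: standardized full-size table yields a 5-axis DF space."""
    table, truth = default_table
    shape = standardize_table(table)
    extant = shape.values[~table.is_fossil.to_numpy()]
    ord_, model = lda_fit(extant, table.locomotor[~table.is_fossil])
    assert ord_.scores.shape[1] == 5
    assert ord_.variance_fraction.sum() == pytest.approx(1.0)
    assert model.error_estimates["apparent"] < 0.2
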