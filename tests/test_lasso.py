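"""Penalized logistic path: oracle equivalences, cross-fitting contracts."""

import subprocess
import sys
import textwrap

import numpy as np
import pytest
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from undersmooth._cd import solve_path, lambda_max
from undersmooth.lasso import fit_lasso_path, make_lambda_grid, predict_oof


@pytest.fixture(scope="module")
def logistic_instance():
    rng = np.random.default_rng(42)
    n, p = 200, 3
    X = rng.normal(size=(n, p))
    beta = np.array([1.0, -0.5, 0.25])
    y = (rng.random(n) < expit(0.3 + X @ beta)).astype(float)
    return X, y


class TestSolverOracles:
    def test_unpenalized_matches_logistic_mle(self, logistic_instance):
        X, y = logistic_instance
        coefs, intercepts = solve_path(X, y, np.array([0.0]), tol=1e-12, max_outer=100)
        mle = LogisticRegression(C=1e10, max_iter=5000, tol=1e-12).fit(X, y)
        assert np.abs(coefs[0] - mle.coef_[0]).max() < 1e-4
        assert abs(intercepts[0] - mle.intercept_[0]) < 1e-4

    def test_all_zero_at_lambda_max(self, logistic_instance):
        X, y = logistic_instance
        lam = lambda_max(X, y)
        coefs, intercepts = solve_path(X, y, np.array([lam * 1.0001]))
        assert np.all(coefs[0] == 0)
        # intercept-only fit reproduces the marginal prevalence
        assert expit(intercepts[0]) == pytest.approx(y.mean(), abs=1e-6)

    def test_l1_norm_monotone_in_lambda(self, logistic_instance):
        X, y = logistic_instance
        lams = make_lambda_grid(X, y, grid_size=30, lambda_min_ratio=1e-3)
        coefs, _ = solve_path(X, y, lams)
        norms = np.abs(coefs).sum(axis=1)
        assert np.all(np.diff(norms) >= -1e-6)

    def test_sparse_and_dense_kernels_agree(self):
        rng = np.random.default_rng(7)
        X = (rng.random((400, 30)) < 0.2).astype(float)
        y = (rng.random(400) < 0.4).astype(float)
        lams = make_lambda_grid(X, y, grid_size=20, lambda_min_ratio=1e-2)
        import undersmooth._cd as cd
        sparse = solve_path(X, y, lams)
        old = cd._SPARSE_DENSITY
        try:
            cd._SPARSE_DENSITY = -1.0  # force the dense kernel
            dense = solve_path(X, y, lams)
        finally:
            cd._SPARSE_DENSITY = old
        assert np.abs(sparse[0] - dense[0]).max() < 1e-10
        assert np.abs(sparse[1] - dense[1]).max() < 1e-10

    def test_matches_r_glmnet_on_small_instance(self, tmp_path, logistic_instance):
        """Independent oracle: r-glmnet on the identical data and grid."""
        X, y = logistic_instance
        lams = make_lambda_grid(X, y, grid_size=10, lambda_min_ratio=1e-2)
        np.savetxt(tmp_path / "X.csv", X, delimiter=",")
        np.savetxt(tmp_path / "y.csv", y)
        np.savetxt(tmp_path / "lam.csv", lams)
        rscript = textwrap.dedent(f"""
            suppressMessages(library(glmnet))
            X <- as.matrix(read.csv('{tmp_path}/X.csv', header=FALSE))
            y <- scan('{tmp_path}/y.csv', quiet=TRUE)
            lam <- scan('{tmp_path}/lam.csv', quiet=TRUE)
            fit <- glmnet(X, y, family='binomial', standardize=FALSE, lambda=lam,
                          thresh=1e-12)
            out <- as.matrix(coef(fit))
            write.csv(t(out), '{tmp_path}/coefs.csv', row.names=FALSE)
        """)
        (tmp_path / "fit.R").write_text(rscript)
        res = subprocess.run(
            ["Rscript", str(tmp_path / "fit.R")], capture_output=True, text=True
        )
        if res.returncode != 0:
            pytest.skip(f"Rscript/glmnet unavailable: {res.stderr[:200]}")
        ours_c, ours_i = solve_path(X, y, lams, tol=1e-12, max_outer=100)
        theirs = np.loadtxt(tmp_path / "coefs.csv", delimiter=",", skiprows=1)
        assert np.abs(theirs[:, 0] - ours_i).max() < 1e-3
        assert np.abs(theirs[:, 1:] - ours_c).max() < 1e-3


class TestFitLassoPath:
    def test_null_design_gives_marginal_prevalence(self, separable_free_cohort):
        c = separable_free_cohort
        path = fit_lasso_path(c.X, c.A, grid_size=20, seed=0)
        # at lambda_max all penalized coefficients are zero
        assert np.all(path.coefficients[0] == 0)
        oof = predict_oof(path, 0)
        # each fold's prediction is that fold's training prevalence
        assert np.abs(oof - c.A.mean()).max() < 0.05

    def test_strong_single_predictor_recovers_mle(self):
        rng = np.random.default_rng(11)
        n = 10_000
        x = rng.normal(size=(n, 1))
        a = (rng.random(n) < expit(2.0 * x[:, 0])).astype(float)
        path = fit_lasso_path(x, a, grid_size=40, lambda_min_ratio=1e-4, seed=1)
        mle = LogisticRegression(C=1e10, max_iter=2000).fit(x, a)
        assert path.coefficients[-1, 0] == pytest.approx(mle.coef_[0, 0], abs=0.15)

    def test_cv_deviance_argmin_beats_lambda_max(self, small_confounded_cohort):
        c = small_confounded_cohort
        path = fit_lasso_path(c.X, c.A, grid_size=30, seed=2)
        assert path.cv_deviance[path.lambda_cv_index] <= path.cv_deviance[0]
        assert path.lambda_cv_index == int(np.argmin(path.cv_deviance))

    def test_nonzero_count_grows_down_the_path(self, small_confounded_cohort):
        c = small_confounded_cohort
        path = fit_lasso_path(c.X, c.A, grid_size=30, seed=2)
        counts = path.nonzero_counts()
        assert counts[-1] >= counts[0]

    def test_oof_probabilities_are_probabilities(self, small_confounded_cohort):
        path = fit_lasso_path(
            small_confounded_cohort.X, small_confounded_cohort.A, grid_size=15, seed=3
        )
        assert np.all(path.oof_probabilities > 0)
        assert np.all(path.oof_probabilities < 1)

    def test_deterministic_under_seed(self, small_confounded_cohort):
        c = small_confounded_cohort
        p1 = fit_lasso_path(c.X, c.A, grid_size=10, seed=9)
        p2 = fit_lasso_path(c.X, c.A, grid_size=10, seed=9)
        assert np.array_equal(p1.fold_labels, p2.fold_labels)
        assert np.array_equal(p1.oof_probabilities, p2.oof_probabilities)

    def test_leave_one_out_predictions_exclude_own_row(self):
        """Brute-force refit oracle on a 10-row toy with K = n."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 2))
        a = np.array([0, 1, 0, 1, 0, 1, 0, 1, 0, 1], dtype=float)
        lams = make_lambda_grid(X, a, grid_size=5, lambda_min_ratio=0.1)
        path = fit_lasso_path(X, a, folds=5, grid_size=5, lambda_min_ratio=0.1,
                              seed=4, standardize=False)
        for k in np.unique(path.fold_labels):
            mask = path.fold_labels == k
            coefs, ints = solve_path(X[~mask], a[~mask], path.lambdas)
            manual = expit(ints[None, :] + X[mask] @ coefs.T)
            assert np.abs(manual - path.oof_probabilities[mask]) .max() < 1e-6

    def test_single_class_exposure_rejected(self):
        X = np.zeros((20, 2))
        with pytest.raises(ValueError):
            fit_lasso_path(X, np.ones(20))

    def test_zero_column_design_degenerates_to_intercept(self):
        rng = np.random.default_rng(6)
        a = (rng.random(200) < 0.4).astype(float)
        path = fit_lasso_path(np.empty((200, 0)), a)
        assert path.oof_probabilities.shape == (200, 1)
        assert np.abs(path.oof_probabilities[:, 0] - a.mean()).max() < 0.1

    def test_continuous_design_is_standardized_and_backtransformed(self):
        # a column with large scale must not be penalized away relative to
        # a unit-scale column carrying the same signal
        rng = np.random.default_rng(13)
        n = 4000
        z = rng.normal(size=n)
        X = np.column_stack([z * 100.0, rng.normal(size=n)])
        a = (rng.random(n) < expit(z)).astype(float)
        path = fit_lasso_path(X, a, grid_size=30, seed=1)
        assert path.standardized
        # back-transformed coefficient on the scaled column ~ 1/100
        assert path.coefficients[-1, 0] == pytest.approx(0.01, rel=0.3)
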