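"""L1-penalized logistic propensity-score paths with K-fold cross-fitting.

``fit_lasso_path`` fits the penalized logistic model

    minimize  (1/n) * negative log-likelihood(b0, beta)  +  lam * ||beta||_1

over a descending lambda grid and, for every grid point, stores both the
full-data coefficients and *out-of-fold* predicted probabilities: each
subject's propensity comes from a model trained on the other K-1 folds.
Out-of-fold prediction is what the weighting step consumes — it curbs the
overfitting bias that in-sample propensities induce in weighted estimators
once the penalty is relaxed below the cross-validation optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold

from ._cd import lambda_max, solve_path

__all__ = ["LassoPath", "fit_lasso_path", "predict_oof", "make_lambda_grid"]


@dataclass
class LassoPath:
    """A fitted regularization path.

    Attributes
    ----------
    lambdas : (L,) strictly decreasing penalty grid.
    coefficients : (L, p) full-data coefficients, original covariate scale.
    intercepts : (L,) full-data intercepts.
    oof_probabilities : (n, L) held-out propensities, clipped into (0,1).
    fold_labels : (n,) fold assignment in 0..K-1.
    cv_deviance : (L,) mean out-of-fold binomial deviance.
    lambda_cv_index : argmin of ``cv_deviance`` (first index on ties).
    """

    lambdas: np.ndarray
    coefficients: np.ndarray
    intercepts: np.ndarray
    oof_probabilities: np.ndarray
    fold_labels: np.ndarray
    cv_deviance: np.ndarray
    lambda_cv_index: int
    standardized: bool = False

    @property
    def n_lambdas(self) -> int:
        return len(self.lambdas)

    def nonzero_counts(self) -> np.ndarray:
        return (self.coefficients != 0).sum(axis=1)

    def predict_proba(self, X: np.ndarray, lambda_index: int, clip: float = 1e-6) -> np.ndarray:
        """Full-data-model propensities at one grid point, clipped."""
        self._check_index(lambda_index)
        p = expit(self.intercepts[lambda_index] + X @ self.coefficients[lambda_index])
        return np.clip(p, clip, 1.0 - clip)

    def _check_index(self, lambda_index: int) -> None:
        if not 0 <= lambda_index < self.n_lambdas:
            raise IndexError(f"lambda_index {lambda_index} outside grid of {self.n_lambdas}")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "lambda": self.lambdas,
                "cv_deviance": self.cv_deviance,
                "nonzero": self.nonzero_counts(),
                "is_cv_choice": np.arange(self.n_lambdas) == self.lambda_cv_index,
            }
        )


def make_lambda_grid(
    X: np.ndarray, a: np.ndarray, grid_size: int = 100, lambda_min_ratio: float = 1e-4
) -> np.ndarray:
    """Log-spaced grid from the null-model entry point lambda_max down."""
    lam_max = lambda_max(X, a)
    if lam_max <= 0:
        # exposure uncorrelated with every column to machine precision
        lam_max = 1e-3
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, grid_size)


def binomial_deviance(a: np.ndarray, p: np.ndarray) -> float:
    """Mean binomial deviance -2/n * loglik."""
    return float(-2.0 * np.mean(a * np.log(p) + (1 - a) * np.log1p(-p)))


def _resolve_standardize(X: np.ndarray, standardize) -> np.ndarray | None:
    """Column scales (1/sd) when standardizing, else None.

    "auto" standardizes only when some column is non-binary: binary designs
    share a common scale already, and leaving them untouched keeps the
    penalty interpretable in log-odds units.
    """
    if standardize == "auto":
        standardize = bool(np.any((X != 0) & (X != 1)))
    if not standardize:
        return None
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return 1.0 / sd


def fit_lasso_path(
    X: np.ndarray,
    a: np.ndarray,
    folds: int = 5,
    grid_size: int = 100,
    lambda_min_ratio: float = 1e-4,
    seed: int = 0,
    clip: float = 1e-6,
    standardize="auto",
    tol: float = 1e-8,
) -> LassoPath:
    """Fit the cross-fitted penalized logistic path.

    The lambda grid is computed once on the full data and reused in every
    fold, so per-lambda quantities are comparable across folds.  Folds are
    stratified on the exposure so both classes appear in each.
    """
    X = np.asarray(X, dtype=np.float64)
    a = np.asarray(a, dtype=np.float64).ravel()
    n = len(a)
    if X.shape[0] != n:
        raise ValueError("X and a have incompatible shapes")
    classes = np.unique(a)
    if not np.isin(classes, (0.0, 1.0)).all() or len(classes) < 2:
        raise ValueError("exposure must contain both classes 0 and 1")

    if X.shape[1] == 0:
        return _intercept_only_path(a, folds, seed, clip)

    inv_sd = _resolve_standardize(X, standardize)
    Xs = X * inv_sd if inv_sd is not None else X

    lambdas = make_lambda_grid(Xs, a, grid_size, lambda_min_ratio)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_labels = np.empty(n, dtype=np.int32)
    oof = np.empty((n, len(lambdas)))
    for k, (train, test) in enumerate(skf.split(Xs, a)):
        fold_labels[test] = k
        coefs, intercepts = solve_path(Xs[train], a[train], lambdas, tol=tol)
        oof[test] = expit(intercepts[None, :] + Xs[test] @ coefs.T)
    oof = np.clip(oof, clip, 1.0 - clip)

    cv_dev = np.array([binomial_deviance(a, oof[:, l]) for l in range(len(lambdas))])
    coefs, intercepts = solve_path(Xs, a, lambdas, tol=tol)
    if inv_sd is not None:
        coefs = coefs * inv_sd[None, :]  # back to original covariate scale

    return LassoPath(
        lambdas=lambdas,
        coefficients=coefs,
        intercepts=intercepts,
        oof_probabilities=oof,
        fold_labels=fold_labels,
        cv_deviance=cv_dev,
        lambda_cv_index=int(np.argmin(cv_dev)),
        standardized=inv_sd is not None,
    )


def _intercept_only_path(a, folds, seed, clip):
    """Degenerate p=0 path: one grid point, fold-mean probabilities."""
    n = len(a)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_labels = np.empty(n, dtype=np.int32)
    oof = np.empty((n, 1))
    for k, (train, test) in enumerate(skf.split(np.zeros((n, 1)), a)):
        fold_labels[test] = k
        oof[test, 0] = a[train].mean()
    oof = np.clip(oof, clip, 1.0 - clip)
    abar = a.mean()
    return LassoPath(
        lambdas=np.array([0.0]),
        coefficients=np.zeros((1, 0)),
        intercepts=np.array([np.log(abar / (1 - abar))]),
        oof_probabilities=oof,
        fold_labels=fold_labels,
        cv_deviance=np.array([binomial_deviance(a, oof[:, 0])]),
        lambda_cv_index=0,
    )


def predict_oof(path: LassoPath, lambda_index: int) -> np.ndarray:
    """Held-out propensities at one grid point (each row's model never saw it)."""
    path._check_index(lambda_index)
    return path.oof_probabilities[:, lambda_index].copy()
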