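"""Scikit-learn-style propensity-score estimator with pluggable tuning.

``LassoPropensityScore`` wraps the penalized path fit, the cross-validated
or balance-based lambda choice, and weight construction behind the usual
fit / predict_proba surface, so it composes with sklearn pipelines and
model selection.  The balance-tuned variants ("max-smd", "mean-smd")
undersmooth: they scan the whole regularization path for the lambda whose
out-of-fold weighted cohort best balances the covariates, typically a
lambda below the deviance optimum.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .balance import select_lambda, weighted_smd_profile
from .lasso import fit_lasso_path
from .weighting import compute_weights, weighted_mean_difference

__all__ = ["LassoPropensityScore"]


class LassoPropensityScore(BaseEstimator):
    """L1-penalized logistic propensity model with CV or balance tuning.

    Parameters
    ----------
    tuning : "cv" (minimum out-of-fold deviance), "max-smd" or "mean-smd"
        (balance-metric undersmoothing).
    weight_scheme : "ipw", "mw" or "ow"; used both to build the balance
        profile during tuning and by :meth:`weights`.
    folds, grid_size, lambda_min_ratio, clip, standardize : path settings.
    balance_denominator : "unweighted" (fixed pre-weighting scale) or
        "weighted".

    Attributes (after ``fit``)
    --------------------------
    path_ : the full :class:`~undersmooth.lasso.LassoPath`.
    lambda_index_, lambda_ : the selected grid point.
    coef_, intercept_ : full-data coefficients at the selected lambda.
    oof_propensity_ : out-of-fold propensities at the selected lambda.
    balance_report_ : balance profile (balance tuning only).
    """

    def __init__(
        self,
        tuning: str = "cv",
        weight_scheme: str = "ipw",
        folds: int = 5,
        grid_size: int = 100,
        lambda_min_ratio: float = 1e-4,
        clip: float = 1e-6,
        standardize="auto",
        balance_denominator: str = "unweighted",
        random_state: int = 0,
    ):
        self.tuning = tuning
        self.weight_scheme = weight_scheme
        self.folds = folds
        self.grid_size = grid_size
        self.lambda_min_ratio = lambda_min_ratio
        self.clip = clip
        self.standardize = standardize
        self.balance_denominator = balance_denominator
        self.random_state = random_state

    def fit(self, X, a):
        X = np.asarray(X, dtype=np.float64)
        a = np.asarray(a).ravel()
        self.path_ = fit_lasso_path(
            X,
            a,
            folds=self.folds,
            grid_size=self.grid_size,
            lambda_min_ratio=self.lambda_min_ratio,
            seed=self.random_state,
            clip=self.clip,
            standardize=self.standardize,
        )
        if self.tuning == "cv":
            self.lambda_index_ = self.path_.lambda_cv_index
            self.balance_report_ = None
        elif self.tuning in ("max-smd", "mean-smd"):
            self.balance_report_ = weighted_smd_profile(
                X, a, self.path_, self.weight_scheme, denominator=self.balance_denominator
            )
            self.lambda_index_ = select_lambda(self.balance_report_, self.tuning.split("-")[0])
        else:
            raise ValueError(f"unknown tuning rule {self.tuning!r}")
        self.lambda_ = float(self.path_.lambdas[self.lambda_index_])
        self.coef_ = self.path_.coefficients[self.lambda_index_]
        self.intercept_ = float(self.path_.intercepts[self.lambda_index_])
        self.oof_propensity_ = self.path_.oof_probabilities[:, self.lambda_index_]
        self.n_features_in_ = X.shape[1]
        self._a = a
        return self

    def predict_proba(self, X) -> np.ndarray:
        """(n, 2) class probabilities from the full-data model."""
        check_is_fitted(self, "coef_")
        p1 = self.path_.predict_proba(np.asarray(X, dtype=np.float64), self.lambda_index_, self.clip)
        return np.column_stack([1.0 - p1, p1])

    def propensity(self, X=None) -> np.ndarray:
        """Propensities; with no argument, the out-of-fold training values."""
        check_is_fitted(self, "coef_")
        if X is None:
            return self.oof_propensity_.copy()
        return self.predict_proba(X)[:, 1]

    def weights(self, scheme: str | None = None) -> np.ndarray:
        """PS weights for the training rows from out-of-fold propensities."""
        check_is_fitted(self, "coef_")
        return compute_weights(self.oof_propensity_, self._a, scheme or self.weight_scheme)

    def effect(self, y, scheme: str | None = None):
        """Weighted mean-difference estimate on the training cohort."""
        scheme = scheme or self.weight_scheme
        return weighted_mean_difference(
            np.asarray(y, dtype=np.float64), self._a, self.weights(scheme), scheme,
            lambda_used=self.lambda_,
        )
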