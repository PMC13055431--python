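"""Covariate balance after PS weighting, and balance-based lambda selection.

For a binary covariate k with prevalences p1 (exposed) and p0 (unexposed)
the standardized difference is

    s_k = (p1 - p0) / sqrt((p1*(1-p1) + p0*(1-p0)) / 2),

and after weighting the numerator uses weighted prevalences.  For a general
column the same formula applies with arm variances in place of p(1-p)
(identical for 0/1 data).  Two scalar balance metrics summarize a weighted
cohort: the largest absolute standardized difference, max_k |s_k|, and the
average, (1/d) sum_k |s_k|.  Undersmoothing a LASSO propensity model by
balance means scanning the regularization path and choosing the lambda
whose out-of-fold weighted cohort minimizes one of these metrics — in
practice a lambda at or below the cross-validation optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lasso import LassoPath
from .weighting import compute_weights

__all__ = [
    "standardized_difference",
    "weighted_smd_profile",
    "select_lambda",
    "BalanceReport",
    "smd_columns",
]

_TIE_TOL = 1e-10


@dataclass
class BalanceReport:
    """Per-lambda standardized differences and the two balance metrics."""

    smd_matrix: np.ndarray  # (L, d) signed standardized differences
    metric_max: np.ndarray  # (L,) max_k |s_k|
    metric_mean: np.ndarray  # (L,) mean_k |s_k|
    valid: np.ndarray  # (L,) lambdas with positive weight mass in both arms
    selected_index_max: int
    selected_index_mean: int
    weight_scheme: str = "ipw"

    def to_frame(self, lambdas: np.ndarray | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "metric_max": self.metric_max,
                "metric_mean": self.metric_mean,
                "valid": self.valid,
            }
        )
        if lambdas is not None:
            df.insert(0, "lambda", lambdas)
        return df


def standardized_difference(p_exposed: float, p_unexposed: float) -> float:
    """Standardized difference of two prevalences (dimensionless)."""
    if not (0 <= p_exposed <= 1 and 0 <= p_unexposed <= 1):
        raise ValueError("prevalences must lie in [0,1]")
    var = (p_exposed * (1 - p_exposed) + p_unexposed * (1 - p_unexposed)) / 2.0
    if var <= 0.0:
        if p_exposed == p_unexposed:
            return 0.0
        raise ValueError("degenerate covariate: both prevalences are 0/1 but unequal")
    return (p_exposed - p_unexposed) / np.sqrt(var)


def smd_columns(
    X: np.ndarray, a: np.ndarray, weights: np.ndarray, denominator: str = "unweighted"
) -> np.ndarray:
    """Signed standardized difference of every column under given weights.

    The numerator always uses weighted arm means.  ``denominator`` chooses
    between the unweighted (pre-weighting) pooled variance — the usual
    convention, keeping the scale fixed while lambda varies — and the fully
    weighted variant.  Columns degenerate in both arms contribute 0.
    """
    X = np.asarray(X, dtype=np.float64)
    a = np.asarray(a)
    w = np.asarray(weights, dtype=np.float64)
    exposed = a == 1

    num = _weighted_mean(X[exposed], w[exposed]) - _weighted_mean(X[~exposed], w[~exposed])
    if denominator == "unweighted":
        v1 = X[exposed].var(axis=0)
        v0 = X[~exposed].var(axis=0)
    elif denominator == "weighted":
        v1 = _weighted_var(X[exposed], w[exposed])
        v0 = _weighted_var(X[~exposed], w[~exposed])
    else:
        raise ValueError("denominator must be 'unweighted' or 'weighted'")
    denom = np.sqrt((v1 + v0) / 2.0)
    out = np.zeros(X.shape[1])
    ok = denom > 0
    out[ok] = num[ok] / denom[ok]
    return out


def _weighted_mean(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    return (w @ X) / w.sum()


def _weighted_var(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    m = _weighted_mean(X, w)
    return (w @ (X - m) ** 2) / w.sum()


def weighted_smd_profile(
    X: np.ndarray,
    a: np.ndarray,
    path: LassoPath,
    scheme: str = "ipw",
    denominator: str = "unweighted",
) -> BalanceReport:
    """Balance of the out-of-fold weighted cohort at every lambda.

    ``X`` must be the matrix the path was fitted on (raw covariates, or the
    expanded indicator basis when that is what the PS model saw).
    """
    a = np.asarray(a)
    if path.oof_probabilities.shape[0] != len(a):
        raise ValueError("path was fitted on a different number of rows")
    L = path.n_lambdas
    d = X.shape[1]
    smd = np.zeros((L, d))
    metric_max = np.full(L, np.inf)
    metric_mean = np.full(L, np.inf)
    valid = np.zeros(L, dtype=bool)
    for l in range(L):
        w = compute_weights(path.oof_probabilities[:, l], a, scheme)
        if w[a == 1].sum() <= 0 or w[a == 0].sum() <= 0:
            continue
        s = smd_columns(X, a, w, denominator=denominator)
        smd[l] = s
        metric_max[l] = np.abs(s).max()
        metric_mean[l] = np.abs(s).mean()
        valid[l] = True
    report = BalanceReport(
        smd_matrix=smd,
        metric_max=metric_max,
        metric_mean=metric_mean,
        valid=valid,
        selected_index_max=0,
        selected_index_mean=0,
        weight_scheme=scheme,
    )
    report.selected_index_max = select_lambda(report, "max")
    report.selected_index_mean = select_lambda(report, "mean")
    return report


def select_lambda(report: BalanceReport, criterion: str = "max") -> int:
    """Grid index minimizing the chosen balance metric.

    Ties within 1e-10 break toward the smallest index, i.e. the largest
    lambda (most regularization) achieving the minimum.
    """
    if criterion == "max":
        values = report.metric_max
    elif criterion == "mean":
        values = report.metric_mean
    else:
        raise ValueError("criterion must be 'max' or 'mean'")
    if not report.valid.any():
        raise ValueError("no lambda produced a valid weighted cohort")
    finite = np.where(report.valid, values, np.inf)
    best = finite.min()
    return int(np.flatnonzero(finite <= best + _TIE_TOL)[0])


def love_plot_table(
    X: np.ndarray,
    a: np.ndarray,
    weights: np.ndarray,
    names: list[str] | None = None,
) -> pd.DataFrame:
    """Per-covariate unadjusted vs weighted absolute SMD (Love-plot data)."""
    unadj = smd_columns(X, a, np.ones(len(a)))
    adj = smd_columns(X, a, weights)
    if names is None:
        names = [f"X{j + 1}" for j in range(X.shape[1])]
    return pd.DataFrame(
        {"covariate": names, "unadjusted_smd": np.abs(unadj), "weighted_smd": np.abs(adj)}
    )
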