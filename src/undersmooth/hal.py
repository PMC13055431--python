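"""Zero-order indicator basis expansion (highly-adaptive-LASSO style).

Each continuous covariate contributes indicator columns I(x >= knot) at
empirical-quantile knots; binary covariates contribute their identity
column.  Products of indicators from distinct covariates, up to
``max_degree``, add interaction columns.  Fitting an L1-penalized logistic
model on this expansion approximates an arbitrary bounded-variation logit
with piecewise-constant sections, which is how a nonlinear propensity
surface is handled without specifying its functional form.

This is a deliberately simplified expansion — quantile-placed knots with a
per-covariate budget rather than knots at every observed value — so column
counts stay manageable; the approximation is documented in the methods
note.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["IndicatorBasis", "expand_basis", "apply_basis", "BasisMatrix"]


@dataclass
class BasisMatrix:
    """An evaluated indicator basis plus the specs to re-evaluate it.

    ``column_specs[c]`` is a tuple of (covariate_index, knot) pairs; the
    column equals the product of I(x_j >= knot) over its pairs.
    """

    columns: np.ndarray
    column_specs: list[tuple[tuple[int, float], ...]]
    parent_dimension: int

    @property
    def n_basis(self) -> int:
        return len(self.column_specs)


class IndicatorBasis(TransformerMixin, BaseEstimator):
    """Transformer producing the zero-order indicator expansion.

    Parameters
    ----------
    max_degree : highest interaction order (1 = main effects only).
    knots_per_covariate : knot budget per continuous covariate; actual
        knots are empirical quantiles, capped at the number of distinct
        values.
    """

    def __init__(self, max_degree: int = 2, knots_per_covariate: int = 25):
        self.max_degree = max_degree
        self.knots_per_covariate = knots_per_covariate

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if self.max_degree < 1 or self.knots_per_covariate < 1:
            raise ValueError("max_degree and knots_per_covariate must be >= 1")
        n, d = X.shape

        # per-covariate univariate indicator specs
        per_cov: list[list[tuple[int, float]]] = []
        for j in range(d):
            col = X[:, j]
            uniq = np.unique(col)
            if len(uniq) <= 1:
                per_cov.append([])  # constant column contributes nothing
                continue
            if set(uniq.tolist()) <= {0.0, 1.0}:
                per_cov.append([(j, 1.0)])  # identity column of a binary covariate
                continue
            k = min(self.knots_per_covariate, len(uniq))
            if k >= len(uniq):
                knots = uniq  # I(x >= min) is constant and dropped by dedupe
            else:
                qs = np.quantile(col, np.linspace(0.0, 1.0, k + 2)[1:-1])
                knots = np.unique(qs)
            per_cov.append([(j, float(t)) for t in knots])

        # all interaction products of specs from distinct covariates
        specs: list[tuple[tuple[int, float], ...]] = []
        for j in range(d):
            for s in per_cov[j]:
                specs.append((s,))
        degree_prev = [(spec, spec[-1][0]) for spec in specs]
        for _ in range(2, self.max_degree + 1):
            nxt = []
            for spec, last_j in degree_prev:
                for j in range(last_j + 1, d):
                    for s in per_cov[j]:
                        nxt.append((spec + (s,), j))
            specs.extend(spec for spec, _ in nxt)
            degree_prev = nxt

        cols = _evaluate(specs, X)
        keep = _dedupe_mask(cols)
        self.column_specs_ = [s for s, k in zip(specs, keep) if k]
        self.n_features_in_ = d
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(f"X must have {self.n_features_in_} columns")
        return _evaluate(self.column_specs_, X)

    def to_json(self, path) -> None:
        payload = {
            "parent_dimension": self.n_features_in_,
            "max_degree": self.max_degree,
            "knots_per_covariate": self.knots_per_covariate,
            "column_specs": [[list(pair) for pair in spec] for spec in self.column_specs_],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "IndicatorBasis":
        with open(path) as fh:
            payload = json.load(fh)
        obj = cls(payload["max_degree"], payload["knots_per_covariate"])
        obj.column_specs_ = [
            tuple((int(j), float(t)) for j, t in spec) for spec in payload["column_specs"]
        ]
        obj.n_features_in_ = payload["parent_dimension"]
        return obj


def _evaluate(specs, X: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    out = np.empty((n, len(specs)))
    for c, spec in enumerate(specs):
        col = np.ones(n)
        for j, knot in spec:
            col *= X[:, j] >= knot
        out[:, c] = col
    return out


def _dedupe_mask(cols: np.ndarray) -> np.ndarray:
    """Drop constant columns and later duplicates of earlier columns."""
    keep = np.ones(cols.shape[1], dtype=bool)
    seen = {}
    for c in range(cols.shape[1]):
        col = cols[:, c]
        if col.min() == col.max():
            keep[c] = False
            continue
        key = col.tobytes()
        if key in seen:
            keep[c] = False
        else:
            seen[key] = c
    return keep


def expand_basis(
    X: np.ndarray, max_degree: int = 2, knots_per_covariate: int = 25
) -> BasisMatrix:
    """Functional wrapper over :class:`IndicatorBasis`."""
    tr = IndicatorBasis(max_degree, knots_per_covariate).fit(X)
    return BasisMatrix(
        columns=tr.transform(X),
        column_specs=tr.column_specs_,
        parent_dimension=tr.n_features_in_,
    )


def apply_basis(column_specs, X_new: np.ndarray, parent_dimension: int | None = None) -> np.ndarray:
    """Evaluate stored indicator specs on new rows."""
    X_new = np.asarray(X_new, dtype=np.float64)
    if parent_dimension is not None and X_new.shape[1] != parent_dimension:
        raise ValueError("X_new has the wrong number of columns")
    return _evaluate(list(column_specs), X_new)
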