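"""Synthetic cohort generators for the two benchmark simulation designs.

Design 1 ("sim1") emulates a sparse high-dimensional healthcare-database
study: 1000 binary baseline covariates, each ~ Bernoulli(0.2), of which the
first 100 confound both a logistic exposure model and a logistic outcome
model (coefficients uniform on [0, 0.693] ≈ [log 1, log 2]); the remaining
900 are spurious.  Intercepts are calibrated by root-finding so exposure
prevalence is 30% and outcome incidence 5%.  The exposure effect is null:
the outcome model never sees A.

Design 2 ("sim2") is a low-dimensional nonlinear design: five uniform(-2,2)
and five Bernoulli(0.6) covariates, a nonlinear logistic exposure model and
a Gaussian outcome that is linear in transformed covariates, again with a
null exposure effect.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "DGPSpec",
    "Cohort",
    "calibrate_intercept",
    "generate_sim1",
    "generate_sim2",
    "generate_cohort",
]

# E[U^2] for U ~ uniform(-2, 2); centers the squared terms in design 2
_E_U2 = 4.0 / 3.0


@dataclass
class DGPSpec:
    """Parameters of a data-generating process.

    ``design_id`` selects the built-in design ("sim1", "sim2") or "custom".
    ``coefficient_seed`` and ``data_seed`` feed two independent RNG streams
    so the model coefficients do not change when ``n`` does.
    """

    design_id: str = "sim1"
    n: int = 10_000
    d: int = 1000
    confounder_count: int = 100
    coefficient_low: float = 0.0
    coefficient_high: float = 0.693
    target_exposure_prevalence: float = 0.30
    target_outcome_incidence: float = 0.05
    covariate_prevalence: float = 0.2
    coefficient_seed: int = 0
    data_seed: int = 0
    redraw_coefficients_per_replicate: bool = False
    noise_is_sd: bool = False  # sim2: interpret 0.1 as SD instead of variance

    def __post_init__(self) -> None:
        if not 0 < self.target_exposure_prevalence < 1:
            raise ValueError("target_exposure_prevalence must be in (0,1)")
        if not 0 < self.target_outcome_incidence < 1:
            raise ValueError("target_outcome_incidence must be in (0,1)")
        if self.confounder_count > self.d:
            raise ValueError("confounder_count cannot exceed d")
        if self.n <= 0:
            raise ValueError("n must be positive")

    @classmethod
    def sim1(cls, n: int = 10_000, **kw) -> "DGPSpec":
        return cls(design_id="sim1", n=n, d=1000, confounder_count=100, **kw)

    @classmethod
    def sim2(cls, n: int = 1000, **kw) -> "DGPSpec":
        return cls(design_id="sim2", n=n, d=10, confounder_count=7, **kw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Cohort:
    """An observed cohort {Y, A, X} plus generator-side truth when known."""

    Y: np.ndarray
    A: np.ndarray
    X: np.ndarray
    true_ps: Optional[np.ndarray] = None
    true_effect: float = 0.0
    provenance: object = "external"

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=np.float64)
        self.A = np.asarray(self.A)
        self.X = np.asarray(self.X, dtype=np.float64)
        n = len(self.Y)
        if len(self.A) != n or self.X.shape[0] != n:
            raise ValueError("Y, A and X must have the same number of rows")
        if not np.isin(self.A, (0, 1)).all():
            raise ValueError("A must be binary 0/1")
        self.A = self.A.astype(np.int8)
        if self.true_ps is not None:
            self.true_ps = np.asarray(self.true_ps, dtype=np.float64)
            if np.any(self.true_ps <= 0) or np.any(self.true_ps >= 1):
                raise ValueError("true_ps must lie strictly in (0,1)")

    @property
    def n(self) -> int:
        return len(self.Y)

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = {"Y": self.Y, "A": self.A.astype(int)}
        for j in range(self.d):
            cols[f"X{j + 1}"] = self.X[:, j]
        if self.true_ps is not None:
            cols["true_ps"] = self.true_ps
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Cohort":
        df = pd.read_csv(path)
        xcols = sorted(
            (c for c in df.columns if c.startswith("X") and c[1:].isdigit()),
            key=lambda c: int(c[1:]),
        )
        if not xcols or "Y" not in df or "A" not in df:
            raise ValueError("cohort CSV needs columns Y, A, X1..Xd")
        true_ps = df["true_ps"].to_numpy() if "true_ps" in df else None
        return cls(
            Y=df["Y"].to_numpy(),
            A=df["A"].to_numpy(),
            X=df[xcols].to_numpy(dtype=np.float64),
            true_ps=true_ps,
        )


def calibrate_intercept(
    linear_predictor: np.ndarray, target_prevalence: float, tol: float = 1e-10
) -> float:
    """Intercept b0 with mean(expit(b0 + lp)) equal to ``target_prevalence``.

    The map b0 -> mean expit(b0 + lp) is strictly increasing, so a bracketed
    root always exists for targets in (0,1); the bracket is expanded until it
    straddles the root.
    """
    lp = np.asarray(linear_predictor, dtype=np.float64)
    if not np.all(np.isfinite(lp)):
        raise ValueError("linear predictor contains non-finite values")
    if not 0 < target_prevalence < 1:
        raise ValueError("target prevalence must lie in (0,1)")

    def f(b0: float) -> float:
        return float(expit(b0 + lp).mean() - target_prevalence)

    lo, hi = -10.0, 10.0
    for _ in range(20):
        if f(lo) < 0 < f(hi):
            break
        lo *= 2.0
        hi *= 2.0
    else:
        raise RuntimeError("intercept calibration failed to bracket a root")
    return float(brentq(f, lo, hi, xtol=tol))


def _rngs(spec: DGPSpec, replicate: int = 0):
    coef_seed = spec.coefficient_seed
    if spec.redraw_coefficients_per_replicate:
        coef_seed = np.random.SeedSequence([spec.coefficient_seed, replicate]).generate_state(1)[0]
    data_seed = np.random.SeedSequence([spec.data_seed, replicate]).generate_state(1)[0]
    return np.random.default_rng(coef_seed), np.random.default_rng(data_seed)


def generate_sim1(spec: DGPSpec, replicate: int = 0) -> Cohort:
    """Draw one design-1 cohort.

    The intercepts of both logistic models are calibrated on the realized
    linear predictor, so the marginal exposure and outcome probabilities hit
    their targets exactly in expectation over the Bernoulli draws.
    """
    if spec.design_id != "sim1" and spec.design_id != "custom":
        raise ValueError("spec.design_id must be 'sim1' or 'custom'")
    rng_coef, rng_data = _rngs(spec, replicate)
    k = spec.confounder_count
    beta = rng_coef.uniform(spec.coefficient_low, spec.coefficient_high, size=k)
    alpha = rng_coef.uniform(spec.coefficient_low, spec.coefficient_high, size=k)

    X = (rng_data.random((spec.n, spec.d)) < spec.covariate_prevalence).astype(np.float64)
    lp_a = X[:, :k] @ beta
    b0 = calibrate_intercept(lp_a, spec.target_exposure_prevalence)
    ps = expit(b0 + lp_a)
    A = (rng_data.random(spec.n) < ps).astype(np.int8)

    lp_y = X[:, :k] @ alpha
    a0 = calibrate_intercept(lp_y, spec.target_outcome_incidence)
    Y = (rng_data.random(spec.n) < expit(a0 + lp_y)).astype(np.float64)  # null effect: no A term
    return Cohort(Y=Y, A=A, X=X, true_ps=ps, true_effect=0.0, provenance=spec)


def sim2_propensity(X: np.ndarray) -> np.ndarray:
    """Design-2 exposure probability e(X) (columns X1..X10, 0-indexed)."""
    return expit(
        X[:, 1] ** 2
        - np.exp(0.5 * X[:, 0])
        - X[:, 2]
        + X[:, 3]
        - np.exp(0.5 * X[:, 4])
        + X[:, 5]
        + X[:, 6]
    )


def generate_sim2(spec: DGPSpec, replicate: int = 0) -> Cohort:
    """Draw one design-2 cohort (nonlinear exposure, Gaussian outcome)."""
    if spec.design_id != "sim2":
        raise ValueError("spec.design_id must be 'sim2'")
    _, rng_data = _rngs(spec, replicate)
    n = spec.n
    X = np.empty((n, 10))
    X[:, :5] = rng_data.uniform(-2.0, 2.0, size=(n, 5))
    X[:, 5:] = (rng_data.random((n, 5)) < 0.6).astype(np.float64)
    ps = sim2_propensity(X)
    A = (rng_data.random(n) < ps).astype(np.int8)
    sd = 0.1 if spec.noise_is_sd else np.sqrt(0.1)
    eps = rng_data.normal(0.0, sd, size=n)
    Y = (
        -2.0 * X[:, 1] ** 2
        + 2.0 * X[:, 0]
        + 2.0 * _E_U2
        + X[:, 1]
        + X[:, 0] * X[:, 1]
        + X[:, 2]
        + X[:, 3]
        + 2.0 * X[:, 4] ** 2
        - 2.0 * _E_U2
        + eps
    )
    return Cohort(Y=Y, A=A, X=X, true_ps=ps, true_effect=0.0, provenance=spec)


def generate_cohort(spec: DGPSpec, replicate: int = 0) -> Cohort:
    """Dispatch on ``spec.design_id``."""
    if spec.design_id == "sim2":
        return generate_sim2(spec, replicate)
    return generate_sim1(spec, replicate)
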