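"""Propensity-score weights and weighted mean-difference effect estimates.

Three weighting schemes are supported, all functions of the propensity
e = e(X) and the exposure indicator A:

    IPW (inverse probability):  w = A/e + (1-A)/(1-e)
    MW  (matching):             w = min(e, 1-e)/e for exposed,
                                    min(e, 1-e)/(1-e) for unexposed
    OW  (overlap):              w = A(1-e) + (1-A)e

IPW targets the average effect in the whole population; MW and OW
down-weight subjects with extreme propensities and target populations
concentrated where exposure groups overlap, which also makes them far less
sensitive to near-violations of positivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import statsmodels.api as sm

__all__ = [
    "WEIGHT_SCHEMES",
    "compute_weights",
    "weighted_mean_difference",
    "coverage_probability",
    "EffectEstimate",
]

WEIGHT_SCHEMES = ("ipw", "mw", "ow")


@dataclass
class EffectEstimate:
    """A weighted mean-difference estimate with a 95% normal interval."""

    estimate: float
    standard_error: float
    ci_low: float
    ci_high: float
    scheme: str = "ipw"
    lambda_used: float | None = None
    n_effective_exposed: float = np.nan
    n_effective_unexposed: float = np.nan

    def covers(self, truth: float) -> bool:
        return self.ci_low <= truth <= self.ci_high


def compute_weights(ps: np.ndarray, a: np.ndarray, scheme: str) -> np.ndarray:
    """Weights for one scheme; ``ps`` must lie strictly in (0,1)."""
    ps = np.asarray(ps, dtype=np.float64)
    a = np.asarray(a)
    if np.any(ps <= 0.0) or np.any(ps >= 1.0):
        raise ValueError("propensities must lie strictly in (0,1); clip before weighting")
    scheme = scheme.lower()
    exposed = a == 1
    if scheme == "ipw":
        return np.where(exposed, 1.0 / ps, 1.0 / (1.0 - ps))
    if scheme == "mw":
        m = np.minimum(ps, 1.0 - ps)
        return np.where(exposed, m / ps, m / (1.0 - ps))
    if scheme == "ow":
        return np.where(exposed, 1.0 - ps, ps)
    raise ValueError(f"unknown weight scheme {scheme!r}; expected one of {WEIGHT_SCHEMES}")


def _kish(w: np.ndarray) -> float:
    s = w.sum()
    return float(s * s / np.sum(w * w)) if s > 0 else 0.0


def weighted_mean_difference(
    y: np.ndarray, a: np.ndarray, weights: np.ndarray, scheme: str = "ipw",
    lambda_used: float | None = None,
) -> EffectEstimate:
    """Hájek (normalized) weighted difference in mean outcome.

    The standard error is the HC3 sandwich from a weighted least-squares
    regression of Y on the exposure indicator with the PS weights, the
    usual robust variance for weighted mean differences.
    """
    y = np.asarray(y, dtype=np.float64)
    a = np.asarray(a)
    w = np.asarray(weights, dtype=np.float64)
    exposed = a == 1
    sw1 = w[exposed].sum()
    sw0 = w[~exposed].sum()
    if sw1 <= 0 or sw0 <= 0:
        raise ValueError("each exposure arm needs positive weight mass")
    est = float(y[exposed] @ w[exposed] / sw1 - y[~exposed] @ w[~exposed] / sw0)

    design = sm.add_constant(a.astype(float))
    fit = sm.WLS(y, design, weights=w).fit(cov_type="HC3")
    se = float(fit.bse[1])
    half = 1.959963984540054 * se
    return EffectEstimate(
        estimate=est,
        standard_error=se,
        ci_low=est - half,
        ci_high=est + half,
        scheme=scheme,
        lambda_used=lambda_used,
        n_effective_exposed=_kish(w[exposed]),
        n_effective_unexposed=_kish(w[~exposed]),
    )


def coverage_probability(estimates: Iterable[EffectEstimate], truth: float) -> float:
    """Fraction of 95% intervals containing ``truth``."""
    ests = list(estimates)
    if not ests:
        raise ValueError("need at least one estimate")
    return float(np.mean([e.covers(truth) for e in ests]))
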