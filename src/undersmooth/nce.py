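"""Synthetic negative-control-exposure cohorts for bias detection.

A negative control exposure is a variable known to have no effect on the
outcome but sharing the real exposure's confounding structure: any nonzero
adjusted association between it and the outcome signals residual
confounding.  Here such controls are *synthesized*:

1.  Fit a cross-validation-tuned LASSO propensity model ê(X) on the full
    cohort.  No undersmoothing at this step — the goal is the best estimate
    of the propensity surface itself, not of the causal parameter.
2.  Calibrate an odds multiplier c so the synthetic assignment probability
    g(X), with logit g = logit ê + log c (proportional odds), has a chosen
    marginal prevalence among the unexposed.
3.  Restrict to the unexposed rows (their outcomes are untouched by the
    real exposure).
4.  Bootstrap-oversample those rows with replacement back up to the study
    size.
5.  Assign a synthetic exposure Z_i ~ Bernoulli(g(X_i)) independently per
    bootstrap row — exposure is regenerated from the model, never
    resampled, so positivity holds by construction and LASSO-on-bootstrap
    pathologies are avoided.

Because Z depends on the data only through X, Z ⫫ Y | X holds exactly and
the true Z effect is zero in every synthetic cohort.  Running a candidate
PS-weighted analysis on many such cohorts and averaging its Z-effect
estimates measures the *synthetic bias* of that analysis: an analysis that
cannot recover the null here is flagged as failing to control the measured
confounding captured by ê.  The screen detects bias only; it does not rank
unbiased analyses by efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .datagen import Cohort
from .lasso import LassoPath, fit_lasso_path
from .balance import weighted_smd_profile, select_lambda
from .weighting import compute_weights, weighted_mean_difference

__all__ = [
    "SyntheticSpec",
    "SyntheticCohort",
    "AnalysisSpec",
    "BiasDetectionReport",
    "fit_generator_model",
    "calibrate_proportional_odds",
    "generate_synthetic_cohorts",
    "screen_analyses",
    "SyntheticNegativeControl",
]


@dataclass
class SyntheticSpec:
    """Settings for synthetic-cohort generation."""

    B: int = 500
    target_size: int | None = None  # None -> original cohort n
    target_prevalence: float | None = None  # None -> original exposure prevalence
    calibrate: bool = True  # False -> proportionality constant c = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.target_size is not None and self.target_size < 1:
            raise ValueError("target_size must be >= 1")


@dataclass
class SyntheticCohort:
    """One bootstrap-oversampled unexposed cohort with synthetic exposure Z."""

    Y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    g_hat: np.ndarray
    source_row_ids: np.ndarray


@dataclass
class AnalysisSpec:
    """A candidate estimator: a tuning rule crossed with a weight scheme.

    tuning: "unadjusted", "cv", "max-smd", "mean-smd", or "oracle"
    (oracle weights by the true assignment probability g used to build the
    synthetic cohorts — a construction-truth reference, not a real
    analysis).
    """

    tuning: str = "cv"
    scheme: str = "ipw"
    folds: int = 5
    grid_size: int = 100
    lambda_min_ratio: float = 1e-4
    clip: float = 1e-6

    @property
    def name(self) -> str:
        if self.tuning in ("unadjusted", "oracle"):
            return self.tuning
        return f"{self.tuning}-{self.scheme}"


def fit_generator_model(
    cohort: Cohort,
    folds: int = 5,
    grid_size: int = 100,
    lambda_min_ratio: float = 1e-4,
    seed: int = 0,
    X: np.ndarray | None = None,
) -> tuple[LassoPath, np.ndarray]:
    """CV-tuned LASSO propensity fit; returns (path, ê at lambda_CV).

    ê comes from the full-data coefficients at the cross-validated lambda.
    ``X`` overrides the design matrix (e.g. an indicator-basis expansion).
    """
    design = cohort.X if X is None else X
    path = fit_lasso_path(
        design, cohort.A, folds=folds, grid_size=grid_size,
        lambda_min_ratio=lambda_min_ratio, seed=seed,
    )
    e_hat = path.predict_proba(design, path.lambda_cv_index)
    return path, e_hat


def calibrate_proportional_odds(
    e_hat_unexposed: np.ndarray, target_prevalence: float, tol: float = 1e-10
) -> float:
    """Odds multiplier c with mean expit(logit ê + log c) = target prevalence.

    The map log c -> mean assignment probability is strictly increasing, so
    the root is unique; the bracket expands until it straddles it.
    """
    if not 0 < target_prevalence < 1:
        raise ValueError("target prevalence must lie in (0,1)")
    lo_ = np.asarray(e_hat_unexposed, dtype=np.float64)
    if np.any(lo_ <= 0) or np.any(lo_ >= 1):
        raise ValueError("e_hat must lie strictly in (0,1)")
    lp = logit(lo_)

    def f(log_c: float) -> float:
        return float(expit(lp + log_c).mean() - target_prevalence)

    lo, hi = -10.0, 10.0
    for _ in range(20):
        if f(lo) < 0 < f(hi):
            break
        lo *= 2.0
        hi *= 2.0
    else:
        raise RuntimeError("proportional-odds calibration failed to bracket a root")
    return float(np.exp(brentq(f, lo, hi, xtol=tol)))


def generate_synthetic_cohorts(
    cohort: Cohort, e_hat: np.ndarray, spec: SyntheticSpec
) -> list[SyntheticCohort]:
    """Steps 3-5: restrict to unexposed, oversample, regenerate exposure."""
    unexposed = np.flatnonzero(cohort.A == 0)
    if len(unexposed) < 2:
        raise ValueError("need at least 2 unexposed subjects")
    e_un = np.clip(np.asarray(e_hat)[unexposed], 1e-12, 1 - 1e-12)

    if spec.calibrate:
        target = (
            spec.target_prevalence
            if spec.target_prevalence is not None
            else float(np.mean(cohort.A))
        )
        c = calibrate_proportional_odds(e_un, target)
    else:
        c = 1.0
    g_un = expit(logit(e_un) + np.log(c))

    m = spec.target_size if spec.target_size is not None else cohort.n
    root = np.random.SeedSequence(spec.seed)
    cohorts = []
    for child in root.spawn(spec.B):
        rng = np.random.default_rng(child)
        draw = rng.integers(0, len(unexposed), size=m)
        g = g_un[draw]
        z = (rng.random(m) < g).astype(np.int8)
        rows = unexposed[draw]
        cohorts.append(
            SyntheticCohort(
                Y=cohort.Y[rows],
                X=cohort.X[rows],
                Z=z,
                g_hat=g,
                source_row_ids=rows,
            )
        )
    return cohorts


@dataclass
class BiasDetectionReport:
    """Synthetic bias of each candidate analysis, truth 0 by construction."""

    table: pd.DataFrame  # analysis, synthetic_bias, mc_se, synthetic_percent_bias, flagged, n_failed
    B: int
    reference: str = "unadjusted"

    def __getitem__(self, name: str) -> pd.Series:
        return self.table.set_index("analysis").loc[name]


def _run_analyses_on_cohort(
    syn: SyntheticCohort, specs: list[AnalysisSpec], seed: int,
    design: np.ndarray | None = None,
) -> dict[str, float]:
    """All candidates on one synthetic cohort (Z as exposure).

    Candidates with identical path settings share one cross-fitted LASSO
    path; only the lambda selection and weights differ between them.
    """
    X = syn.X if design is None else design
    z = syn.Z
    out: dict[str, float] = {}
    paths: dict[tuple, object] = {}
    profiles: dict[tuple, object] = {}
    for spec in specs:
        if spec.tuning == "unadjusted":
            out[spec.name] = float(syn.Y[z == 1].mean() - syn.Y[z == 0].mean())
            continue
        if spec.tuning == "oracle":
            g = np.clip(syn.g_hat, spec.clip, 1 - spec.clip)
            w = compute_weights(g, z, spec.scheme)
            out[spec.name] = weighted_mean_difference(syn.Y, z, w, spec.scheme).estimate
            continue
        key = (spec.folds, spec.grid_size, spec.lambda_min_ratio, spec.clip)
        if key not in paths:
            paths[key] = fit_lasso_path(
                X, z, folds=spec.folds, grid_size=spec.grid_size,
                lambda_min_ratio=spec.lambda_min_ratio, seed=seed, clip=spec.clip,
            )
        path = paths[key]
        if spec.tuning == "cv":
            idx = path.lambda_cv_index
        elif spec.tuning in ("max-smd", "mean-smd"):
            pkey = key + (spec.scheme,)
            if pkey not in profiles:
                profiles[pkey] = weighted_smd_profile(X, z, path, spec.scheme)
            idx = select_lambda(profiles[pkey], spec.tuning.split("-")[0])
        else:
            raise ValueError(f"unknown tuning rule {spec.tuning!r}")
        w = compute_weights(path.oof_probabilities[:, idx], z, spec.scheme)
        out[spec.name] = weighted_mean_difference(syn.Y, z, w, spec.scheme).estimate
    return out


def screen_analyses(
    cohorts: list[SyntheticCohort],
    analyses: list[AnalysisSpec],
    seed: int = 0,
    flag_k_se: float = 3.0,
    flag_fraction_of_unadjusted: float = 0.10,
    basis_specs=None,
) -> BiasDetectionReport:
    """Run each candidate on every synthetic cohort and summarize its bias.

    ``synthetic_percent_bias`` is 100 * bias / bias(unadjusted); the
    unadjusted row is therefore exactly 100.  An analysis is flagged when
    its |bias| exceeds both ``flag_k_se`` Monte-Carlo SEs and
    ``flag_fraction_of_unadjusted`` of the unadjusted bias magnitude.
    A candidate failing on more than 10% of cohorts is reported as failed.
    ``basis_specs``: indicator-basis column specs to expand each synthetic
    cohort's X with before fitting (nonlinear designs).
    """
    from .hal import apply_basis

    specs = list(analyses)
    if not any(s.tuning == "unadjusted" for s in specs):
        specs = [AnalysisSpec(tuning="unadjusted")] + specs

    B = len(cohorts)
    estimates = {s.name: [] for s in specs}
    failures = {s.name: 0 for s in specs}
    for b, syn in enumerate(cohorts):
        design = apply_basis(basis_specs, syn.X) if basis_specs is not None else None
        try:
            results = _run_analyses_on_cohort(syn, specs, seed=seed + b, design=design)
        except Exception:
            # a failure before any candidate ran (e.g. single-class Z)
            for s in specs:
                failures[s.name] += 1
            continue
        for s in specs:
            if s.name in results and np.isfinite(results[s.name]):
                estimates[s.name].append(results[s.name])
            else:
                failures[s.name] += 1

    rows = []
    unadj_bias = None
    for s in specs:
        ests = np.asarray(estimates[s.name])
        failed = failures[s.name] > 0.10 * B
        bias = float(ests.mean()) if len(ests) else np.nan
        mc_se = float(ests.std(ddof=1) / np.sqrt(len(ests))) if len(ests) > 1 else np.nan
        if s.tuning == "unadjusted":
            unadj_bias = bias
        rows.append(
            {
                "analysis": s.name,
                "synthetic_bias": bias,
                "mc_se": mc_se,
                "n_failed": failures[s.name],
                "failed": failed,
            }
        )
    table = pd.DataFrame(rows)
    if unadj_bias is not None and unadj_bias != 0:
        table["synthetic_percent_bias"] = 100.0 * table["synthetic_bias"] / unadj_bias
    else:
        table["synthetic_percent_bias"] = np.nan
    table["flagged"] = (
        (table["synthetic_bias"].abs() > flag_k_se * table["mc_se"])
        & (table["synthetic_bias"].abs() > flag_fraction_of_unadjusted * abs(unadj_bias or np.nan))
    )
    return BiasDetectionReport(table=table, B=B)


class SyntheticNegativeControl:
    """End-to-end screen: fit generator, build cohorts, run candidates.

    Thin object API over the module functions; ``fit`` performs steps 1-2
    of the generation algorithm, ``generate`` steps 3-5, and ``screen``
    evaluates candidate analyses.
    """

    def __init__(
        self,
        spec: SyntheticSpec | None = None,
        folds: int = 5,
        grid_size: int = 100,
        lambda_min_ratio: float = 1e-4,
        basis=None,  # fitted IndicatorBasis, for nonlinear designs
    ):
        self.spec = spec or SyntheticSpec()
        self.folds = folds
        self.grid_size = grid_size
        self.lambda_min_ratio = lambda_min_ratio
        self.basis = basis

    def fit(self, cohort: Cohort) -> "SyntheticNegativeControl":
        self.cohort_ = cohort
        design = self.basis.transform(cohort.X) if self.basis is not None else None
        self.generator_path_, self.e_hat_ = fit_generator_model(
            cohort, folds=self.folds, grid_size=self.grid_size,
            lambda_min_ratio=self.lambda_min_ratio, seed=self.spec.seed, X=design,
        )
        return self

    def generate(self) -> list[SyntheticCohort]:
        self.cohorts_ = generate_synthetic_cohorts(self.cohort_, self.e_hat_, self.spec)
        return self.cohorts_

    def screen(self, analyses: list[AnalysisSpec], **kw) -> BiasDetectionReport:
        if not hasattr(self, "cohorts_"):
            self.generate()
        basis_specs = self.basis.column_specs_ if self.basis is not None else None
        self.report_ = screen_analyses(
            self.cohorts_, analyses, seed=self.spec.seed, basis_specs=basis_specs, **kw
        )
        return self.report_
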