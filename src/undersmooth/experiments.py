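"""Monte-Carlo replication of the simulation studies.

``run_replication`` repeatedly draws cohorts from one of the built-in
designs, runs every (tuning rule x weight scheme) candidate plus the
unadjusted contrast on each, and optionally screens the same candidates on
synthetic negative-control cohorts built from each replicate.  Outputs are
tidy DataFrames: a per-replicate estimates table and an aggregate table
with bias, percent bias relative to unadjusted, SD, 95% coverage of the
null, and the synthetic counterparts.

One cross-fitted LASSO path is fitted per replicate (per design matrix)
and shared by all tuning rules and schemes, which is what makes full
factorial sweeps affordable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .balance import select_lambda, weighted_smd_profile, love_plot_table
from .datagen import DGPSpec, generate_cohort
from .hal import IndicatorBasis
from .lasso import fit_lasso_path
from .nce import (
    AnalysisSpec,
    SyntheticSpec,
    fit_generator_model,
    generate_synthetic_cohorts,
    screen_analyses,
)
from .weighting import compute_weights, weighted_mean_difference

__all__ = ["ExperimentConfig", "run_replication", "balance_figure_table"]

TUNING_RULES = ("cv", "max-smd", "mean-smd")


@dataclass
class ExperimentConfig:
    """One replication experiment over a grid of sample sizes."""

    design_id: str = "sim1"
    sample_sizes: tuple = (5000,)
    replicates: int = 50
    B_synthetic: int = 0  # 0 disables the synthetic screen
    tuning_rules: tuple = TUNING_RULES
    weight_schemes: tuple = ("ipw", "mw", "ow")
    folds: int = 5
    grid_size: int = 100
    lambda_min_ratio: float = 1e-4
    basis_max_degree: int = 2
    basis_knots: int = 25
    master_seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _candidate_names(config: ExperimentConfig):
    return ["unadjusted"] + [
        f"{rule}-{scheme}"
        for rule, scheme in itertools.product(config.tuning_rules, config.weight_schemes)
    ]


def _analyze_cohort(cohort, config: ExperimentConfig, seed: int, design=None):
    """All candidate estimates on one cohort from a single shared path."""
    X = cohort.X if design is None else design
    path = fit_lasso_path(
        X, cohort.A, folds=config.folds, grid_size=config.grid_size,
        lambda_min_ratio=config.lambda_min_ratio, seed=seed,
    )
    out = {}
    unadj = float(cohort.Y[cohort.A == 1].mean() - cohort.Y[cohort.A == 0].mean())
    out["unadjusted"] = (unadj, np.nan, np.nan)
    indices = {}
    reports = {}
    for scheme in config.weight_schemes:
        for rule in config.tuning_rules:
            if rule == "cv":
                idx = path.lambda_cv_index
            else:
                if scheme not in reports:
                    reports[scheme] = weighted_smd_profile(X, cohort.A, path, scheme)
                idx = select_lambda(reports[scheme], rule.split("-")[0])
            indices[(rule, scheme)] = idx
            w = compute_weights(path.oof_probabilities[:, idx], cohort.A, scheme)
            est = weighted_mean_difference(cohort.Y, cohort.A, w, scheme)
            out[f"{rule}-{scheme}"] = (est.estimate, est.ci_low, est.ci_high)
    return out, path, indices


def run_replication(config: ExperimentConfig) -> dict[str, pd.DataFrame]:
    """Run the experiment; returns {'estimates': ..., 'summary': ...}.

    Per-replicate seeds derive deterministically from ``master_seed``, so a
    failed replicate can be reproduced in isolation.  When ``output_dir``
    is set, tables are checkpointed to CSV as they grow.
    """
    rows = []
    syn_rows = []
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    for n in config.sample_sizes:
        for r in range(config.replicates):
            seed = int(
                np.random.SeedSequence([config.master_seed, int(n), r]).generate_state(1)[0]
                % (2**31 - 1)
            )
            spec = _make_spec(config, n, seed)
            cohort = generate_cohort(spec, replicate=r)
            basis = None
            design = None
            if config.design_id == "sim2":
                basis = IndicatorBasis(config.basis_max_degree, config.basis_knots).fit(cohort.X)
                design = basis.transform(cohort.X)
            estimates, path, _ = _analyze_cohort(cohort, config, seed, design)
            for name, (est, lo, hi) in estimates.items():
                rows.append(
                    {"n": n, "replicate": r, "seed": seed, "analysis": name,
                     "estimate": est, "ci_low": lo, "ci_high": hi}
                )
            if config.B_synthetic > 0:
                syn = _screen_replicate(cohort, config, seed, basis)
                for _, srow in syn.iterrows():
                    syn_rows.append({"n": n, "replicate": r, **srow.to_dict()})
            if outdir:
                pd.DataFrame(rows).to_csv(outdir / "estimates.csv", index=False)
                if syn_rows:
                    pd.DataFrame(syn_rows).to_csv(outdir / "synthetic.csv", index=False)

    estimates = pd.DataFrame(rows)
    synthetic = pd.DataFrame(syn_rows) if syn_rows else None
    summary = summarize(estimates, synthetic)
    if outdir:
        summary.to_csv(outdir / "summary.csv", index=False)
    out = {"estimates": estimates, "summary": summary}
    if synthetic is not None:
        out["synthetic"] = synthetic
    return out


def _make_spec(config: ExperimentConfig, n: int, seed: int) -> DGPSpec:
    if config.design_id == "sim2":
        return DGPSpec.sim2(n=n, data_seed=seed)
    # coefficients held fixed across replicates: one DGP per experiment
    return DGPSpec.sim1(n=n, coefficient_seed=config.master_seed, data_seed=seed)


def _screen_replicate(cohort, config: ExperimentConfig, seed: int, basis):
    design = basis.transform(cohort.X) if basis is not None else None
    _, e_hat = fit_generator_model(
        cohort, folds=config.folds, grid_size=config.grid_size,
        lambda_min_ratio=config.lambda_min_ratio, seed=seed, X=design,
    )
    syn_spec = SyntheticSpec(B=config.B_synthetic, seed=seed)
    cohorts = generate_synthetic_cohorts(cohort, e_hat, syn_spec)
    analyses = [
        AnalysisSpec(tuning=rule, scheme=scheme, folds=config.folds,
                     grid_size=config.grid_size, lambda_min_ratio=config.lambda_min_ratio)
        for rule, scheme in itertools.product(config.tuning_rules, config.weight_schemes)
    ]
    report = screen_analyses(
        cohorts, analyses, seed=seed,
        basis_specs=basis.column_specs_ if basis is not None else None,
    )
    return report.table


def summarize(estimates: pd.DataFrame, synthetic: pd.DataFrame | None = None) -> pd.DataFrame:
    """Aggregate bias, percent bias, SD and coverage per (n, analysis).

    Percent bias uses the ratio of mean biases (mean estimate over
    replicates divided by mean unadjusted estimate), which stays stable
    when individual unadjusted estimates pass near zero.  The true effect
    is null in both designs, so bias = mean estimate and coverage is of 0.
    """
    out = []
    for (n, name), grp in estimates.groupby(["n", "analysis"]):
        unadj = estimates[(estimates["n"] == n) & (estimates["analysis"] == "unadjusted")]
        mean_unadj = unadj["estimate"].mean()
        bias = grp["estimate"].mean()
        covered = (
            np.nan
            if grp["ci_low"].isna().all()
            else float(((grp["ci_low"] <= 0) & (grp["ci_high"] >= 0)).mean())
        )
        out.append(
            {
                "n": n,
                "analysis": name,
                "bias": bias,
                "percent_bias": 100.0 * bias / mean_unadj if mean_unadj != 0 else np.nan,
                "sd": grp["estimate"].std(ddof=1) if len(grp) > 1 else np.nan,
                "coverage": covered,
                "replicates": len(grp),
            }
        )
    summary = pd.DataFrame(out)
    if synthetic is not None and len(synthetic):
        syn = (
            synthetic.groupby(["n", "analysis"])
            .agg(synthetic_bias=("synthetic_bias", "mean"),
                 synthetic_percent_bias=("synthetic_percent_bias", "mean"))
            .reset_index()
        )
        summary = summary.merge(syn, on=["n", "analysis"], how="left")
    return summary


def balance_figure_table(
    n: int = 10_000,
    seed: int = 0,
    folds: int = 5,
    grid_size: int = 100,
    lambda_min_ratio: float = 1e-4,
) -> pd.DataFrame:
    """Per-covariate unadjusted vs IPW-weighted absolute SMD, design 1.

    One cohort, CV-tuned LASSO propensity, inverse probability weights from
    out-of-fold propensities — the data behind a Love plot of balance
    before and after weighting.
    """
    spec = DGPSpec.sim1(n=n, coefficient_seed=seed, data_seed=seed + 1)
    cohort = generate_cohort(spec)
    path = fit_lasso_path(
        cohort.X, cohort.A, folds=folds, grid_size=grid_size,
        lambda_min_ratio=lambda_min_ratio, seed=seed,
    )
    w = compute_weights(path.oof_probabilities[:, path.lambda_cv_index], cohort.A, "ipw")
    return love_plot_table(cohort.X, cohort.A, w)
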