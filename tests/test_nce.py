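"""Synthetic negative-control generation and bias-detection screening."""

import numpy as np
import pytest
from scipy.special import expit, logit

from undersmooth.datagen import Cohort, DGPSpec, generate_sim1
from undersmooth.nce import (
    AnalysisSpec,
    SyntheticNegativeControl,
    SyntheticSpec,
    calibrate_proportional_odds,
    fit_generator_model,
    generate_synthetic_cohorts,
    screen_analyses,
)


@pytest.fixture(scope="module")
def confounded_cohort():
    spec = DGPSpec(
        design_id="custom", n=2500, d=30, confounder_count=8,
        coefficient_low=0.3, coefficient_high=1.2,
        target_exposure_prevalence=0.35, target_outcome_incidence=0.20,
        coefficient_seed=41, data_seed=42,
    )
    return generate_sim1(spec)


@pytest.fixture(scope="module")
def generator_fit(confounded_cohort):
    path, e_hat = fit_generator_model(confounded_cohort, grid_size=30, seed=1)
    return path, e_hat


class TestGeneratorModel:
    def test_recovers_true_propensity_ordering(self, confounded_cohort, generator_fit):
        _, e_hat = generator_fit
        r = np.corrcoef(logit(np.clip(e_hat, 1e-9, 1 - 1e-9)),
                        logit(confounded_cohort.true_ps))[0, 1]
        assert r > 0.90

    def test_spurious_only_design_predicts_marginal(self, separable_free_cohort):
        path, e_hat = fit_generator_model(separable_free_cohort, grid_size=15, seed=2)
        assert np.abs(e_hat - separable_free_cohort.A.mean()).max() < 0.05

    def test_deterministic(self, confounded_cohort):
        p1, e1 = fit_generator_model(confounded_cohort, grid_size=15, seed=3)
        p2, e2 = fit_generator_model(confounded_cohort, grid_size=15, seed=3)
        assert np.array_equal(e1, e2)
        assert np.array_equal(p1.coefficients, p2.coefficients)


class TestProportionalOddsCalibration:
    def test_fixed_point_at_current_mean(self):
        e = np.array([0.2, 0.3, 0.4])
        c = calibrate_proportional_odds(e, float(e.mean()))
        assert c == pytest.approx(1.0, abs=1e-6)

    def test_closed_form_odds_shift(self):
        # all e = 0.25 (odds 1/3); target 0.5 (odds 1) -> c = 3
        e = np.full(10, 0.25)
        assert calibrate_proportional_odds(e, 0.5) == pytest.approx(3.0, abs=1e-8)

    def test_monotone_in_target(self):
        rng = np.random.default_rng(4)
        e = rng.uniform(0.05, 0.6, size=200)
        cs = [calibrate_proportional_odds(e, t) for t in (0.2, 0.4, 0.6)]
        assert cs[0] < cs[1] < cs[2]

    def test_calibrated_mean_hits_target(self):
        rng = np.random.default_rng(5)
        e = rng.uniform(0.01, 0.9, size=5000)
        c = calibrate_proportional_odds(e, 0.3)
        assert expit(logit(e) + np.log(c)).mean() == pytest.approx(0.3, abs=1e-8)


class TestGenerateSyntheticCohorts:
    def test_rows_come_from_unexposed_only(self, confounded_cohort, generator_fit):
        _, e_hat = generator_fit
        spec = SyntheticSpec(B=5, seed=10)
        cohorts = generate_synthetic_cohorts(confounded_cohort, e_hat, spec)
        unexposed = set(np.flatnonzero(confounded_cohort.A == 0))
        for syn in cohorts:
            assert set(syn.source_row_ids) <= unexposed
            assert len(syn.Z) == confounded_cohort.n

    def test_proportional_odds_holds_exactly(self, confounded_cohort, generator_fit):
        _, e_hat = generator_fit
        spec = SyntheticSpec(B=3, seed=11)
        cohorts = generate_synthetic_cohorts(confounded_cohort, e_hat, spec)
        for syn in cohorts:
            shift = logit(syn.g_hat) - logit(
                np.clip(e_hat[syn.source_row_ids], 1e-12, 1 - 1e-12)
            )
            assert np.ptp(shift) < 1e-8  # constant log-odds offset

    def test_mean_z_prevalence_matches_calibration_target(self, confounded_cohort, generator_fit):
        _, e_hat = generator_fit
        B = 200
        spec = SyntheticSpec(B=B, seed=12)
        cohorts = generate_synthetic_cohorts(confounded_cohort, e_hat, spec)
        target = confounded_cohort.A.mean()
        prevs = np.array([syn.Z.mean() for syn in cohorts])
        mc_se = prevs.std(ddof=1) / np.sqrt(B)
        assert abs(prevs.mean() - target) < max(3 * mc_se, 0.01)

    def test_degenerate_zero_probability_gives_all_zero_z(self, confounded_cohort):
        e_hat = np.full(confounded_cohort.n, 1e-12)
        spec = SyntheticSpec(B=2, seed=13, calibrate=False)
        cohorts = generate_synthetic_cohorts(confounded_cohort, e_hat, spec)
        for syn in cohorts:
            assert syn.Z.sum() == 0

    def test_duplicate_rows_draw_independent_z(self, confounded_cohort, generator_fit):
        _, e_hat = generator_fit
        spec = SyntheticSpec(B=20, seed=14)
        cohorts = generate_synthetic_cohorts(confounded_cohort, e_hat, spec)
        # find a cohort with a duplicated source row whose copies disagree
        disagreement = False
        for syn in cohorts:
            ids, counts = np.unique(syn.source_row_ids, return_counts=True)
            for rid in ids[counts > 1]:
                z_vals = syn.Z[syn.source_row_ids == rid]
                if z_vals.min() != z_vals.max():
                    disagreement = True
                    break
            if disagreement:
                break
        assert disagreement

    def test_deterministic_under_seed(self, confounded_cohort, generator_fit):
        _, e_hat = generator_fit
        c1 = generate_synthetic_cohorts(confounded_cohort, e_hat, SyntheticSpec(B=3, seed=15))
        c2 = generate_synthetic_cohorts(confounded_cohort, e_hat, SyntheticSpec(B=3, seed=15))
        for a, b in zip(c1, c2):
            assert np.array_equal(a.Z, b.Z)
            assert np.array_equal(a.source_row_ids, b.source_row_ids)

    def test_no_unexposed_rows_rejected(self):
        c = Cohort(Y=np.zeros(4), A=np.ones(4, dtype=int), X=np.zeros((4, 1)))
        with pytest.raises(ValueError):
            generate_synthetic_cohorts(c, np.full(4, 0.5), SyntheticSpec(B=1))

    def test_z_independent_of_y_given_x(self, confounded_cohort, generator_fit):
        """Z is drawn from X alone, so adding Y to a logistic model of Z on
        the true assignment logit must contribute nothing."""
        import statsmodels.api as sm

        _, e_hat = generator_fit
        spec = SyntheticSpec(B=60, seed=16)
        cohorts = generate_synthetic_cohorts(confounded_cohort, e_hat, spec)
        zs = np.concatenate([s.Z for s in cohorts])
        ys = np.concatenate([s.Y for s in cohorts])
        lps = np.concatenate([logit(s.g_hat) for s in cohorts])
        design = sm.add_constant(np.column_stack([lps, ys]))
        fit = sm.GLM(zs, design, family=sm.families.Binomial()).fit()
        # Y-coefficient indistinguishable from zero at large B*n
        assert abs(fit.params[2]) < 3 * fit.bse[2] + 0.02


@pytest.fixture(scope="module")
def screen(confounded_cohort):
    nc = SyntheticNegativeControl(
        SyntheticSpec(B=25, seed=20), grid_size=25, lambda_min_ratio=1e-3
    ).fit(confounded_cohort)
    analyses = [
        AnalysisSpec(tuning="oracle", scheme="ipw"),
        AnalysisSpec(tuning="cv", scheme="ipw", grid_size=25, lambda_min_ratio=1e-3),
    ]
    return nc.screen(analyses)


class TestScreenAnalyses:
    def test_unadjusted_percent_bias_is_exactly_100(self, screen):
        row = screen["unadjusted"]
        assert row["synthetic_percent_bias"] == pytest.approx(100.0, abs=1e-12)

    def test_oracle_weighting_recovers_null(self, screen):
        row = screen["oracle"]
        assert abs(row["synthetic_bias"]) < 3 * row["mc_se"]

    def test_unadjusted_is_flagged_when_confounded(self, screen):
        assert bool(screen["unadjusted"]["flagged"])

    def test_adjusted_bias_below_unadjusted(self, screen):
        assert abs(screen["cv-ipw"]["synthetic_bias"]) < abs(
            screen["unadjusted"]["synthetic_bias"]
        )
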