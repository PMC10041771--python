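"""Concordance, calibration and bootstrap validation."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit

from _oracles import auc_pair_count, logistic_newton
from conftest import cohort_from_counts
from eupred.model import EUModelFit, EUModelSpec, FitOptions, fit_eu_model
from eupred.simulate import scenario_truth, simulate_cohort
from eupred.validation import (
    ValidationReport,
    calibration_curve,
    calibration_slope,
    concordance_auc,
    external_validate,
    internal_validate,
    observed_vs_fitted_table,
)


class TestConcordance:
    def test_three_of_four_pairs_concordant(self):
        assert concordance_auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == 0.75

    def test_perfect_separation(self):
        assert concordance_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert concordance_auc([0.5] * 6, [1, 0, 1, 0, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            concordance_auc([0.2, 0.4], [1, 1])

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_equals_brute_force_pair_count(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 201))
        # discretized scores force plenty of ties
        p = rng.integers(0, 10, size=n) / 10.0
        y = rng.integers(0, 2, size=n)
        if y.sum() in (0, n):
            y[0], y[-1] = 0, 1
        assert concordance_auc(p, y) == pytest.approx(auc_pair_count(p, y), abs=0)


class TestCalibrationSlope:
    def test_symmetric_outcomes_give_zero_slope(self):
        p = expit(np.array([-1.0, -1.0, 1.0, 1.0]))
        slope, _ = calibration_slope(p, [0, 1, 0, 1])
        assert slope == pytest.approx(0.0, abs=1e-8)

    def test_constant_predictions_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            calibration_slope([0.5, 0.5, 0.5], [0, 1, 0])

    def test_out_of_range_predictions_rejected(self):
        with pytest.raises(ValueError):
            calibration_slope([0.0, 0.5], [0, 1])

    def test_matches_independent_newton_solver(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.05, 0.95, size=400)
        y = (rng.random(400) < p).astype(float)
        slope, intercept = calibration_slope(p, y)
        X = np.column_stack([np.ones(400), logit(p)])
        beta = logistic_newton(X, y)
        assert intercept == pytest.approx(beta[0], abs=1e-8)
        assert slope == pytest.approx(beta[1], abs=1e-8)

    def test_well_specified_simulation_slope_one(self):
        rng = np.random.default_rng(123)
        n = 50_000
        p = expit(rng.normal(-0.4, 0.9, size=n))
        y = (rng.random(n) < p).astype(float)
        slope, intercept = calibration_slope(p, y)
        assert slope == pytest.approx(1.0, abs=0.05)
        assert intercept == pytest.approx(0.0, abs=0.05)

    def test_doubled_logits_halve_the_slope(self):
        rng = np.random.default_rng(321)
        n = 50_000
        lp = rng.normal(-0.4, 0.9, size=n)
        y = (rng.random(n) < expit(lp)).astype(float)
        slope, _ = calibration_slope(expit(2 * lp), y)
        assert slope == pytest.approx(0.5, abs=0.05)


class TestCalibrationCurve:
    def test_bin_counts_sum_to_n(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.1, 0.9, 137)
        y = rng.integers(0, 2, 137)
        curve = calibration_curve(p, y)
        assert curve["n"].sum() == 137
        assert curve["mean_predicted"].is_monotonic_increasing


class TestInternalValidation:
    def test_optimism_arithmetic_is_definitional(self):
        report = ValidationReport(
            apparent_auc=0.70,
            apparent_slope=1.0,
            auc_optimisms=np.full(10, 0.05),
            slope_optimisms=np.full(10, 0.2),
            n_bootstrap=10,
            n_failed=0,
            seed=0,
        )
        assert report.corrected_auc == pytest.approx(0.65)
        assert report.corrected_slope == pytest.approx(0.8)

    def test_overfit_model_shows_positive_optimism(self):
        truth = scenario_truth("overfit-bait")
        cohort = simulate_cohort(truth, seed=77)
        spec = EUModelSpec.from_dfs({v: 3 for v in ("female_age", "t2", "int_t3_t2", "int_t5_t4")})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = internal_validate(spec, cohort, n_bootstrap=60, seed=5)
        assert report.corrected_auc < report.apparent_auc
        assert report.corrected_slope < report.apparent_slope

    def test_constant_prediction_model_rejected(self):
        # intercept-only model: every cycle gets the same prediction, so the
        # calibration slope is undefined
        truth = scenario_truth("null")
        cohort = simulate_cohort(truth, seed=6)
        with pytest.raises(ValueError, match="constant"):
            internal_validate(EUModelSpec(), cohort, n_bootstrap=10, seed=2)

    def test_fixed_model_has_near_zero_optimism(self):
        # when the "refit" returns the same frozen model on every resample
        # there is nothing to overfit, so optimism averages out to ~0
        truth = scenario_truth("clinicA-like")
        cohort = simulate_cohort(truth, seed=15)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            frozen = fit_eu_model(
                truth.spec_for_fit(), cohort, FitOptions(n_restarts=1, compute_covariance=False)
            )
            report = internal_validate(
                truth.spec_for_fit(),
                cohort,
                n_bootstrap=80,
                seed=3,
                refit=lambda sample: frozen,
            )
        assert abs(report.corrected_auc - report.apparent_auc) < 0.02
        assert abs(report.corrected_slope - report.apparent_slope) < 0.1


class TestExternalValidation:
    @pytest.fixture(scope="class")
    def fit_and_cohorts(self):
        truth = scenario_truth("clinicA-like")
        train = simulate_cohort(truth, seed=41)
        test = simulate_cohort(truth, seed=43)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_eu_model(
                truth.spec_for_fit(), train, FitOptions(n_restarts=1, compute_covariance=False)
            )
        return fit, train, test

    def test_report_structure_and_ci_order(self, fit_and_cohorts):
        fit, _, test = fit_and_cohorts
        res = external_validate(fit, test, n_ci_bootstrap=200, seed=3)
        assert res.auc_ci[0] <= res.auc <= res.auc_ci[1]
        assert res.slope_ci[0] <= res.slope <= res.slope_ci[1]
        assert res.curve["n"].sum() == res.n_cycles
        assert np.isfinite([res.auc, res.slope, res.intercept]).all()

    def test_doubled_logit_model_has_half_slope(self):
        # with u pinned at 1 the prediction logit IS the E linear predictor,
        # so doubling the true E coefficients doubles every prediction logit
        # and the calibration slope drops to ~1/2 (no fitting involved)
        import dataclasses

        base_truth = scenario_truth("clinicA-like")
        truth = dataclasses.replace(
            base_truth, name="u1", u_intercept=50.0, n_cycles=4000, n_det=0
        )
        test = simulate_cohort(truth, seed=17)
        spec1 = dataclasses.replace(truth.spec_for_fit(), u_fixed=1.0)
        be, _ = truth.true_beta()
        for scale, want in ((1.0, 1.0), (2.0, 0.5)):
            model = EUModelFit(
                spec=spec1, beta_e=scale * be, beta_u=np.zeros(0), loglik=-1.0,
                converged=True, n_cycles=0, n_embryos=0,
            )
            res = external_validate(model, test, n_ci_bootstrap=50, seed=4)
            assert res.slope == pytest.approx(want, abs=0.08)

    def test_true_model_slope_ci_covers_one_in_most_runs(self):
        # predictions from the generating model itself are calibrated, so the
        # 95% bootstrap CI for the slope should cover 1 in most fresh cohorts
        import dataclasses

        truth = scenario_truth("clinicA-like")
        spec = truth.spec_for_fit()
        be, bu = truth.true_beta()
        true_fit = EUModelFit(
            spec=spec, beta_e=be, beta_u=bu, loglik=-1.0, converged=True,
            n_cycles=0, n_embryos=0,
        )
        hits = 0
        for seed in range(10):
            test = simulate_cohort(truth, seed=900 + seed)
            res = external_validate(true_fit, test, n_ci_bootstrap=300, seed=seed)
            if res.slope_ci[0] <= 1.0 <= res.slope_ci[1]:
                hits += 1
        assert hits >= 8


class TestObservedVsFitted:
    def test_clinic_a_observed_percentages(self, clinic_a_counts_cohort):
        table = observed_vs_fitted_table(None, clinic_a_counts_cohort)
        set_row = table[table["transfer"] == "SET"].iloc[0]
        det_row = table[table["transfer"] == "DET"].iloc[0]
        assert round(set_row["observed_0_sacs_pct"], 1) == 61.3
        assert round(set_row["observed_1_sacs_pct"], 1) == 38.7
        assert set_row["observed_2_sacs_pct"] == 0.0
        assert round(det_row["observed_0_sacs_pct"], 1) == 67.9
        assert round(det_row["observed_1_sacs_pct"], 1) == 26.9
        assert round(det_row["observed_2_sacs_pct"], 1) == 5.1

    def test_clinic_b_observed_percentages(self, clinic_b_counts_cohort):
        table = observed_vs_fitted_table(None, clinic_b_counts_cohort)
        set_row = table[table["transfer"] == "SET"].iloc[0]
        det_row = table[table["transfer"] == "DET"].iloc[0]
        assert round(set_row["observed_0_sacs_pct"], 1) == 62.8
        assert round(set_row["observed_1_sacs_pct"], 1) == 37.2
        assert round(det_row["observed_0_sacs_pct"], 1) == 65.2
        assert round(det_row["observed_1_sacs_pct"], 1) == 26.2
        assert round(det_row["observed_2_sacs_pct"], 1) == 8.6

    def test_rows_sum_to_100(self, clinic_a_counts_cohort):
        table = observed_vs_fitted_table(None, clinic_a_counts_cohort)
        for _, row in table.iterrows():
            total = sum(row[f"observed_{k}_sacs_pct"] for k in (0, 1, 2))
            assert total == pytest.approx(100.0, abs=0.1)

    def test_saturated_intercept_model_fits_exactly(self):
        cohort = cohort_from_counts(set0=60, set1=40, det0=0, det1=0, det2=0)
        fit = fit_eu_model(
            EUModelSpec(u_fixed=1.0), cohort, FitOptions(compute_covariance=False)
        )
        table = observed_vs_fitted_table(fit, cohort)
        set_row = table[table["transfer"] == "SET"].iloc[0]
        assert set_row["fitted_0_sacs_pct"] == pytest.approx(60.0, abs=1e-3)
        assert set_row["fitted_1_sacs_pct"] == pytest.approx(40.0, abs=1e-3)
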