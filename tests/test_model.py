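"""EU likelihood, maximum-likelihood fitting and prediction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit

from _oracles import (
    grid_search_two_param_mle,
    loglik_enumerated,
    outcome_distribution_enumerated,
)
from conftest import cohort_from_counts, make_cycle
from eupred.cohort import Cohort
from eupred.model import (
    ETerm,
    EUModelFit,
    EUModelSpec,
    FitOptions,
    cycle_outcome_distribution,
    fit_eu_model,
    log_likelihood,
    predict_cycle,
    prediction_curve,
)
from eupred.simulate import SimulationTruth, simulate_cohort

probs = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


class TestOutcomeDistribution:
    def test_receptive_uterus_reduces_to_bernoulli(self):
        assert cycle_outcome_distribution(1.0, [0.5]) == pytest.approx([0.5, 0.5])

    def test_unreceptive_uterus_forces_no_pregnancy(self):
        assert cycle_outcome_distribution(0.0, [0.9, 0.9])[0] == 1.0

    def test_det_example_matches_enumeration(self):
        got = cycle_outcome_distribution(0.8, [0.6, 0.3])
        assert got == pytest.approx([0.424, 0.432, 0.144], abs=1e-12)
        assert got == pytest.approx(outcome_distribution_enumerated(0.8, [0.6, 0.3]))

    def test_rejects_invalid_probabilities(self):
        with pytest.raises(ValueError):
            cycle_outcome_distribution(1.2, [0.5])
        with pytest.raises(ValueError):
            cycle_outcome_distribution(0.5, [-0.1, 0.5])

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(u=probs, e1=probs, e2=probs)
    def test_equals_latent_state_enumeration(self, u, e1, e2):
        for e in ([e1], [e1, e2]):
            got = cycle_outcome_distribution(u, e)
            want = outcome_distribution_enumerated(u, e)
            assert np.max(np.abs(got - want)) < 1e-12
            assert np.sum(got) == pytest.approx(1.0, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(u=probs, e1=probs, e2=probs)
    def test_det_dominates_best_set_and_twin_below_each(self, u, e1, e2):
        det = cycle_outcome_distribution(u, [e1, e2])
        set1 = cycle_outcome_distribution(u, [e1])
        set2 = cycle_outcome_distribution(u, [e2])
        assert 1 - det[0] >= max(set1[1], set2[1]) - 1e-12
        assert det[2] <= min(set1[1], set2[1]) + 1e-12


def _intercept_spec(u_fixed=None):
    return EUModelSpec(e_terms=(), u_terms=(), u_fixed=u_fixed)


class TestLogLikelihood:
    def test_single_set_cycle_half(self):
        cohort = Cohort(cycles=[make_cycle("c1", n_sacs=1)])
        # u = 1 (fixed), e = 0.5 -> log 0.5
        spec = _intercept_spec(u_fixed=1.0)
        ll = log_likelihood(spec, np.array([0.0]), np.array([]), cohort)
        assert ll == pytest.approx(np.log(0.5))

    def test_matches_enumeration_on_toy_cohort(self):
        cohort = Cohort(
            cycles=[
                make_cycle("c1", n_sacs=1, n_embryos=1),
                make_cycle("c2", n_sacs=0, n_embryos=2),
                make_cycle("c3", n_sacs=2, n_embryos=2),
            ]
        )
        be, bu = np.array([0.3]), np.array([0.7])
        ll = log_likelihood(_intercept_spec(), be, bu, cohort)
        u, e = expit(0.7), expit(0.3)
        want = loglik_enumerated(
            [u, u, u], [[e], [e, e], [e, e]], [1, 0, 2]
        )
        assert ll == pytest.approx(want, abs=1e-12)

    def test_impossible_observation_is_minus_inf(self):
        cohort = Cohort(cycles=[make_cycle("c1", n_sacs=2, n_embryos=2)])
        spec = _intercept_spec(u_fixed=0.0)
        ll = log_likelihood(spec, np.array([0.0]), np.array([]), cohort)
        assert ll == -np.inf

    def test_wrong_parameter_length_rejected(self):
        cohort = Cohort(cycles=[make_cycle("c1", n_sacs=1)])
        with pytest.raises(ValueError, match="length"):
            log_likelihood(_intercept_spec(), np.array([0.0, 1.0]), np.array([0.0]), cohort)


class TestFitting:
    def test_bernoulli_mle_closed_form(self):
        # u pinned at 1, intercept-only E part, SET-only with 243/628 pregnant:
        # the MLE is the empirical logit
        cohort = cohort_from_counts(set0=385, set1=243, det0=0, det1=0, det2=0)
        fit = fit_eu_model(
            _intercept_spec(u_fixed=1.0), cohort, FitOptions(compute_covariance=False)
        )
        assert fit.beta_e[0] == pytest.approx(logit(243 / 628), abs=1e-6)
        assert fit.converged

    def test_two_param_fit_matches_zoomed_grid_search(self):
        truth = SimulationTruth(
            name="tiny2", n_cycles=50, n_det=20, u_intercept=1.0, e_intercept=0.2
        )
        cohort = simulate_cohort(truth, seed=11)
        counts = {
            "set0": sum(1 for c in cohort if not c.is_det and c.n_sacs == 0),
            "set1": sum(1 for c in cohort if not c.is_det and c.n_sacs == 1),
            "det0": sum(1 for c in cohort if c.is_det and c.n_sacs == 0),
            "det1": sum(1 for c in cohort if c.is_det and c.n_sacs == 1),
            "det2": sum(1 for c in cohort if c.is_det and c.n_sacs == 2),
        }
        be_grid, bu_grid = grid_search_two_param_mle(counts)
        fit = fit_eu_model(_intercept_spec(), cohort, FitOptions(compute_covariance=False))
        assert fit.beta_e[0] == pytest.approx(be_grid, abs=1e-3)
        assert fit.beta_u[0] == pytest.approx(bu_grid, abs=1e-3)

    def test_recovers_truth_within_3_se(self, recovery_cohort):
        truth, cohort = recovery_cohort
        fit = fit_eu_model(truth.spec_for_fit(), cohort, FitOptions(n_restarts=2))
        be, bu = truth.true_beta()
        est = np.concatenate([fit.beta_e, fit.beta_u])
        true = np.concatenate([be, bu])
        se = fit.standard_errors()
        assert not fit.covariance_unreliable
        assert np.all(np.abs(est - true) <= 3 * se)

    def test_set_only_cohort_warns_weak_identification(self):
        cohort = cohort_from_counts(set0=30, set1=20, det0=0, det1=0, det2=0)
        with pytest.warns(UserWarning, match="weakly identified"):
            fit_eu_model(_intercept_spec(), cohort, FitOptions(compute_covariance=False))

    def test_single_class_cohort_rejected(self):
        cohort = cohort_from_counts(set0=20, set1=0, det0=0, det1=0, det2=0)
        with pytest.raises(ValueError, match="pregnancy"):
            fit_eu_model(_intercept_spec(u_fixed=1.0), cohort)

    def test_loglik_invariant_to_cycle_order(self):
        truth = SimulationTruth(
            name="shuffle", n_cycles=120, n_det=30, u_intercept=1.5, e_intercept=-0.2
        )
        cohort = simulate_cohort(truth, seed=5)
        fit1 = fit_eu_model(_intercept_spec(), cohort, FitOptions(compute_covariance=False))
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(cohort))
        shuffled = Cohort(cycles=[cohort[int(i)] for i in perm])
        fit2 = fit_eu_model(_intercept_spec(), shuffled, FitOptions(compute_covariance=False))
        assert abs(fit1.loglik - fit2.loglik) < 1e-8


class TestSerialization:
    def test_json_round_trip_is_bit_exact(self, recovery_cohort):
        truth, cohort = recovery_cohort
        small = Cohort(cycles=list(cohort.cycles[:300]))
        fit = fit_eu_model(truth.spec_for_fit(), small, FitOptions(n_restarts=0))
        back = EUModelFit.from_json(fit.to_json())
        assert back.spec == fit.spec
        assert back.beta_e.tolist() == fit.beta_e.tolist()
        assert back.beta_u.tolist() == fit.beta_u.tolist()
        assert back.loglik == fit.loglik
        assert back.covariance.tolist() == fit.covariance.tolist()

    def test_file_round_trip(self, tmp_path, recovery_cohort):
        truth, cohort = recovery_cohort
        small = Cohort(cycles=list(cohort.cycles[:200]))
        fit = fit_eu_model(
            truth.spec_for_fit(), small, FitOptions(n_restarts=0, compute_covariance=False)
        )
        path = tmp_path / "model.json"
        fit.to_json(path)
        back = EUModelFit.from_json(path)
        assert back.beta_e.tolist() == fit.beta_e.tolist()


def _manual_fit(beta_e, beta_u, e_terms=()):
    """Assemble an EUModelFit directly from coefficients (for prediction tests)."""
    spec = EUModelSpec(e_terms=e_terms)
    return EUModelFit(
        spec=spec,
        beta_e=np.asarray(beta_e, dtype=float),
        beta_u=np.asarray(beta_u, dtype=float),
        loglik=-1.0,
        converged=True,
        n_cycles=0,
        n_embryos=0,
    )


class TestPrediction:
    def test_det_singleton_twin_pattern(self):
        # u = 0.86 with viabilities (0.488372, 0.5): singleton 43%, twin 21%,
        # while the separate SET chances are 42% and 43% — adding the second
        # embryo leaves the singleton chance at ~42-43% and only adds twin risk
        p0, p1, p2 = cycle_outcome_distribution(0.86, [0.488372, 0.5])
        assert p1 == pytest.approx(0.430, abs=5e-4)
        assert p2 == pytest.approx(0.210, abs=5e-4)
        set1 = 0.86 * 0.488372
        set2 = 0.86 * 0.5
        assert set1 == pytest.approx(0.42, abs=5e-3)
        assert set2 == pytest.approx(0.43, abs=5e-3)
        assert (1 - p0) == pytest.approx(0.640, abs=1e-3)

    def test_zero_viability_means_no_pregnancy(self):
        fit = _manual_fit([-40.0], [2.0])  # e ~ 0
        cycle = make_cycle("p", n_sacs=0)
        pred = predict_cycle(fit, cycle)
        assert pred.p_pregnant == pytest.approx(0.0, abs=1e-12)

    def test_det_twin_symmetric_in_embryo_order(self):
        fit = _manual_fit([0.1, 0.05], [1.0], e_terms=(ETerm("t2", df=1),))
        det = make_cycle("d", n_embryos=2, n_sacs=0)
        pred = predict_cycle(fit, det)
        swapped = make_cycle("d2", n_embryos=2, n_sacs=0)
        object.__setattr__(swapped, "embryos", det.embryos[::-1])
        pred2 = predict_cycle(fit, swapped)
        assert pred.p_sacs == pytest.approx(pred2.p_sacs)
        assert pred.p_sacs[2] <= pred.u * min(pred.e) + 1e-12

    def test_prediction_normalizes(self):
        fit = _manual_fit([0.3, -0.1], [0.7], e_terms=(ETerm("int_t3_t2", df=1),))
        pred = predict_cycle(fit, make_cycle("x", n_embryos=2, n_sacs=0))
        assert sum(pred.p_sacs) == pytest.approx(1.0, abs=1e-12)


class TestPredictionCurve:
    def test_intercept_only_curve_is_flat(self):
        fit = _manual_fit([0.2], [1.0])
        curve = prediction_curve(fit, "int_t3_t2", np.linspace(5, 20, 7))
        assert curve["p_pregnant"].nunique() == 1
        assert curve["p_pregnant"].iloc[0] == pytest.approx(expit(1.0) * expit(0.2))

    def test_single_point_grid_matches_predict(self):
        fit = _manual_fit([0.1, 0.03], [0.9], e_terms=(ETerm("t2", df=1),))
        curve = prediction_curve(fit, "t2", [25.0])
        cycle = make_cycle("q", n_sacs=0)  # t2 = 25
        assert curve["p_pregnant"].iloc[0] == pytest.approx(
            predict_cycle(fit, cycle).p_pregnant
        )

    def test_positive_linear_coefficient_gives_increasing_curve(self):
        fit = _manual_fit([0.0, 0.2], [1.0], e_terms=(ETerm("int_t5_t4", df=1),))
        curve = prediction_curve(fit, "int_t5_t4", np.linspace(5, 25, 9))
        assert np.all(np.diff(curve["p_pregnant"]) > 0)

    def test_unknown_covariate_rejected(self):
        fit = _manual_fit([0.2], [1.0])
        with pytest.raises(ValueError, match="unknown"):
            prediction_curve(fit, "nope", [1.0])
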