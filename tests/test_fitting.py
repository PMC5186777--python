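"""Likelihood, priors, posterior and MAP estimation."""

import math

import numpy as np
import pytest

from tomnet import (
    FitConfig,
    GridResolution,
    ModelParams,
    PriorConfig,
    StudyData,
    fit_map,
    fit_map_grid,
    grid_agreement_tolerance,
    log_likelihood,
    log_posterior,
    log_prior,
    predict_false_belief_closed_form,
    predicted_vs_observed,
    simulate_study_counts,
)

UNIFORM = PriorConfig(b_delta=1.0, b_eps=1.0)


def _hand_log_binom(k, n, p):
    return (
        math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
        + k * math.log(p) + (n - k) * math.log(1 - p)
    )


class TestStudyData:
    def test_rejects_k_above_n(self):
        with pytest.raises(ValueError, match="k_ka"):
            StudyData("x", 5, 10, 11, 10, 5, 10)

    def test_rejects_zero_total(self):
        with pytest.raises(ValueError, match="n_fb"):
            StudyData("x", 5, 10, 5, 10, 0, 0)


class TestLogLikelihood:
    def test_certain_success_has_zero_loglik(self):
        data = StudyData("x", 20, 20, 20, 20, 20, 20)
        assert log_likelihood(ModelParams(1, 1, 0, 0), data) == 0.0

    def test_single_bernoulli_trial(self):
        # DB: one trial at p=0.5; KA and FB at certainty with k=n
        # (delta=1 drives pi_FB = 0.5*1 + (1 - 0.5)*1 = 1)
        params = ModelParams(0.5, 1.0, 1.0, 0.0)
        data = StudyData("x", 1, 1, 7, 7, 4, 4)
        assert log_likelihood(params, data) == pytest.approx(math.log(0.5))

    def test_matches_termwise_hand_evaluation(self, example_params):
        data = StudyData("x", 40, 50, 35, 50, 28, 50)
        pi_fb = predict_false_belief_closed_form(example_params)
        expected = (
            _hand_log_binom(40, 50, 0.8)
            + _hand_log_binom(35, 50, 0.7)
            + _hand_log_binom(28, 50, pi_fb)
        )
        assert log_likelihood(example_params, data) == pytest.approx(
            expected, abs=1e-10
        )

    def test_impossible_count_gives_neg_infinity(self):
        data = StudyData("x", 1, 10, 5, 10, 5, 10)
        assert log_likelihood(ModelParams(0, 0.5, 0, 0), data) == -math.inf


class TestLogPrior:
    def test_uniform_priors_vanish(self):
        assert log_prior(ModelParams(0.3, 0.9, 0.2, 0.7), UNIFORM) == 0.0

    def test_asymmetric_prior_at_zero(self):
        # Beta(1, 19) density at 0 equals 19 for both noise parameters
        value = log_prior(ModelParams(0.5, 0.5, 0.0, 0.0), PriorConfig())
        assert value == pytest.approx(2 * math.log(19))

    def test_asymmetric_prior_interior(self):
        value = log_prior(ModelParams(0.5, 0.5, 0.05, 0.0), PriorConfig())
        assert value == pytest.approx(
            math.log(19 * 0.95 ** 18) + math.log(19)
        )

    def test_vanishing_density_at_boundary(self):
        # Beta(1, 19) vanishes at 1
        assert log_prior(ModelParams(0.5, 0.5, 1.0, 0.0), PriorConfig()) == -math.inf

    def test_rejects_nonpositive_shape(self):
        with pytest.raises(ValueError, match="b_delta"):
            PriorConfig(b_delta=0.0)


class TestLogPosterior:
    def test_uniform_prior_reduces_to_likelihood(self):
        data = StudyData("x", 12, 20, 15, 20, 9, 20)
        params = ModelParams(0.6, 0.7, 0.03, 0.03)
        assert log_posterior(params, data, UNIFORM) == log_likelihood(params, data)

    def test_infinite_likelihood_dominates(self):
        data = StudyData("x", 1, 10, 5, 10, 5, 10)
        assert log_posterior(ModelParams(0, 0.5, 0, 0), data, PriorConfig()) == -math.inf

    def test_additivity(self, example_params):
        data = StudyData("x", 40, 50, 35, 50, 28, 50)
        priors = PriorConfig()
        assert log_posterior(example_params, data, priors) == pytest.approx(
            log_likelihood(example_params, data) + log_prior(example_params, priors)
        )

    def test_finite_on_open_hypercube_for_interior_counts(self):
        data = StudyData("x", 12, 20, 15, 20, 9, 20)
        rng = np.random.default_rng(5)
        for row in rng.uniform(0.01, 0.99, size=(50, 4)):
            value = log_posterior(ModelParams(*row), data, PriorConfig())
            assert math.isfinite(value)


class TestFitMap:
    def test_ceiling_data_pushes_to_noiseless_corner(self):
        data = StudyData("x", 100, 100, 100, 100, 100, 100)
        result = fit_map(data)
        assert result.map_params.pi_B > 0.98
        assert result.map_params.pi_V > 0.98
        assert result.map_params.delta < 0.02
        assert result.map_params.epsilon < 0.02
        assert result.boundary_flags["pi_B"]

    def test_recovers_generating_parameters(self):
        truth = ModelParams(0.8, 0.7, 0.02, 0.02)
        data = simulate_study_counts(truth, 10_000, seed=1)
        result = fit_map(data)
        assert result.map_params.pi_B == pytest.approx(0.8, abs=0.02)
        assert result.map_params.pi_V == pytest.approx(0.7, abs=0.02)

    def test_map_beats_plugin_candidate(self):
        data = StudyData("x", 13, 30, 22, 30, 8, 30)
        priors = PriorConfig()
        result = fit_map(data, priors)
        plugin = ModelParams(
            pi_B=13 / 30, pi_V=22 / 30,
            delta=priors.mode("delta") or 1e-4,
            epsilon=priors.mode("epsilon") or 1e-4,
        )
        assert result.log_posterior_at_map >= log_posterior(plugin, data, priors)

    def test_fitted_fb_is_closed_form_of_map(self):
        data = StudyData("x", 13, 30, 22, 30, 8, 30)
        result = fit_map(data)
        assert result.fitted_proportions[2] == predict_false_belief_closed_form(
            result.map_params
        )

    def test_deterministic_given_seed(self):
        data = StudyData("x", 13, 30, 22, 30, 8, 30)
        a = fit_map(data, config=FitConfig(seed=42))
        b = fit_map(data, config=FitConfig(seed=42))
        assert a.map_params == b.map_params
        assert a.log_posterior_at_map == b.log_posterior_at_map


class TestFitMapGrid:
    def test_single_point_grid_returns_it(self):
        res = GridResolution(
            pi_B_values=[0.5], pi_V_values=[0.5],
            delta_values=[0.05], epsilon_values=[0.05],
        )
        data = StudyData("x", 13, 30, 22, 30, 8, 30)
        result = fit_map_grid(data, resolution=res)
        assert result.map_params == ModelParams(0.5, 0.5, 0.05, 0.05)
        assert result.method == "grid"

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty grid"):
            fit_map_grid(
                StudyData("x", 1, 2, 1, 2, 1, 2),
                resolution=GridResolution(pi_B_values=[]),
            )

    def test_swapping_db_and_ka_swaps_estimates(self):
        # pi_FB depends on pi_B and pi_V only through their product, so with
        # equal priors the posterior is symmetric under the swap
        a = fit_map_grid(StudyData("x", 40, 50, 30, 50, 22, 50))
        b = fit_map_grid(StudyData("x", 30, 50, 40, 50, 22, 50))
        assert a.map_params.pi_B == b.map_params.pi_V
        assert a.map_params.pi_V == b.map_params.pi_B
        assert a.map_params.delta == b.map_params.delta
        assert a.map_params.epsilon == b.map_params.epsilon

    def test_agrees_with_optimizer_to_grid_resolution(self):
        rng = np.random.default_rng(17)
        res = GridResolution()
        for _ in range(5):
            truth = ModelParams(
                rng.uniform(0.3, 0.95), rng.uniform(0.3, 0.95),
                rng.uniform(0.0, 0.1), rng.uniform(0.0, 0.1),
            )
            data = simulate_study_counts(truth, 500, seed=int(rng.integers(2**31)))
            opt = fit_map(data)
            grid = fit_map_grid(data, resolution=res)
            assert opt.log_posterior_at_map >= grid.log_posterior_at_map - 1e-9
            for name in ("pi_B", "pi_V", "delta", "epsilon"):
                tol = grid_agreement_tolerance(name, opt.map_params, res)
                assert abs(
                    getattr(opt.map_params, name)
                    - getattr(grid.map_params, name)
                ) <= tol + 1e-9


class TestPredictedVsObserved:
    def test_schema(self):
        data = StudyData("x", 13, 30, 22, 30, 8, 30)
        table = predicted_vs_observed(fit_map(data), data)
        assert list(table["task"]) == ["DB", "KA", "FB"]
        assert len(table) == 3
        assert ((table["observed"] >= 0) & (table["observed"] <= 1)).all()
        assert ((table["fitted"] >= 0) & (table["fitted"] <= 1)).all()

    def test_consistent_data_fits_closely(self):
        # counts chosen so k_FB/n_FB equals the DB*KA product exactly
        data = StudyData("x", 800, 1000, 700, 1000, 560, 1000)
        table = predicted_vs_observed(fit_map(data), data)
        assert table["abs_diff"].max() <= 0.02

    def test_repeat_fit_gives_identical_table(self):
        data = StudyData("x", 13, 30, 22, 30, 8, 30)
        t1 = predicted_vs_observed(fit_map(data), data)
        t2 = predicted_vs_observed(fit_map(data), data)
        assert t1.equals(t2)

    def test_multiplicative_relation_at_small_noise(self):
        data = StudyData("x", 800, 1000, 700, 1000, 560, 1000)
        result = fit_map(data)
        p = result.map_params
        if max(p.delta, p.epsilon) < 0.05:
            assert abs(
                result.fitted_proportions[2] - p.pi_B * p.pi_V
            ) <= max(p.delta, p.epsilon) + 1e-12
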