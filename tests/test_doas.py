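"""The four dose-optimisation strategies and their building blocks."""

import numpy as np
import pytest
from scipy.special import expit

from cobedose import (
    AdaptiveNaiveStrategy,
    CoBeStrategy,
    DosingDomain,
    KernelSpec,
    Observation,
    ParametricStrategy,
    UniformNaiveStrategy,
    UtilitySpec,
    fit_parametric,
    latent_linear,
    latent_quadratic,
    make_strategy,
)
from cobedose.doas import (
    FitError,
    argmax_random_ties,
    make_pseudo_data,
    softmax_probabilities,
    uniform_naive_allocate,
)

MAX_EFF = UtilitySpec.maximum_efficacy()


class TestLatentModels:
    def test_quadratic_at_zero_params(self):
        assert latent_quadratic([[0.3]], (0, 0, 0))[0] == pytest.approx(0.5)

    def test_quadratic_scalar_value(self):
        # z = 0 + 4*0.5 - 4*0.25 = 1
        assert latent_quadratic([[0.5]], (0, 4, 4))[0] == pytest.approx(expit(1.0))

    def test_quadratic_monotone_in_intercept(self):
        vals = [latent_quadratic([[0.4]], (a, 1, 1))[0] for a in (-5, 0, 5, 50)]
        assert all(v1 < v2 for v1, v2 in zip(vals, vals[1:]))
        assert vals[-1] > 0.999

    def test_quadratic_2d_uses_each_axis_squared(self):
        # symmetric parameters must give a symmetric surface
        p = (0.0, 2.0, 3.0, 2.0, 3.0)
        a = latent_quadratic([[0.2, 0.9]], p)[0]
        b = latent_quadratic([[0.9, 0.2]], p)[0]
        assert a == pytest.approx(b)

    def test_linear_scalar_values(self):
        assert latent_linear([[0.5]], (0, 0))[0] == pytest.approx(0.5)
        assert latent_linear([[0.5]], (-2, 4))[0] == pytest.approx(0.5)

    def test_linear_monotone_for_positive_slope(self):
        grid = np.linspace(0, 1, 21).reshape(-1, 1)
        vals = latent_linear(grid, (-1.0, 3.0))
        assert np.all(np.diff(vals) > 0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            latent_quadratic([[0.5, 0.5]], (0, 1, 1))
        with pytest.raises(ValueError):
            latent_linear([[0.5, 0.5, 0.5]], (0, 1, 1, 1))


class TestParametricFit:
    def test_probability_recovery_at_large_n(self):
        """Fitted curve within 0.03 of truth everywhere, n = 5000."""
        rng = np.random.default_rng(42)
        truth = (-1.0, 6.0, 4.0)
        doses = rng.random((5000, 1))
        y = (rng.random(5000) < latent_quadratic(doses, truth)).astype(float)
        params = fit_parametric("efficacy", doses, y)
        grid = np.linspace(0, 1, 101).reshape(-1, 1)
        err = np.abs(latent_quadratic(grid, params) - latent_quadratic(grid, truth))
        assert err.max() < 0.03

    def test_no_data_fit_is_finite(self):
        params = fit_parametric("efficacy", np.empty((0, 1)), np.empty(0))
        assert np.all(np.isfinite(params))

    def test_pseudo_data_prevent_separation_divergence(self):
        # all responders: the unpenalised MLE pushes the intercept to +inf
        doses = np.linspace(0, 1, 50).reshape(-1, 1)
        params = fit_parametric("efficacy", doses, np.ones(50))
        assert np.all(np.isfinite(params))
        assert np.abs(params).max() < 50

    def test_toxicity_fit_recovers_slope_sign(self):
        rng = np.random.default_rng(5)
        doses = rng.random((2000, 1))
        y = (rng.random(2000) < latent_linear(doses, (-2.0, 3.0))).astype(float)
        params = fit_parametric("toxicity", doses, y)
        assert params[1] > 0

    def test_pseudo_data_layout(self):
        d1, y1, w1 = make_pseudo_data(1)
        assert sorted(set(d1[:, 0])) == [0.0, 0.5, 1.0]
        assert y1.sum() == 3 and len(y1) == 6
        assert np.all(w1 == 0.5)
        d2, y2, _ = make_pseudo_data(2)
        assert len(d2) == 10  # 4 corners + centre, success and failure each


class TestSoftmaxSelection:
    def test_greedy_limit(self):
        probs = softmax_probabilities(np.array([0.8, 0.6, 0.1]), temperature=1e-4)
        assert probs[0] == pytest.approx(1.0)

    def test_uniform_limit(self):
        probs = softmax_probabilities(np.array([0.8, 0.6, 0.1]), temperature=1e6)
        np.testing.assert_allclose(probs, 1 / 3, atol=1e-6)

    def test_two_dose_frequency(self):
        """U=(0.8, 0.6), T=0.1: pick-first probability e^8/(e^8+e^6)."""
        expected = np.exp(8) / (np.exp(8) + np.exp(6))
        probs = softmax_probabilities(np.array([0.8, 0.6]), temperature=0.1)
        assert probs[0] == pytest.approx(expected, rel=1e-12)
        rng = np.random.default_rng(1)
        draws = rng.choice(2, size=10_000, p=probs)
        freq = np.mean(draws == 0)
        se = np.sqrt(expected * (1 - expected) / 10_000)
        assert abs(freq - expected) < 3 * se

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            softmax_probabilities(np.array([0.5]), temperature=0.0)


class TestThompsonSelection:
    def _frozen_cobe(self, alphas, betas):
        domain = DosingDomain.regular_grid(len(alphas), 1)
        strat = CoBeStrategy(domain, MAX_EFF)
        strat.state.alpha[:, 0] = alphas
        strat.state.beta[:, 0] = betas
        return strat

    def test_dominant_dose_nearly_always_selected(self):
        strat = self._frozen_cobe([200, 1, 1, 1], [1, 200, 200, 200])
        idx = strat.propose_cohort(1000, np.random.default_rng(0))
        assert np.mean(idx == 0) >= 0.99

    def test_symmetric_states_select_uniformly(self):
        strat = self._frozen_cobe([1, 1, 1, 1], [1, 1, 1, 1])
        idx = strat.propose_cohort(10_000, np.random.default_rng(1))
        freq = np.bincount(idx, minlength=4) / 10_000
        se = np.sqrt(0.25 * 0.75 / 10_000)
        np.testing.assert_allclose(freq, 0.25, atol=3 * se)

    def test_two_dose_selection_probability(self):
        """P(select first) = P(X > Y), X ~ Beta(2,1), Y ~ U(0,1)."""
        strat = self._frozen_cobe([2, 1], [1, 1])
        rng = np.random.default_rng(2)
        idx = strat.propose_cohort(100_000, rng)
        freq = np.mean(idx == 0)
        oracle_rng = np.random.default_rng(3)
        x = oracle_rng.beta(2, 1, 1_000_000)
        y = oracle_rng.random(1_000_000)
        oracle = np.mean(x > y)  # closed form: 2/3
        se = np.sqrt(oracle * (1 - oracle) * (1 / 1e5 + 1 / 1e6))
        assert abs(freq - oracle) < 2 * se
        assert oracle == pytest.approx(2 / 3, abs=2e-3)

    def test_frequencies_match_probability_of_optimality(self):
        """Empirical Thompson frequencies vs a brute-force joint-draw oracle."""
        alphas = np.array([3.0, 5.0, 2.0, 4.0])
        betas = np.array([2.0, 5.0, 1.0, 2.0])
        strat = self._frozen_cobe(alphas, betas)
        idx = strat.propose_cohort(100_000, np.random.default_rng(4))
        freq = np.bincount(idx, minlength=4) / 100_000

        oracle_rng = np.random.default_rng(5)
        joint = oracle_rng.beta(alphas, betas, size=(100_000, 4))
        p_opt = np.bincount(np.argmax(joint, axis=1), minlength=4) / 100_000
        se = np.sqrt(p_opt * (1 - p_opt) * 2 / 100_000)
        np.testing.assert_array_less(np.abs(freq - p_opt), 3 * se + 1e-12)


class TestFinalDoseSelection:
    def test_worked_example_prefers_updated_dose(self):
        # d1 ~ Beta(2,1) has median sqrt(0.5) > median of Beta(1.5,1)
        domain = DosingDomain([[0.0], [0.5]])
        strat = CoBeStrategy(domain, MAX_EFF)
        strat.state.alpha[:, 0] = [2.0, 1.5]
        assert strat.nominate(np.random.default_rng(0)) == 0

    def test_flat_prior_ties_break_uniformly(self):
        domain = DosingDomain.regular_grid(4, 1)
        strat = CoBeStrategy(domain, MAX_EFF)
        rng = np.random.default_rng(6)
        picks = np.bincount(
            [strat.nominate(rng) for _ in range(10_000)], minlength=4
        ) / 10_000
        se = np.sqrt(0.25 * 0.75 / 10_000)
        np.testing.assert_allclose(picks, 0.25, atol=3 * se)

    def test_contour_prefers_safer_dose(self):
        """High-toxicity dose loses to a moderately efficacious safe dose."""
        contour = UtilitySpec.contour()
        domain = DosingDomain([[0.0], [1.0]])
        strat = CoBeStrategy(domain, contour)
        # dose 1: very efficacious but toxic beyond the anchor
        strat.state.alpha[1, 0], strat.state.beta[1, 0] = 90, 10  # p_eff ~ 0.9
        strat.state.alpha[1, 1], strat.state.beta[1, 1] = 80, 20  # p_tox ~ 0.8
        # dose 0: moderate efficacy, nearly no toxicity
        strat.state.alpha[0, 0], strat.state.beta[0, 0] = 60, 40
        strat.state.alpha[0, 1], strat.state.beta[0, 1] = 1, 99
        from cobedose.ccbp import medians
        from cobedose.utility import utility_vector

        ranked = utility_vector(
            medians(strat.state, "efficacy"), medians(strat.state, "toxicity"), contour
        )
        pick = strat.nominate(np.random.default_rng(0))
        assert pick == int(np.argmax(ranked)) == 0

    def test_argmax_random_ties_uniform(self):
        rng = np.random.default_rng(8)
        picks = np.bincount(
            [argmax_random_ties(np.array([1.0, 1.0, 0.5]), rng) for _ in range(4000)],
            minlength=3,
        )
        assert picks[2] == 0
        assert abs(picks[0] - 2000) < 3 * np.sqrt(4000 * 0.25)


class TestParametricStrategy:
    def test_monotone_fit_nominates_highest_dose(self):
        domain = DosingDomain.regular_grid(101, 1)
        strat = ParametricStrategy(domain, MAX_EFF)
        doses = np.tile(np.linspace(0, 1, 10), 20).reshape(-1, 1)
        p = latent_quadratic(doses, (-2.0, 4.0, 0.0))
        rng = np.random.default_rng(9)
        strat.observe(
            [
                Observation((d[0],), efficacy=int(rng.random() < pi))
                for d, pi in zip(doses, p)
            ]
        )
        assert strat.nominate(rng) == 100

    def test_interior_vertex_recovered(self):
        """Quadratic truth peaking at b/(2c): nomination within one grid step."""
        domain = DosingDomain.regular_grid(101, 1)
        strat = ParametricStrategy(domain, MAX_EFF)
        truth = (-1.0, 8.0, 10.0)  # vertex at 0.4
        rng = np.random.default_rng(10)
        doses = rng.random((3000, 1))
        strat.observe(
            [
                Observation((d[0],), efficacy=int(rng.random() < pi))
                for d, pi in zip(doses, latent_quadratic(doses, truth))
            ]
        )
        nominated = domain.doses[strat.nominate(rng), 0]
        assert abs(nominated - 0.4) <= 0.05

    def test_nomination_matches_brute_force_scan(self):
        domain = DosingDomain.regular_grid(51, 1)
        strat = ParametricStrategy(domain, MAX_EFF)
        rng = np.random.default_rng(11)
        strat.observe(
            [Observation((rng.random(),), efficacy=int(rng.random() < 0.5)) for _ in range(40)]
        )
        utilities = strat.predicted_utilities()
        assert strat.nominate(rng) == int(np.argmax(utilities))

    def test_proposals_follow_softmax_distribution(self):
        domain = DosingDomain.regular_grid(6, 1)
        strat = ParametricStrategy(domain, MAX_EFF, temperature=0.07)
        rng = np.random.default_rng(12)
        strat.observe(
            [Observation((0.6,), efficacy=1) for _ in range(10)]
            + [Observation((0.0,), efficacy=0) for _ in range(10)]
        )
        expected = softmax_probabilities(strat.predicted_utilities(), 0.07)
        idx = strat.propose_cohort(20_000, rng)
        freq = np.bincount(idx, minlength=6) / 20_000
        se = np.sqrt(expected * (1 - expected) / 20_000)
        np.testing.assert_array_less(np.abs(freq - expected), 3 * se + 1e-3)

    def test_3d_toxicity_unsupported(self):
        domain = DosingDomain.regular_grid(3, 3)
        with pytest.raises(ValueError, match="3-D"):
            ParametricStrategy(domain, UtilitySpec.contour())


class TestNaiveStrategies:
    def test_adaptive_update_touches_one_dose(self, coarse_1d):
        strat = AdaptiveNaiveStrategy(coarse_1d, MAX_EFF)
        strat.observe([Observation((0.2,), efficacy=1)])
        assert strat.state.alpha[1, 0] == 2.0
        assert strat.state.alpha[:, 0].sum() == 7.0

    def test_dominant_state_selected(self, coarse_1d):
        strat = AdaptiveNaiveStrategy(coarse_1d, MAX_EFF)
        strat.state.alpha[3, 0] = 300.0
        strat.state.beta[[0, 1, 2, 4, 5], 0] = 300.0
        idx = strat.propose_cohort(500, np.random.default_rng(13))
        assert np.mean(idx == 3) > 0.99

    def test_cobe_with_vanishing_lengths_matches_adaptive(self, coarse_1d, rng):
        cobe = CoBeStrategy(coarse_1d, MAX_EFF, kernel_eff=KernelSpec((1e-6,)))
        naive = AdaptiveNaiveStrategy(coarse_1d, MAX_EFF)
        batch = [
            Observation(tuple(coarse_1d[rng.integers(6)]), efficacy=int(rng.random() < 0.5))
            for _ in range(30)
        ]
        cobe.observe(batch)
        naive.observe(batch)
        np.testing.assert_allclose(cobe.state.alpha, naive.state.alpha, atol=1e-9)
        np.testing.assert_allclose(cobe.state.beta, naive.state.beta, atol=1e-9)

    def test_uniform_allocation_covers_domain_once(self, coarse_1d):
        idx = uniform_naive_allocate(coarse_1d)
        assert sorted(idx) == list(range(6))

    def test_uniform_cohort_size_enforced(self, coarse_1d):
        strat = UniformNaiveStrategy(coarse_1d, MAX_EFF)
        assert strat.required_cohort_size == 6
        with pytest.raises(ValueError, match="cohort size"):
            strat.propose_cohort(5, np.random.default_rng(0))

    def test_uniform_allocation_ignores_outcomes(self, coarse_1d):
        strat = UniformNaiveStrategy(coarse_1d, MAX_EFF)
        rng = np.random.default_rng(14)
        first = strat.propose_cohort(6, rng)
        strat.observe([Observation((d,), efficacy=0) for d in coarse_1d.doses[:, 0]])
        second = strat.propose_cohort(6, rng)
        np.testing.assert_array_equal(first, second)


class TestFactoryAndDeterminism:
    def test_factory_domains(self, grid_1d):
        assert len(make_strategy("cobe", grid_1d, MAX_EFF).trial_domain) == 101
        assert len(make_strategy("adaptive_naive", grid_1d, MAX_EFF).trial_domain) == 6
        assert len(make_strategy("uniform_naive", grid_1d, MAX_EFF).trial_domain) == 6
        with pytest.raises(ValueError):
            make_strategy("nonsense", grid_1d, MAX_EFF)

    @pytest.mark.parametrize("name", ["cobe", "parametric", "adaptive_naive", "uniform_naive"])
    def test_identical_seeds_identical_choices(self, name, grid_1d):
        runs = []
        for _ in range(2):
            strat = make_strategy(name, grid_1d, MAX_EFF)
            rng = np.random.default_rng(99)
            c = strat.required_cohort_size or 6
            idx = strat.propose_cohort(c, rng)
            strat.observe(
                [Observation(tuple(strat.trial_domain[i]), efficacy=1) for i in idx]
            )
            runs.append((idx.tolist(), strat.nominate(rng)))
        assert runs[0] == runs[1]

    @pytest.mark.parametrize("name", ["cobe", "parametric", "adaptive_naive", "uniform_naive"])
    def test_proposals_stay_in_trial_domain(self, name, grid_1d):
        strat = make_strategy(name, grid_1d, MAX_EFF)
        rng = np.random.default_rng(15)
        c = strat.required_cohort_size or 6
        idx = strat.propose_cohort(c, rng)
        assert np.all((0 <= idx) & (idx < len(strat.trial_domain)))
        assert 0 <= strat.nominate(rng) < len(strat.prediction_domain)
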