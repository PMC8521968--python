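import numpy as np
import pytest
from scipy.stats import norm

from oracles import quad_evidence, quad_probit_gaussian

from bayespta.gp_mixture import AlphaTable, GPComponent, MixtureModel, SideInfo, mixing_weights
from bayespta.inference import (
    laplace_fit_component,
    posterior_log_likelihood,
    posterior_mixture,
    posterior_predictive_response,
    posterior_threshold_estimate,
    predict_threshold_component,
)
from bayespta.response_model import Stimulus, Trial


def make_trials(pairs):
    """pairs: iterable of (x, h, y)."""
    return [Trial(Stimulus(x, h), y) for x, h, y in pairs]


class TestLaplaceFit:
    def test_zero_trials_returns_prior(self, simple_component):
        post = laplace_fit_component(simple_component, [], 5.0)
        assert post.log_evidence == 0.0
        assert post.log_evidence_laplace == 0.0
        mu, sd = post.predict([4.0, 12.0])
        np.testing.assert_allclose(mu, simple_component.mean(np.array([4.0, 12.0])))
        np.testing.assert_allclose(sd, np.sqrt(simple_component.kernel_variance))

    def test_one_trial_evidence_matches_quadrature(self, simple_component):
        trials = make_trials([(8.0, 35.0, 1)])
        post = laplace_fit_component(simple_component, trials, 5.0)
        expected = np.log(quad_evidence(simple_component, trials, 5.0))
        assert post.log_evidence == pytest.approx(expected, abs=1e-3)

    def test_laplace_expansion_evidence_at_moderate_scale(self):
        # the expansion estimate is accurate when prior SD ~ sigma_p
        comp = GPComponent((30.0, 0.0, 0.0, 0.0), 25.0, 4.0)
        for h, y in [(30.0, 1), (35.0, -1), (25.0, 1)]:
            trials = make_trials([(10.0, h, y)])
            post = laplace_fit_component(comp, trials, 5.0, evidence="laplace")
            expected = np.log(quad_evidence(comp, trials, 5.0))
            assert post.log_evidence == post.log_evidence_laplace
            assert post.log_evidence == pytest.approx(expected, abs=1e-2)

    def test_audible_trial_pulls_mode_down(self, simple_component):
        # an audible response implies the threshold lies below the tone level
        x = 8.0
        prior_mean = simple_component.mean(np.array([x]))[0]
        trials = make_trials([(x, prior_mean + 10.0, 1)])
        post = laplace_fit_component(simple_component, trials, 5.0)
        assert post.posterior_mode[0] <= prior_mean

    def test_duplicate_frequencies_share_latent(self, simple_component):
        trials = make_trials([(8.0, 35.0, 1), (8.0, 30.0, -1), (12.0, 50.0, 1)])
        post = laplace_fit_component(simple_component, trials, 5.0)
        assert post.training_xs.size == 2

    def test_converges_on_many_consistent_trials(self, simple_component):
        rng = np.random.default_rng(5)
        xs = np.linspace(2.0, 18.0, 6)
        t_true = simple_component.mean(xs)
        trials = []
        for _ in range(30):
            j = int(rng.integers(6))
            h = t_true[j] + rng.uniform(-15, 15)
            y = 1 if h > t_true[j] else -1
            trials.append(Trial(Stimulus(float(xs[j]), float(h)), y))
        post = laplace_fit_component(simple_component, trials, 5.0)
        assert np.all(np.isfinite(post.posterior_mode))
        assert np.linalg.eigvalsh(post.posterior_cov).min() > 0


class TestPosteriorMixture:
    def test_single_component_weight(self, single_component_model):
        state = posterior_mixture(
            single_component_model, SideInfo(), make_trials([(8.0, 35.0, 1)])
        )
        np.testing.assert_allclose(state.pi, [1.0])

    def test_zero_trials_gives_prior_weights(self, population_model):
        info = SideInfo(age=80, gender="female")
        state = posterior_mixture(population_model, info, [])
        np.testing.assert_allclose(state.pi, mixing_weights(population_model, info))

    def test_weights_match_bruteforce_quadrature(self, two_component_model):
        trials = make_trials([(5.0, 25.0, 1), (12.0, 50.0, -1)])
        state = posterior_mixture(two_component_model, SideInfo(), trials)
        alpha = mixing_weights(two_component_model, SideInfo())
        z = np.array(
            [quad_evidence(c, trials, two_component_model.sigma_p) for c in two_component_model.components]
        )
        pi_expected = alpha * z / np.sum(alpha * z)
        np.testing.assert_allclose(state.pi, pi_expected, atol=0.02)

    def test_weights_normalized_along_a_session(self, population_model, rng):
        trials = []
        for h in (30.0, 20.0, 45.0, 10.0):
            trials.append(Trial(Stimulus(10.0, h), int(rng.choice([-1, 1]))))
            state = posterior_mixture(population_model, SideInfo(), trials)
            assert state.pi.sum() == pytest.approx(1.0, abs=1e-10)
            assert np.all(state.pi >= 0)

    def test_sequential_refit_equals_batch(self, two_component_model):
        trials = make_trials([(5.0, 25.0, 1), (12.0, 50.0, -1), (5.0, 15.0, -1)])
        running = []
        for t in trials:
            running.append(t)
            seq_state = posterior_mixture(two_component_model, SideInfo(), running)
        batch_state = posterior_mixture(two_component_model, SideInfo(), trials)
        np.testing.assert_array_equal(seq_state.pi, batch_state.pi)
        for a, b in zip(seq_state.component_posteriors, batch_state.component_posteriors):
            np.testing.assert_array_equal(a.posterior_mode, b.posterior_mode)
            np.testing.assert_array_equal(a.posterior_cov, b.posterior_cov)


class TestPrediction:
    def test_training_frequency_consistency(self, simple_component):
        trials = make_trials([(8.0, 35.0, 1), (12.0, 20.0, -1)])
        post = laplace_fit_component(simple_component, trials, 5.0)
        mu, sd = post.predict(post.training_xs)
        np.testing.assert_allclose(mu, post.posterior_mode, atol=1e-8)
        np.testing.assert_allclose(sd, np.sqrt(np.diag(post.posterior_cov)), atol=1e-8)

    def test_far_frequency_reverts_to_prior(self, simple_component):
        trials = make_trials([(2.0, 35.0, 1)])
        post = laplace_fit_component(simple_component, trials, 5.0)
        x_far = 2.0 + 30.0 * simple_component.kernel_lengthscale
        mu, sd = post.predict(x_far)
        assert mu[0] == pytest.approx(simple_component.mean(np.array([x_far]))[0], rel=0.01)
        assert sd[0] == pytest.approx(np.sqrt(simple_component.kernel_variance), rel=0.01)

    def test_predict_threshold_component_surface(self, simple_component):
        post = laplace_fit_component(simple_component, [], 5.0)
        mu, sd = predict_threshold_component(post, simple_component, 9.0)
        assert mu[0] == pytest.approx(simple_component.mean(np.array([9.0]))[0])

    def test_posterior_sd_shrinks_with_trials(self, simple_component, rng):
        x = 9.0
        t_true = simple_component.mean(np.array([x]))[0]
        sds = []
        for n in (0, 3, 10):
            sd_reps = []
            for _ in range(10):
                trials = []
                for _ in range(n):
                    h = t_true + rng.uniform(-10, 10)
                    y = 1 if rng.random() < norm.cdf((h - t_true) / 5.0) else -1
                    trials.append(Trial(Stimulus(x, float(h)), y))
                post = laplace_fit_component(simple_component, trials, 5.0)
                sd_reps.append(post.predict(x)[1][0])
            sds.append(np.mean(sd_reps))
        assert sds[0] > sds[1] > sds[2]


class TestPosteriorPredictive:
    def test_half_probability_at_posterior_mean(self, single_component_model):
        state = posterior_mixture(single_component_model, SideInfo(), [])
        mu = single_component_model.components[0].mean(np.array([9.0]))[0]
        assert posterior_predictive_response(state, Stimulus(9.0, mu)) == pytest.approx(0.5)

    def test_matches_quadrature(self, two_component_model):
        trials = make_trials([(5.0, 25.0, 1), (12.0, 50.0, -1)])
        state = posterior_mixture(two_component_model, SideInfo(), trials)
        for x, h in [(5.0, 30.0), (9.0, 10.0), (14.0, 60.0)]:
            closed = posterior_predictive_response(state, Stimulus(x, h))
            expected = 0.0
            for pi_c, post in zip(state.pi, state.component_posteriors):
                mu, sd = post.predict(x)
                expected += pi_c * quad_probit_gaussian(1, h, mu[0], sd[0], state.model.sigma_p)
            assert closed == pytest.approx(expected, abs=1e-6)

    def test_reduces_to_response_probability_when_certain(self):
        comp = GPComponent((40.0, 0.0, 0.0, 0.0), 1e-10, 4.0)
        model = MixtureModel([comp], AlphaTable.constant([1.0]), sigma_p=5.0)
        state = posterior_mixture(model, SideInfo(), [])
        p = posterior_predictive_response(state, Stimulus(9.0, 45.0))
        assert p == pytest.approx(norm.cdf(1.0), abs=1e-6)


class TestThresholdEstimate:
    def test_single_component_moments(self, single_component_model):
        state = posterior_mixture(single_component_model, SideInfo(), [])
        xs = np.array([4.0, 10.0])
        mean, sd, mus, sigmas = posterior_threshold_estimate(state, xs)
        np.testing.assert_allclose(mean, mus[0])
        np.testing.assert_allclose(sd, sigmas[0])

    def test_equal_components_mean_independent_of_weights(self):
        comp = GPComponent((30.0, 1.0, 0.0, 0.0), 50.0, 4.0)
        for w in ([0.2, 0.8], [0.7, 0.3]):
            model = MixtureModel([comp, comp], AlphaTable.constant(w), sigma_p=5.0)
            state = posterior_mixture(model, SideInfo(), [])
            mean, _, _, _ = posterior_threshold_estimate(state, np.array([9.0]))
            assert mean[0] == pytest.approx(comp.mean(np.array([9.0]))[0])

    def test_total_variance_formula(self):
        # pi=(.5,.5), mu=(0,10), sigma=(1,1) -> mixture SD = sqrt(26)
        c0 = GPComponent((0.0, 0.0, 0.0, 0.0), 1.0, 4.0)
        c1 = GPComponent((10.0, 0.0, 0.0, 0.0), 1.0, 4.0)
        model = MixtureModel([c0, c1], AlphaTable.constant([0.5, 0.5]), sigma_p=5.0)
        state = posterior_mixture(model, SideInfo(), [])
        mean, sd, _, _ = posterior_threshold_estimate(state, np.array([9.0]))
        assert mean[0] == pytest.approx(5.0)
        assert sd[0] == pytest.approx(np.sqrt(26.0))


class TestPosteriorLogLikelihood:
    def test_closed_form_at_posterior_mean(self, single_component_model):
        state = posterior_mixture(single_component_model, SideInfo(), [])
        xs = np.array([4.0, 10.0, 16.0])
        mus, sds, _, _ = posterior_threshold_estimate(state, xs)
        value = posterior_log_likelihood(state, xs, mus)
        expected = -np.sum(np.log(sds * np.sqrt(2 * np.pi)))
        assert value == pytest.approx(expected, rel=1e-10)

    def test_matches_direct_density(self, two_component_model):
        trials = make_trials([(5.0, 25.0, 1)])
        state = posterior_mixture(two_component_model, SideInfo(), trials)
        xs = np.array([4.0, 11.0])
        t = np.array([22.0, 48.0])
        value = posterior_log_likelihood(state, xs, t)
        direct = 0.0
        for i, x in enumerate(xs):
            dens = 0.0
            for pi_c, post in zip(state.pi, state.component_posteriors):
                mu, sd = post.predict(x)
                dens += pi_c * norm.pdf(t[i], mu[0], sd[0])
            direct += np.log(dens)
        assert value == pytest.approx(direct, abs=1e-10)

    def test_decreases_away_from_mean(self, single_component_model):
        state = posterior_mixture(single_component_model, SideInfo(), [])
        xs = np.array([4.0, 10.0, 16.0])
        mus, _, _, _ = posterior_threshold_estimate(state, xs)
        v0 = posterior_log_likelihood(state, xs, mus)
        v1 = posterior_log_likelihood(state, xs, mus + 5.0)
        v2 = posterior_log_likelihood(state, xs, mus + 15.0)
        assert v0 > v1 > v2
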