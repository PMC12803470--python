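import numpy as np
import pytest
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm

from conftest import brute_force_loglik, brute_force_viterbi
from swimhmm._hmm_core import LOG_FLOOR
from swimhmm.behavior import (
    emission_log_matrix,
    emission_logpdf,
    fit_angle_mixture,
    fit_behavior_hmm,
    mixture_logpdf,
    sample_states_and_angles,
    sequence_loglik,
    viterbi_decode,
    weighted_gamma_mle,
)
from swimhmm.config import FitConfig
from swimhmm.markov import stationary_distribution
from swimhmm.types import BehaviorHMM


def _random_model(rng, symmetric=False):
    P = rng.dirichlet(np.ones(3), size=3)
    pi = rng.dirichlet(np.ones(3))
    return BehaviorHMM(
        P, pi, sigma_f=rng.uniform(5, 25), alpha=rng.uniform(1.2, 4),
        theta=rng.uniform(5, 20), symmetric=False,
    )


class TestEmissions:
    def test_normal_mode_value(self, behavior_model):
        expect = np.log(1.0 / (behavior_model.sigma_f * np.sqrt(2 * np.pi)))
        assert emission_logpdf(0.0, "F", behavior_model) == pytest.approx(expect)

    def test_turn_density_matches_scipy(self, behavior_model):
        got = emission_logpdf(20.0, "L", behavior_model)
        expect = gamma_dist.logpdf(20.0, a=behavior_model.alpha, scale=behavior_model.theta)
        assert got == pytest.approx(expect, abs=1e-12)
        # right turn mirrors on negative angles
        assert emission_logpdf(-20.0, "R", behavior_model) == pytest.approx(expect, abs=1e-12)

    def test_out_of_support_floor(self, behavior_model):
        assert emission_logpdf(-5.0, "L", behavior_model) == LOG_FLOOR
        assert emission_logpdf(5.0, "R", behavior_model) == LOG_FLOOR

    def test_forward_covers_real_line(self, behavior_model):
        logB = emission_log_matrix(np.array([-500.0, 0.0, 500.0]), behavior_model)
        assert np.all(np.isfinite(logB[:, 0]))


class TestForwardAndViterbiOracles:
    @pytest.mark.parametrize("seed", range(5))
    def test_loglik_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        model = _random_model(rng)
        T = int(rng.integers(1, 9))
        angles = rng.normal(0, 20, T)
        logB = emission_log_matrix(angles, model)
        expect = brute_force_loglik(model.transition, model.initial, logB)
        assert sequence_loglik(angles, model) == pytest.approx(expect, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_viterbi_matches_exhaustive_maximum(self, seed):
        rng = np.random.default_rng(100 + seed)
        model = _random_model(rng)
        T = int(rng.integers(1, 9))
        angles = rng.normal(0, 20, T)
        logB = emission_log_matrix(angles, model)
        from swimhmm._hmm_core import viterbi

        path, score = viterbi(model.transition, model.initial, logB)
        best, _ = brute_force_viterbi(model.transition, model.initial, logB)
        assert score == pytest.approx(best, abs=1e-10)

    def test_large_positive_angles_decode_left(self, behavior_model):
        seq = viterbi_decode(np.full(20, 40.0), behavior_model)
        assert (seq.states == 1).all()

    def test_near_deterministic_recovery(self):
        P = np.full((3, 3), 0.0005)
        np.fill_diagonal(P, 0.999)
        model = BehaviorHMM(P, np.ones(3) / 3, 2.0, 3.0, 30.0, symmetric=False)
        states, angles = sample_states_and_angles(model, 2000, 5)
        decoded = viterbi_decode(angles, model)
        assert (decoded.states == states.states).mean() > 0.99


class TestGammaMLE:
    def test_recovers_shape_and_scale(self):
        rng = np.random.default_rng(0)
        x = rng.gamma(2.5, 8.0, 200_000)
        a, t = weighted_gamma_mle(x, np.ones_like(x))
        assert a == pytest.approx(2.5, rel=0.02)
        assert t == pytest.approx(8.0, rel=0.02)

    def test_alpha_clamped_above_one(self):
        rng = np.random.default_rng(1)
        x = rng.gamma(0.5, 8.0, 50_000)  # true shape below the constraint
        a, t = weighted_gamma_mle(x, np.ones_like(x))
        assert a == pytest.approx(1.0, abs=1e-5)


class TestTraining:
    def test_stopping_rule_and_monotone_trace(self, small_sessions):
        seqs = [b.dtheta for b, _ in small_sessions]
        cfg = FitConfig(max_iter=200, tol=1e-6, restarts=2, seed=0)
        model, trace = fit_behavior_hmm(seqs, cfg)
        assert np.all(np.diff(trace) >= -1e-8)
        if model.meta["converged"]:
            assert trace[-1] - trace[-2] < cfg.tol

    def test_symmetry_constraints_hold_after_fit(self, small_sessions):
        seqs = [b.dtheta for b, _ in small_sessions]
        model, _ = fit_behavior_hmm(seqs, FitConfig(max_iter=100, restarts=2, seed=1))
        P = model.transition
        assert P[0, 1] == pytest.approx(P[0, 2], abs=1e-12)
        assert P[1, 1] == pytest.approx(P[2, 2], abs=1e-12)
        assert P[1, 2] == pytest.approx(P[2, 1], abs=1e-12)
        assert P[1, 0] == pytest.approx(P[2, 0], abs=1e-12)
        # symmetric chain puts equal stationary mass on L and R
        pi = stationary_distribution(P)
        assert pi[1] == pytest.approx(pi[2], abs=1e-10)

    def test_unconstrained_fit_learns_symmetry(self, behavior_model):
        # data from a symmetric model: a free fit lands near symmetric rates
        from swimhmm.synthetic import GroundTruth, gen_behavior_sessions

        truth = GroundTruth(seed=21)
        sessions = gen_behavior_sessions(truth, 400, 60, seed=21)
        seqs = [b.dtheta for b, _ in sessions]
        model, _ = fit_behavior_hmm(
            seqs, FitConfig(max_iter=1000, restarts=3, seed=21), symmetric=False
        )
        P = model.transition
        assert abs(P[0, 1] - P[0, 2]) < 0.04
        assert abs(P[1, 1] - P[2, 2]) < 0.04
        assert abs(P[1, 0] - P[2, 0]) < 0.04

    def test_warns_on_tiny_dataset(self):
        rng = np.random.default_rng(2)
        with pytest.warns(UserWarning, match="pooled bouts"):
            fit_behavior_hmm(
                [rng.normal(0, 15, 30)], FitConfig(max_iter=5, restarts=1, seed=0)
            )


class TestSampling:
    def test_absorbing_forward_state(self):
        P = np.array([[1.0, 0.0, 0.0], [0.3, 0.4, 0.3], [0.3, 0.3, 0.4]])
        model = BehaviorHMM(P, np.array([1.0, 0, 0]), 15.0, 2.0, 10.0, symmetric=False)
        states, angles = sample_states_and_angles(model, 500, 0)
        assert (states.states == 0).all()
        assert np.isfinite(angles).all()
        # Normal(0, 15) sample moments
        assert abs(angles.mean()) < 3.0
        assert np.std(angles) == pytest.approx(15.0, rel=0.15)

    def test_sampled_transition_frequencies(self, behavior_model):
        states, _ = sample_states_and_angles(behavior_model, 100_000, 4)
        s = states.states
        C = np.zeros((3, 3))
        np.add.at(C, (s[:-1], s[1:]), 1.0)
        P_hat = C / C.sum(axis=1, keepdims=True)
        assert np.max(np.abs(P_hat - behavior_model.transition)) < 0.01

    def test_angle_histogram_matches_stationary_mixture(self, behavior_model):
        states, angles = sample_states_and_angles(behavior_model, 50_000, 9)
        pi = stationary_distribution(behavior_model.transition)
        from swimhmm.behavior import MixtureFit, mixture_cdf

        fit = MixtureFit(
            pi[0], pi[1], pi[2], behavior_model.sigma_f, behavior_model.alpha,
            behavior_model.theta, 0.0,
        )
        grid = np.linspace(-80, 80, 41)
        emp = np.searchsorted(np.sort(angles), grid) / angles.size
        assert np.max(np.abs(emp - mixture_cdf(grid, fit))) < 0.01


class TestAngleMixture:
    def test_self_consistency_qq_on_simulated_mixture(self, behavior_model):
        _, angles = sample_states_and_angles(behavior_model, 50_000, 11)
        fit, qq = fit_angle_mixture(angles)
        interior = (qq[:, 0] > np.quantile(qq[:, 0], 0.005)) & (
            qq[:, 0] < np.quantile(qq[:, 0], 0.995)
        )
        assert np.max(np.abs(qq[interior, 0] - qq[interior, 1])) < 2.0

    def test_pure_normal_data_still_fits_density(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 14, 30_000)
        fit, _ = fit_angle_mixture(x)
        grid = np.linspace(-50, 50, 101)
        dens = np.exp(mixture_logpdf(grid, fit))
        hist, edges = np.histogram(x, bins=grid, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        dens_c = np.exp(mixture_logpdf(centers, fit))
        assert np.max(np.abs(hist - dens_c)) < 0.004

    def test_beats_gaussian_mixture_in_heavy_tails(self, behavior_model):
        from sklearn.mixture import GaussianMixture

        _, angles = sample_states_and_angles(behavior_model, 30_000, 13)
        train, test = angles[:20_000], angles[20_000:]
        fit, _ = fit_angle_mixture(train)
        ll_mix = mixture_logpdf(test, fit).sum()
        gmm = GaussianMixture(3, random_state=0).fit(train[:, None])
        ll_gmm = gmm.score_samples(test[:, None]).sum()
        assert ll_mix > ll_gmm

    def test_requires_minimum_sample(self):
        with pytest.raises(ValueError):
            fit_angle_mixture(np.random.default_rng(0).normal(0, 10, 50))
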