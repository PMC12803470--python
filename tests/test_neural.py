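import numpy as np
import pytest

from conftest import brute_force_loglik, brute_force_viterbi
from swimhmm._hmm_core import viterbi
from swimhmm.config import FitConfig
from swimhmm.markov import stationary_distribution
from swimhmm.neural import (
    cross_validate_states,
    decode_raster,
    emission_log_matrix,
    fit_neural_hmm,
    label_neural_states,
    lateralized_excitability,
    model_two_point,
    neural_emission_loglik,
    raster_loglik,
    sample_raster,
    two_point_moments,
)
from swimhmm.synthetic import GroundTruth, gen_neural_session
from swimhmm.types import NeuralHMM, NeuralRaster


def _random_neural_model(rng, K=3, N=5):
    P = rng.dirichlet(np.ones(K), size=K)
    return NeuralHMM(P, rng.dirichlet(np.ones(K)), rng.normal(0, 2, (K, N)))


class TestEmission:
    def test_zero_fields_give_uniform_configuration_probability(self):
        model = NeuralHMM(np.ones((1, 1)), np.ones(1), np.zeros((1, 8)))
        config = np.array([1, 0, 1, 1, 0, 0, 1, 0])
        assert neural_emission_loglik(config, 0, model) == pytest.approx(-8 * np.log(2))

    def test_saturated_fields(self):
        N = 6
        model = NeuralHMM(np.ones((1, 1)), np.ones(1), np.full((1, N), 10.0))
        ll = neural_emission_loglik(np.ones(N), 0, model)
        assert ll == pytest.approx(-N * np.log1p(np.exp(-10.0)), abs=1e-12)

    def test_matches_naive_product(self):
        rng = np.random.default_rng(0)
        model = _random_neural_model(rng, K=3, N=7)
        config = (rng.random(7) < 0.5).astype(float)
        for s in range(3):
            p = 1 / (1 + np.exp(-model.fields[s]))
            naive = np.sum(np.where(config > 0, np.log(p), np.log(1 - p)))
            assert neural_emission_loglik(config, s, model) == pytest.approx(naive, abs=1e-12)

    def test_length_mismatch_raises(self):
        model = _random_neural_model(np.random.default_rng(1))
        with pytest.raises(ValueError):
            neural_emission_loglik(np.zeros(3), 0, model)


class TestOracles:
    @pytest.mark.parametrize("seed", range(5))
    def test_forward_and_viterbi_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        model = _random_neural_model(rng, K=3, N=4)
        T = int(rng.integers(1, 9))
        act = (rng.random((4, T)) < 0.5).astype(np.int8)
        logB = emission_log_matrix(act, model)
        raster = NeuralRaster(act, np.array(["left", "left", "right", "right"]), 2.0)
        assert raster_loglik(raster, model) == pytest.approx(
            brute_force_loglik(model.transition, model.initial, logB), abs=1e-10
        )
        _, score = viterbi(model.transition, model.initial, logB)
        best, _ = brute_force_viterbi(model.transition, model.initial, logB)
        assert score == pytest.approx(best, abs=1e-10)


class TestFitting:
    def test_recovery_from_known_model(self):
        truth = GroundTruth(seed=17)
        raster, states = gen_neural_session(truth, 60, 10_000, seed=17)
        model, trace = fit_neural_hmm(raster, K=3, config=FitConfig(restarts=3, seed=17))
        model = label_neural_states(model, raster.side)
        tm = truth.neural_params
        assert np.sqrt(np.mean((model.fields - tm.fields) ** 2)) < 0.1
        assert np.max(np.abs(model.transition - tm.transition)) < 0.02
        assert np.all(np.diff(trace) >= -1e-8)

    def test_single_state_reduces_to_global_logits(self):
        truth = GroundTruth(seed=3)
        raster, _ = gen_neural_session(truth, 10, 500, seed=3)
        model, _ = fit_neural_hmm(raster, K=1)
        p = raster.activity.mean(axis=1)
        expect = np.log(p / (1 - p))
        assert np.allclose(model.fields[0], expect, atol=1e-9)

    def test_too_few_frames_raises(self):
        truth = GroundTruth(seed=3)
        raster, _ = gen_neural_session(truth, 5, 40, seed=3)
        with pytest.raises(ValueError):
            fit_neural_hmm(raster, K=5)


class TestLabeling:
    def _lateralized(self):
        fields = np.array(
            [
                [2.0, 2.0, -2.0, -2.0],   # state A: left-active -> L
                [-2.0, -2.0, 2.0, 2.0],   # state B: right-active -> R
                [0.0, 0.0, 0.0, 0.0],     # state C: balanced -> F
            ]
        )
        P = np.full((3, 3), 0.1) + np.eye(3) * 0.7
        return NeuralHMM(P, np.ones(3) / 3, fields), np.array(
            ["left", "left", "right", "right"]
        )

    def test_construction_example(self):
        model, side = self._lateralized()
        labeled = label_neural_states(model, side)
        # state order after labeling: F, L, R
        dh = lateralized_excitability(labeled, side)
        assert dh[1] > dh[0] > dh[2]
        assert np.allclose(labeled.fields[1], model.fields[0])
        assert np.allclose(labeled.fields[0], model.fields[2])

    def test_permutation_preserves_likelihood(self):
        model, side = self._lateralized()
        rng = np.random.default_rng(5)
        act = (rng.random((4, 200)) < 0.4).astype(np.int8)
        raster = NeuralRaster(act, side, 2.0)
        labeled = label_neural_states(model, side)
        assert raster_loglik(raster, labeled) == pytest.approx(
            raster_loglik(raster, model), abs=1e-8
        )

    def test_recovers_generating_labels(self):
        truth = GroundTruth(seed=17)
        raster, states = gen_neural_session(truth, 40, 5_000, seed=8)
        model, _ = fit_neural_hmm(raster, K=3, config=FitConfig(restarts=3, seed=8))
        model = label_neural_states(model, raster.side)
        decoded = decode_raster(raster, model)
        assert (decoded.states == states.states).mean() > 0.95

    def test_tied_excitability_raises(self):
        P = np.full((3, 3), 1 / 3)
        model = NeuralHMM(P, np.ones(3) / 3, np.zeros((3, 4)))
        with pytest.raises(ValueError, match="degenerate"):
            label_neural_states(model, np.array(["left", "left", "right", "right"]))


class TestSampling:
    def test_zero_field_firing_rate(self):
        model = NeuralHMM(np.ones((1, 1)), np.ones(1), np.zeros((1, 10)))
        raster, _ = sample_raster(model, 10_000, 0)
        se = 3 * np.sqrt(0.25 / 10_000)
        assert np.all(np.abs(raster.activity.mean(axis=1) - 0.5) < se * 2)

    def test_mean_activity_matches_stationary_mixture(self, neural_model):
        raster, _ = sample_raster(neural_model, 20_000, 1)
        pi = stationary_distribution(neural_model.transition)
        from swimhmm.neural import logistic

        expect = pi @ logistic(neural_model.fields)
        assert np.max(np.abs(raster.activity.mean(axis=1) - expect)) < 0.02

    def test_contralateral_covariance_reproduced(self, neural_model):
        truth_raster, _ = sample_raster(neural_model, 30_000, 2)
        emp = two_point_moments(truth_raster.activity)
        mod = model_two_point(neural_model)
        left = truth_raster.side == "left"
        cross = np.ix_(left, ~left)
        assert np.corrcoef(emp[cross].ravel(), mod[cross].ravel())[0, 1] > 0.99

    def test_lateralized_activity_ordering(self, neural_model):
        raster, states = sample_raster(neural_model, 20_000, 3)
        left = raster.side == "left"
        mL = raster.activity[left].mean(axis=0)
        mR = raster.activity[~left].mean(axis=0)
        in_L = states.states == 1
        in_R = states.states == 2
        assert mL[in_L].mean() > mR[in_L].mean()
        assert mR[in_R].mean() > mL[in_R].mean()


class TestCrossValidation:
    def test_state_count_selection(self):
        truth = GroundTruth(seed=4)
        raster, _ = gen_neural_session(truth, 40, 4_000, seed=4)
        table = cross_validate_states(raster, [1, 2, 3, 4], config=FitConfig(restarts=2, seed=4))
        score = dict(zip(table.K, table.heldout_loglik_per_s))
        assert score[3] > score[2] > score[1]
        # near-flat beyond the true state count
        assert abs(score[4] - score[3]) < 0.2 * (score[3] - score[2])

    def test_two_point_correlation_against_empirical_oracle(self, neural_model):
        raster, _ = sample_raster(neural_model, 5_000, 5)
        emp = two_point_moments(raster.activity)
        act = raster.activity.astype(float)
        naive = np.array(
            [[np.mean(act[i] * act[j]) for j in range(act.shape[0])] for i in range(act.shape[0])]
        )
        assert np.allclose(emp, naive, atol=1e-12)

    def test_empty_k_list_raises(self, neural_model):
        raster, _ = sample_raster(neural_model, 200, 6)
        with pytest.raises(ValueError):
            cross_validate_states(raster, [])
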