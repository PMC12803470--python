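import numpy as np
import pytest

from swimhmm.markov import stationary_distribution
from swimhmm.synthetic import (
    DEFAULT_BEHAVIOR_TRANSITION,
    GroundTruth,
    default_behavior_model,
    default_neural_model,
)


@pytest.fixture(scope="session")
def behavior_model():
    """Default symmetric behavioral model (study conditions)."""
    return default_behavior_model()


@pytest.fixture(scope="session")
def neural_model():
    return default_neural_model(n_neurons=20, seed=0)


@pytest.fixture(scope="session")
def symmetric_matrix():
    return DEFAULT_BEHAVIOR_TRANSITION.copy()


@pytest.fixture(scope="session")
def symmetric_stationary(symmetric_matrix):
    return stationary_distribution(symmetric_matrix)


@pytest.fixture(scope="session")
def small_sessions():
    """Twenty 40-bout trajectories with ground truth, shared across tests."""
    from swimhmm.synthetic import gen_behavior_sessions

    truth = GroundTruth(seed=7)
    return gen_behavior_sessions(truth, 20, 40, seed=7)


def brute_force_loglik(A, pi, logB):
    """Exhaustive sum over all K^T hidden paths (oracle)."""
    import itertools

    from scipy.special import logsumexp

    T, K = logB.shape
    terms = []
    for path in itertools.product(range(K), repeat=T):
        lp = np.log(pi[path[0]]) + logB[0, path[0]]
        for t in range(1, T):
            lp += np.log(A[path[t - 1], path[t]]) + logB[t, path[t]]
        terms.append(lp)
    return logsumexp(terms)


def brute_force_viterbi(A, pi, logB):
    """Exhaustive max over all K^T hidden paths (oracle)."""
    import itertools

    T, K = logB.shape
    best, best_path = -np.inf, None
    for path in itertools.product(range(K), repeat=T):
        lp = np.log(pi[path[0]]) + logB[0, path[0]]
        for t in range(1, T):
            lp += np.log(A[path[t - 1], path[t]]) + logB[t, path[t]]
        if lp > best:
            best, best_path = lp, path
    return best, np.array(best_path)
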