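"""HMM over binarized neural rasters with independent Bernoulli emissions.

Each hidden state s carries one local field h_i^s per neuron; neuron i
fires in a frame with probability logistic(h_i^s), independently of
the other neurons given the state.  After training, the K=3 states are
assigned F/L/R labels by lateralized excitability: the state with the
largest left-minus-right mean logistic field is Left, the smallest is
Right, the middle one Forward.  No left-right symmetry is enforced on
the neural model.
"""

from __future__ import annotations

import warnings

import numpy as np

from ._hmm_core import forward_backward, forward_loglik, sample_chain, viterbi
from .config import FitConfig
from .markov import stationary_distribution
from .types import NeuralHMM, NeuralRaster, StateSequence

_P_CLIP = 1e-6


def _log1pexp(h: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, h)


def logistic(h: np.ndarray) -> np.ndarray:
    out = np.empty_like(h, dtype=float)
    pos = h >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-h[pos]))
    e = np.exp(h[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def emission_log_matrix(activity: np.ndarray, model: NeuralHMM) -> np.ndarray:
    """T x K log emission probabilities for a raster (neurons x frames)."""
    act = np.asarray(activity, dtype=float)
    # sum_i [h_i^s sigma_i - log(1 + e^{h_i^s})]
    const = _log1pexp(model.fields).sum(axis=1)  # (K,)
    return act.T @ model.fields.T - const[None, :]


def neural_emission_loglik(config: np.ndarray, state: int, model: NeuralHMM) -> float:
    """Log-probability of one binary configuration under one state."""
    config = np.asarray(config, dtype=float)
    if config.shape[0] != model.n_neurons:
        raise ValueError("configuration length must match neuron count")
    h = model.fields[state]
    return float(np.dot(h, config) - _log1pexp(h).sum())


def raster_loglik(raster: NeuralRaster, model: NeuralHMM) -> float:
    logB = emission_log_matrix(raster.activity, model)
    return float(forward_loglik(model.transition, model.initial, logB))


class _DegenerateFit(RuntimeError):
    pass


def _em_once(
    activity: np.ndarray, model: NeuralHMM, config: FitConfig
) -> tuple[NeuralHMM, list[float]]:
    act = np.asarray(activity, dtype=float)
    T = act.shape[1]
    trace: list[float] = []
    for _ in range(config.max_iter):
        logB = emission_log_matrix(act, model)
        ll, gamma, xi = forward_backward(model.transition, model.initial, logB)
        trace.append(ll)
        if len(trace) > 1 and trace[-1] - trace[-2] < config.tol:
            break
        occ = gamma.sum(axis=0)
        if np.any(occ < 1e-8 * T):
            raise _DegenerateFit("state starved of posterior mass")
        if model.n_states > 1:
            P = xi / xi.sum(axis=1, keepdims=True)
        else:
            P = np.ones((1, 1))
        initial = gamma[0] / gamma[0].sum()
        # closed-form field M-step: logit of posterior-weighted mean activity
        p = (act @ gamma) / occ[None, :]  # (N, K)
        p = np.clip(p, _P_CLIP, 1.0 - _P_CLIP)
        fields = np.log(p / (1.0 - p)).T  # (K, N)
        model = NeuralHMM(P, initial, fields)
    return model, trace


def fit_neural_hmm(
    raster: NeuralRaster, K: int = 3, config: FitConfig | None = None
) -> tuple[NeuralHMM, list[float]]:
    """Baum-Welch fit of the K-state Bernoulli-field HMM to a raster.

    Fields are initialized from each neuron's global firing logit with
    per-state perturbations; transitions from a Dirichlet draw.  The
    best of ``config.restarts`` runs (final log-likelihood) is kept.
    """
    config = config or FitConfig()
    if K < 1:
        raise ValueError("K must be at least 1")
    if raster.n_frames < 10 * K:
        raise ValueError("need at least 10 frames per state")
    act = raster.activity.astype(float)
    rng = np.random.default_rng(config.seed)
    base_p = np.clip(act.mean(axis=1), _P_CLIP, 1 - _P_CLIP)
    base_h = np.log(base_p / (1 - base_p))
    if K == 1:
        # degenerate EM: fields are the global firing logits
        model = NeuralHMM(np.ones((1, 1)), np.ones(1), base_h[None, :])
        logB = emission_log_matrix(act, model)
        ll = float(forward_loglik(model.transition, model.initial, logB))
        model.meta.update(iterations=1, final_loglik=ll, seed=config.seed)
        return model, [ll]
    best: tuple[NeuralHMM, list[float]] | None = None
    attempts = 0
    done = 0
    while done < config.restarts and attempts < 4 * config.restarts:
        attempts += 1
        # diagonal-favoring transitions: neural states persist across frames
        P0 = rng.dirichlet(np.ones(K), size=K) * 0.2 + 0.8 * np.eye(K)
        P0 /= P0.sum(axis=1, keepdims=True)
        pi0 = rng.dirichlet(np.ones(K))
        fields0 = base_h[None, :] + rng.normal(0, 1.0, size=(K, act.shape[0]))
        try:
            model, trace = _em_once(act, NeuralHMM(P0, pi0, fields0), config)
        except _DegenerateFit:
            continue
        done += 1
        if best is None or trace[-1] > best[1][-1]:
            best = (model, trace)
    if best is None:
        raise RuntimeError("all EM restarts degenerate")
    model, trace = best
    if len(trace) >= config.max_iter:
        warnings.warn("EM did not converge within max_iter", stacklevel=2)
        model.meta["converged"] = False
    else:
        model.meta["converged"] = True
    model.meta.update(iterations=len(trace), final_loglik=trace[-1], seed=config.seed)
    return model, trace


def lateralized_excitability(model: NeuralHMM, side: np.ndarray) -> np.ndarray:
    """Delta h_s: left-minus-right mean logistic field per state."""
    left = side == "left"
    right = side == "right"
    lf = logistic(model.fields)
    return lf[:, left].mean(axis=1) - lf[:, right].mean(axis=1)


def label_neural_states(model: NeuralHMM, side: np.ndarray) -> NeuralHMM:
    """Permute a K=3 model's states onto F/L/R labels.

    Ordering: Delta h_L > Delta h_F > Delta h_R.  The permuted model
    has state 0 = F, 1 = L, 2 = R; relabeling leaves the likelihood
    unchanged.
    """
    if model.n_states != 3:
        raise ValueError("state labeling requires K = 3")
    dh = lateralized_excitability(model, side)
    if np.min(np.abs(np.diff(np.sort(dh)))) < 1e-12:
        raise ValueError("degenerate fit: tied lateralized excitabilities")
    order = np.argsort(dh)  # ascending: R, F, L
    perm = np.array([order[1], order[2], order[0]])  # -> F, L, R
    out = NeuralHMM(
        model.transition[np.ix_(perm, perm)],
        model.initial[perm],
        model.fields[perm],
        state_labels=np.array([0, 1, 2]),
        meta=dict(model.meta),
    )
    out.meta["delta_h"] = dh[perm]
    return out


def decode_raster(raster: NeuralRaster, model: NeuralHMM) -> StateSequence:
    """Viterbi MAP state path with frame timestamps."""
    logB = emission_log_matrix(raster.activity, model)
    path, _ = viterbi(model.transition, model.initial, logB)
    return StateSequence(path, times=raster.frame_times)


def sample_raster(
    model: NeuralHMM,
    n_frames: int,
    seed: int | np.random.Generator,
    side: np.ndarray | None = None,
    frame_rate_hz: float = 1.0,
) -> tuple[NeuralRaster, StateSequence]:
    """Ancestral sampling: state chain, then independent Bernoulli spikes."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = sample_chain(model.transition, model.initial, n_frames, rng.random(n_frames))
    p = logistic(model.fields)[states]  # (T, N)
    act = (rng.random(p.shape) < p).astype(np.int8).T
    if side is None:
        half = model.n_neurons // 2
        side = np.array(["left"] * half + ["right"] * (model.n_neurons - half))
    raster = NeuralRaster(act, side, frame_rate_hz)
    return raster, StateSequence(states, times=raster.frame_times)


def two_point_moments(activity: np.ndarray) -> np.ndarray:
    """Empirical <sigma_i sigma_j> over frames (N x N)."""
    act = np.asarray(activity, dtype=float)
    return act @ act.T / act.shape[1]


def model_two_point(model: NeuralHMM) -> np.ndarray:
    """Model-generated <sigma_i sigma_j> under the stationary state law.

    Off-diagonal: sum_s pi_s p_i^s p_j^s (within-state independence);
    diagonal: sum_s pi_s p_i^s.
    """
    pi = stationary_distribution(model.transition) if model.n_states > 1 else np.ones(1)
    p = logistic(model.fields)  # (K, N)
    M = np.einsum("s,si,sj->ij", pi, p, p)
    np.fill_diagonal(M, pi @ p)
    return M


def cross_validate_states(
    raster: NeuralRaster,
    K_list: list[int],
    config: FitConfig | None = None,
    train_fraction: float = 0.8,
):
    """Held-out model selection over the number of hidden states.

    Contiguous-block split: the first ``train_fraction`` of frames
    train the model, the remainder is scored.  Returns a table with
    held-out log-likelihood per second and the correlation between
    model-generated and empirical two-point moments (off-diagonal).
    """
    import pandas as pd

    config = config or FitConfig()
    if not K_list:
        raise ValueError("K_list must be non-empty")
    T = raster.n_frames
    split = int(train_fraction * T)
    if split < 10 * max(K_list) or T - split < 10:
        raise ValueError("block too short for the requested split")
    train = NeuralRaster(raster.activity[:, :split], raster.side, raster.frame_rate_hz)
    test_act = raster.activity[:, split:]
    emp = two_point_moments(raster.activity)
    iu = np.triu_indices(raster.n_neurons, k=1)
    rows = []
    for K in K_list:
        model, _ = fit_neural_hmm(train, K=K, config=config)
        logB = emission_log_matrix(test_act, model)
        pi0 = (
            stationary_distribution(model.transition) if K > 1 else np.ones(1)
        )
        ll = float(forward_loglik(model.transition, pi0, logB))
        per_sec = ll / ((T - split) / raster.frame_rate_hz)
        mod = model_two_point(model)
        corr = float(np.corrcoef(emp[iu], mod[iu])[0, 1])
        rows.append({"K": K, "heldout_loglik_per_s": per_sec, "two_point_corr": corr})
    return pd.DataFrame(rows)
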