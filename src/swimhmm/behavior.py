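"""Symmetric 3-state behavioral HMM over reorientation angles.

The model: hidden states F/L/R with Markov transitions; emissions
N(0, sigma) for forward bouts and signed Gamma(alpha, theta) laws for
turns (positive angles are left turns).  Left-right symmetry ties the
transition entries pairwise and shares the turn-emission parameters.
Training is Baum-Welch with an exact E-step and a weighted
maximum-likelihood M-step (Newton solve of the digamma equation for
the Gamma shape, constrained to alpha > 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln, polygamma

from ._hmm_core import (
    LOG_FLOOR,
    forward_backward_pooled,
    forward_loglik,
    sample_chain,
    viterbi,
)
from .config import FitConfig
from .markov import threshold_label
from .types import BehaviorHMM, StateSequence

_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)
_ALPHA_MIN = 1.0 + 1e-6


def _normal_logpdf(x: np.ndarray, sigma: float) -> np.ndarray:
    return -_HALF_LOG_2PI - np.log(sigma) - 0.5 * (x / sigma) ** 2


def _gamma_logpdf(x: np.ndarray, alpha: float, theta: float) -> np.ndarray:
    """Gamma log-density on x > 0; LOG_FLOOR outside the support."""
    x = np.asarray(x, dtype=float)
    out = np.full(x.shape, LOG_FLOOR)
    pos = x > 0
    xp = x[pos]
    out[pos] = (alpha - 1) * np.log(xp) - xp / theta - alpha * np.log(theta) - gammaln(alpha)
    return out


def emission_log_matrix(angles: np.ndarray, model: BehaviorHMM) -> np.ndarray:
    """T x 3 log emission densities for a sequence of angles."""
    angles = np.asarray(angles, dtype=float)
    logB = np.empty((angles.size, 3))
    logB[:, 0] = _normal_logpdf(angles, model.sigma_f)
    logB[:, 1] = _gamma_logpdf(angles, model.alpha, model.theta)
    logB[:, 2] = _gamma_logpdf(-angles, model.alpha, model.theta)
    return logB


def emission_logpdf(angle: float, state: int | str, model: BehaviorHMM) -> float:
    """Log emission density of a single angle under one state."""
    if isinstance(state, str):
        state = {"F": 0, "L": 1, "R": 2}[state]
    return float(emission_log_matrix(np.atleast_1d(angle), model)[0, state])


def sequence_loglik(angles: np.ndarray, model: BehaviorHMM) -> float:
    """Total log-likelihood of one angle sequence (forward recursion)."""
    angles = np.asarray(angles, dtype=float)
    if angles.size < 1:
        raise ValueError("sequence must contain at least one bout")
    logB = emission_log_matrix(angles, model)
    return float(forward_loglik(model.transition, model.initial, logB))


def dataset_loglik(sequences: list[np.ndarray], model: BehaviorHMM) -> float:
    return float(sum(sequence_loglik(a, model) for a in sequences))


def viterbi_decode(angles: np.ndarray, model: BehaviorHMM) -> StateSequence:
    """Maximum a posteriori state path (ties broken F < L < R)."""
    angles = np.asarray(angles, dtype=float)
    if angles.size < 1:
        raise ValueError("sequence must contain at least one bout")
    logB = emission_log_matrix(angles, model)
    path, _ = viterbi(model.transition, model.initial, logB)
    return StateSequence(path)


def sample_states_and_angles(
    model: BehaviorHMM, n: int, seed: int | np.random.Generator
) -> tuple[StateSequence, np.ndarray]:
    """Ancestral sampling of n bouts: hidden states, then angles."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = sample_chain(model.transition, model.initial, n, rng.random(n))
    angles = np.empty(n)
    m = states == 0
    angles[m] = rng.normal(0.0, model.sigma_f, m.sum())
    m = states == 1
    angles[m] = rng.gamma(model.alpha, model.theta, m.sum())
    m = states == 2
    angles[m] = -rng.gamma(model.alpha, model.theta, m.sum())
    return StateSequence(states), angles


# ---------------------------------------------------------------------------
# Weighted Gamma maximum likelihood (M-step for the turn emissions)

def weighted_gamma_mle(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """MLE of Gamma(shape, scale) under weights w, constrained shape > 1.

    Solves log(alpha) - digamma(alpha) = log(wmean x) - wmean(log x) by
    Newton iteration from the Minka closed-form start; if the optimum
    has alpha <= 1, alpha is clamped to 1 + 1e-6 and the scale
    maximized given alpha (theta = wmean / alpha).
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    keep = (x > 0) & (w > 0)
    x, w = x[keep], w[keep]
    wsum = w.sum()
    if wsum <= 0 or x.size < 2:
        raise ValueError("insufficient positive weighted data for Gamma MLE")
    mean = float(np.dot(w, x) / wsum)
    mean_log = float(np.dot(w, np.log(x)) / wsum)
    s = np.log(mean) - mean_log
    if s <= 0:  # degenerate (all x equal); push to the constraint
        return _ALPHA_MIN, mean / _ALPHA_MIN
    alpha = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(50):
        g = np.log(alpha) - digamma(alpha) - s
        h = 1.0 / alpha - polygamma(1, alpha)
        step = g / h
        nxt = alpha - step
        if nxt <= 0:
            nxt = alpha / 2.0
        if abs(nxt - alpha) < 1e-12 * alpha:
            alpha = nxt
            break
        alpha = nxt
    if alpha <= 1.0:
        alpha = _ALPHA_MIN
    theta = mean / alpha
    return float(alpha), float(theta)


# ---------------------------------------------------------------------------
# Baum-Welch training

class _DegenerateFit(RuntimeError):
    """A hidden state starved of posterior mass; restart."""


def _symmetrize_counts(C: np.ndarray) -> np.ndarray:
    """Average the left-right tied entries of an expected-count matrix."""
    C = C.copy()
    C[0, 1] = C[0, 2] = 0.5 * (C[0, 1] + C[0, 2])
    ll_rr = 0.5 * (C[1, 1] + C[2, 2])
    lr_rl = 0.5 * (C[1, 2] + C[2, 1])
    lf_rf = 0.5 * (C[1, 0] + C[2, 0])
    C[1, 1] = C[2, 2] = ll_rr
    C[1, 2] = C[2, 1] = lr_rl
    C[1, 0] = C[2, 0] = lf_rf
    return C


def _init_model(
    sequences: list[np.ndarray], rng: np.random.Generator, symmetric: bool,
    perturb: bool,
) -> BehaviorHMM:
    """Random symmetric transitions; emissions moment-matched on
    threshold labels at 10 degrees, jittered across restarts."""
    pooled = np.concatenate(sequences)
    labels = threshold_label(pooled).states
    f_ang = pooled[labels == 0]
    t_ang = np.abs(pooled[labels != 0])
    sigma = float(np.sqrt(np.mean(f_ang**2))) if f_ang.size else 10.0
    if t_ang.size >= 2 and t_ang.var() > 0:
        alpha = max(float(t_ang.mean() ** 2 / t_ang.var()), _ALPHA_MIN)
        theta = float(t_ang.mean() / alpha)
    else:
        alpha, theta = 2.0, 10.0
    if perturb:
        sigma *= np.exp(rng.normal(0, 0.2))
        alpha = max(alpha * np.exp(rng.normal(0, 0.2)), _ALPHA_MIN)
        theta *= np.exp(rng.normal(0, 0.2))
    P = rng.dirichlet(np.ones(3), size=3)
    if symmetric:
        P = _symmetrize_counts(P)
        P /= P.sum(axis=1, keepdims=True)
    initial = rng.dirichlet(np.ones(3))
    if symmetric:
        initial[1] = initial[2] = 0.5 * (initial[1] + initial[2])
        initial /= initial.sum()
    return BehaviorHMM(P, initial, sigma, alpha, theta, symmetric=symmetric)


def _em_once(
    sequences: list[np.ndarray], model: BehaviorHMM, config: FitConfig,
) -> tuple[BehaviorHMM, list[float]]:
    trace: list[float] = []
    symmetric = model.symmetric
    pooled = np.concatenate(sequences)
    offsets = np.concatenate([[0], np.cumsum([len(a) for a in sequences])]).astype(np.int64)
    for _ in range(config.max_iter):
        logB = emission_log_matrix(pooled, model)
        total_ll, gamma, xi, gamma0 = forward_backward_pooled(
            model.transition, model.initial, logB, offsets
        )
        trace.append(total_ll)
        if len(trace) > 1 and trace[-1] - trace[-2] < config.tol:
            break
        occ = gamma.sum(axis=0)
        if np.any(occ < 1e-8 * len(pooled)):
            raise _DegenerateFit("a hidden state received no posterior mass")
        # transitions
        C = _symmetrize_counts(xi) if symmetric else xi
        P = C / C.sum(axis=1, keepdims=True)
        # initial distribution
        initial = gamma0 / gamma0.sum()
        if symmetric:
            initial[1] = initial[2] = 0.5 * (initial[1] + initial[2])
            initial /= initial.sum()
        # forward emission: weighted second moment about zero
        wf = gamma[:, 0]
        sigma = float(np.sqrt(np.dot(wf, pooled**2) / wf.sum()))
        # turn emissions: weighted Gamma MLE on |angle|
        w_turn = np.where(pooled > 0, gamma[:, 1], np.where(pooled < 0, gamma[:, 2], 0.0))
        alpha, theta = weighted_gamma_mle(np.abs(pooled), w_turn)
        model = BehaviorHMM(P, initial, sigma, alpha, theta, symmetric=symmetric)
    return model, trace


def fit_behavior_hmm(
    sequences: list[np.ndarray],
    config: FitConfig | None = None,
    symmetric: bool = True,
) -> tuple[BehaviorHMM, list[float]]:
    """Baum-Welch fit of the behavioral HMM to a list of angle sequences.

    Runs ``config.restarts`` random re-initializations and keeps the
    best final log-likelihood.  Returns the fitted model and the
    log-likelihood trace of the winning run (non-decreasing).
    """
    config = config or FitConfig()
    sequences = [np.asarray(a, dtype=float) for a in sequences]
    if any(a.size < 1 for a in sequences):
        raise ValueError("empty sequence supplied")
    n_pooled = sum(a.size for a in sequences)
    if n_pooled < 100:
        warnings.warn(f"only {n_pooled} pooled bouts: fit may be unreliable", stacklevel=2)
    rng = np.random.default_rng(config.seed)
    best: tuple[BehaviorHMM, list[float]] | None = None
    attempts = 0
    done = 0
    while done < config.restarts and attempts < 4 * config.restarts:
        attempts += 1
        model0 = _init_model(sequences, rng, symmetric, perturb=attempts > 1)
        try:
            model, trace = _em_once(sequences, model0, config)
        except _DegenerateFit:
            continue
        done += 1
        if best is None or trace[-1] > best[1][-1]:
            best = (model, trace)
    if best is None:
        raise RuntimeError("all EM restarts degenerate")
    model, trace = best
    if len(trace) >= config.max_iter:
        model.meta["converged"] = False
        warnings.warn("EM did not converge within max_iter", stacklevel=2)
    else:
        model.meta["converged"] = True
    model.meta.update(iterations=len(trace), final_loglik=trace[-1], seed=config.seed)
    return model, trace


# ---------------------------------------------------------------------------
# Static angle-mixture validation

@dataclass
class MixtureFit:
    """Static 3-component mixture: w_F N(0,sigma) + w_L Gamma(+x) + w_R Gamma(-x)."""

    w_f: float
    w_l: float
    w_r: float
    sigma_f: float
    alpha: float
    theta: float
    loglik: float
    n_restarts_used: int = 1
    meta: dict = field(default_factory=dict)

    @property
    def weights(self) -> np.ndarray:
        return np.array([self.w_f, self.w_l, self.w_r])


def mixture_logpdf(x: np.ndarray, fit: MixtureFit) -> np.ndarray:
    comp = np.stack(
        [
            np.log(max(fit.w_f, 1e-300)) + _normal_logpdf(x, fit.sigma_f),
            np.log(max(fit.w_l, 1e-300)) + _gamma_logpdf(x, fit.alpha, fit.theta),
            np.log(max(fit.w_r, 1e-300)) + _gamma_logpdf(-x, fit.alpha, fit.theta),
        ]
    )
    m = comp.max(axis=0)
    return m + np.log(np.exp(comp - m).sum(axis=0))


def mixture_cdf(x: np.ndarray, fit: MixtureFit) -> np.ndarray:
    from scipy.stats import gamma as gamma_dist, norm

    x = np.asarray(x, dtype=float)
    c = fit.w_f * norm.cdf(x, scale=fit.sigma_f)
    c = c + fit.w_l * np.where(x > 0, gamma_dist.cdf(x, a=fit.alpha, scale=fit.theta), 0.0)
    c = c + fit.w_r * np.where(
        x < 0, gamma_dist.sf(-x, a=fit.alpha, scale=fit.theta), 1.0
    )
    return c


def mixture_ppf(p: np.ndarray, fit: MixtureFit, span: tuple[float, float]) -> np.ndarray:
    """Numerical mixture quantiles by interpolating the CDF on a dense grid."""
    lo, hi = span
    pad = 0.25 * (hi - lo) + 1.0
    grid = np.linspace(lo - pad, hi + pad, 20001)
    cdf = mixture_cdf(grid, fit)
    cdf, idx = np.unique(cdf, return_index=True)
    return np.interp(p, cdf, grid[idx])


def fit_angle_mixture(
    angles: np.ndarray,
    config: FitConfig | None = None,
) -> tuple[MixtureFit, np.ndarray]:
    """Static (no-dynamics) EM fit of the angle mixture, plus QQ pairs.

    Returns the fit and an (n, 2) array of (empirical quantile, fitted
    mixture quantile) pairs at plotting positions (i - 0.5)/n.
    """
    config = config or FitConfig()
    x = np.asarray(angles, dtype=float)
    if x.size < 100:
        raise ValueError("need at least 100 pooled angles")
    labels = threshold_label(x).states
    w = np.array([max((labels == k).mean(), 1e-3) for k in range(3)])
    w /= w.sum()
    f_ang = x[labels == 0]
    t_ang = np.abs(x[labels != 0])
    sigma = float(np.sqrt(np.mean(f_ang**2))) if f_ang.size else float(np.std(x))
    if t_ang.size >= 2 and t_ang.var() > 0:
        alpha = max(float(t_ang.mean() ** 2 / t_ang.var()), _ALPHA_MIN)
        theta = float(t_ang.mean() / alpha)
    else:
        alpha, theta = 2.0, 10.0
    fit = MixtureFit(*w, sigma, alpha, theta, -np.inf)
    n_restarts = 0
    prev_ll = -np.inf
    for _ in range(config.max_iter):
        logp = np.stack(
            [
                np.log(fit.w_f) + _normal_logpdf(x, fit.sigma_f),
                np.log(max(fit.w_l, 1e-300)) + _gamma_logpdf(x, fit.alpha, fit.theta),
                np.log(max(fit.w_r, 1e-300)) + _gamma_logpdf(-x, fit.alpha, fit.theta),
            ]
        ).T
        m = logp.max(axis=1, keepdims=True)
        norm_ = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        ll = float(norm_.sum())
        resp = np.exp(logp - norm_[:, None])
        if ll - prev_ll < config.tol and np.isfinite(prev_ll):
            prev_ll = ll
            break
        prev_ll = ll
        w = resp.mean(axis=0)
        sigma = float(np.sqrt(np.dot(resp[:, 0], x**2) / resp[:, 0].sum()))
        w_turn = np.where(x > 0, resp[:, 1], np.where(x < 0, resp[:, 2], 0.0))
        try:
            alpha, theta = weighted_gamma_mle(np.abs(x), w_turn)
        except ValueError:
            n_restarts += 1
            break
        fit = MixtureFit(w[0], w[1], w[2], sigma, alpha, theta, ll)
    fit.loglik = prev_ll
    fit.n_restarts_used = 1 + n_restarts
    emp = np.sort(x)
    p = (np.arange(1, x.size + 1) - 0.5) / x.size
    qq = np.column_stack([emp, mixture_ppf(p, fit, (emp[0], emp[-1]))])
    return fit, qq
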