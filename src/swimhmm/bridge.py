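"""Temporal comparison of behavioral and neural state dynamics.

Sojourn times (duration of maximal state runs), the optimal temporal
scaling factor f_N/B matching neural to behavioral sojourn quantiles,
matrix-power rescaling of the neural transition matrix, and
switch-path statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import StateSequence, TransitionMatrix


@dataclass
class SojournSample:
    """Per-state lists of run durations (seconds).

    A run of states (s_1 ... s_k) at times (t_1 ... t_k) contributes
    duration t_k - t_1; length-1 runs contribute 0.
    """

    durations: dict[int, np.ndarray] = field(default_factory=dict)

    def pooled(self, drop_zero: bool = False) -> np.ndarray:
        if not self.durations:
            return np.empty(0)
        out = np.concatenate([np.asarray(v, dtype=float) for v in self.durations.values()])
        if drop_zero:
            out = out[out > 0]
        return out

    def n_sojourns(self) -> int:
        return sum(len(v) for v in self.durations.values())


def sojourn_times(seq: StateSequence, k_states: int = 3) -> SojournSample:
    """Durations of maximal runs in a time-stamped state sequence."""
    if seq.times is None:
        raise ValueError("timestamps required for sojourn times")
    s, t = seq.states, seq.times
    out: dict[int, list[float]] = {k: [] for k in range(k_states)}
    if len(s) == 0:
        return SojournSample({k: np.array(v) for k, v in out.items()})
    change = np.flatnonzero(np.diff(s) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change, [len(s) - 1]])
    for a, b in zip(starts, ends):
        out[int(s[a])].append(float(t[b] - t[a]))
    return SojournSample({k: np.array(v) for k, v in out.items()})


def merge_sojourns(samples: list[SojournSample]) -> SojournSample:
    keys = set()
    for s in samples:
        keys |= set(s.durations)
    merged = {
        k: np.concatenate([s.durations.get(k, np.empty(0)) for s in samples])
        for k in keys
    }
    return SojournSample(merged)


def quantile_grid(n_quantiles: int) -> np.ndarray:
    """Evenly spaced interior probabilities (plotting positions)."""
    return (np.arange(n_quantiles) + 0.5) / n_quantiles


@dataclass
class ScalingFit:
    f: float
    grid: np.ndarray
    rmse: np.ndarray

    @property
    def rmse_min(self) -> float:
        return float(np.min(self.rmse))


def fit_scaling_factor(
    behavior: SojournSample,
    neural: SojournSample,
    n_quantiles: int = 101,
    step: float = 0.001,
    drop_zero: bool = False,
) -> ScalingFit:
    """Optimal f in [0,1] minimizing RMSE(Q(dt_b), f * Q(dt_n)).

    Sojourns are pooled across the three states per modality; matched
    quantile vectors are taken on an evenly spaced interior
    probability grid (plotting positions (i - 1/2)/m, which avoid the
    sample extremes: the pooled sojourn maxima are heavy-tailed and
    would otherwise dominate the RMSE).  The RMSE-vs-f curve is
    evaluated on a grid of step ``step``; the reported argmin is the
    exact minimizer of the quadratic, clamped to [0, 1].
    """
    db = behavior.pooled(drop_zero=drop_zero)
    dn = neural.pooled(drop_zero=drop_zero)
    if len(db) < 20 or len(dn) < 20:
        raise ValueError("need at least 20 sojourns per modality")
    if np.all(db == 0) or np.all(dn == 0):
        raise ValueError("degenerate sojourn sample (all zero durations)")
    p = quantile_grid(n_quantiles)
    qb = np.quantile(db, p)
    qn = np.quantile(dn, p)
    grid = np.arange(0.0, 1.0 + step / 2, step)
    # RMSE(f)^2 = mean(qb^2) - 2 f mean(qb qn) + f^2 mean(qn^2)
    a = np.mean(qn**2)
    b = np.mean(qb * qn)
    c = np.mean(qb**2)
    rmse = np.sqrt(np.maximum(c - 2 * grid * b + grid**2 * a, 0.0))
    # the quadratic has its exact minimum at b/a; clamp to [0, 1]
    f_star = float(np.clip(b / a, 0.0, 1.0)) if a > 0 else 0.0
    return ScalingFit(f_star, grid, rmse)


def rescale_exponent(nu: float, f: float) -> int:
    """Nearest-integer exponent round(nu * f), halves away from zero."""
    x = nu * f
    return int(np.floor(x + 0.5))


def rescale_transitions(
    P: TransitionMatrix | np.ndarray, nu: float, f: float
) -> np.ndarray:
    """Matrix-power rescaling P* = P^round(nu*f) of a per-frame matrix."""
    M = P.matrix if isinstance(P, TransitionMatrix) else np.asarray(P, dtype=float)
    k = rescale_exponent(nu, f)
    if k < 1:
        raise ValueError(f"rescaling exponent round({nu}*{f}) = {k} < 1")
    return np.linalg.matrix_power(M, k)


def transition_rmse(
    P_behavior: np.ndarray | TransitionMatrix,
    P_neural_rescaled: np.ndarray | TransitionMatrix,
) -> float:
    """Root mean squared difference over all matrix entries.

    Accepts single matrices or equal-length lists (pooled RMSE over
    all entries of all pairs).
    """
    def as_arr(x):
        return x.matrix if isinstance(x, TransitionMatrix) else np.asarray(x, dtype=float)

    if isinstance(P_behavior, (list, tuple)):
        if len(P_behavior) != len(P_neural_rescaled):
            raise ValueError("matrix lists must have equal length")
        diffs = [as_arr(a) - as_arr(b) for a, b in zip(P_behavior, P_neural_rescaled)]
        d = np.concatenate([x.ravel() for x in diffs])
    else:
        A, B = as_arr(P_behavior), as_arr(P_neural_rescaled)
        if A.shape != B.shape:
            raise ValueError("matrices must have the same shape (aligned state labels)")
        d = (A - B).ravel()
    return float(np.sqrt(np.mean(d**2)))


def switch_path_ratio(P: TransitionMatrix | np.ndarray) -> float:
    """P(L->R) / P(L->F): direct switches vs switches through forward."""
    M = P.matrix if isinstance(P, TransitionMatrix) else np.asarray(P, dtype=float)
    if M[1, 0] <= 0:
        return float("nan")
    return float(M[1, 2] / M[1, 0])


def switch_path_ratios(models: list[np.ndarray | TransitionMatrix]) -> np.ndarray:
    """Distribution of the switch-path ratio across a list of matrices."""
    return np.array([switch_path_ratio(P) for P in models])
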