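"""Threshold-based bout labeling and Markov-chain estimation.

The baseline comparator: bouts are labeled F/L/R by thresholding the
reorientation angle at +-dtheta0, and a 3-state Markov chain is
estimated from the labeled sequences by transition counting.
"""

from __future__ import annotations

import numpy as np

from .types import StateSequence, TransitionMatrix

#: Conventional angular threshold (degrees) separating forward bouts
#: from turns.  Bouts with |dtheta| exactly equal to the threshold are
#: labeled F (the turn conditions are strict inequalities).
DEFAULT_THRESHOLD_DEG = 10.0


def threshold_label(
    angles: np.ndarray, threshold: float = DEFAULT_THRESHOLD_DEG,
    times: np.ndarray | None = None,
) -> StateSequence:
    """Label each bout by the sign and magnitude of its angle.

    dtheta > +threshold -> L, dtheta < -threshold -> R, otherwise F.
    Positive angles are left turns.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    angles = np.asarray(angles, dtype=float)
    states = np.zeros(angles.shape, dtype=np.int64)
    states[angles > threshold] = 1
    states[angles < -threshold] = 2
    return StateSequence(states, times=times)


def count_transitions(sequences: list[StateSequence], k: int = 3) -> np.ndarray:
    """Pooled transition counts; no counting across trajectory boundaries."""
    counts = np.zeros((k, k))
    for seq in sequences:
        s = seq.states
        if len(s) < 2:
            continue
        np.add.at(counts, (s[:-1], s[1:]), 1.0)
    return counts


def estimate_transitions(sequences: list[StateSequence]) -> TransitionMatrix:
    """Maximum-likelihood transition matrix from pooled counts.

    Raises if a state that appears as a transition source has no
    outgoing transitions recorded, or if a row-state never occurs at
    all (its row would be undefined).
    """
    counts = count_transitions(sequences)
    row = counts.sum(axis=1)
    if np.any(row == 0):
        missing = [("F", "L", "R")[i] for i in np.flatnonzero(row == 0)]
        raise ValueError(
            f"no outgoing transitions observed from state(s) {missing}; "
            "row(s) undefined (supply a prior or more data)"
        )
    P = counts / row[:, None]
    return TransitionMatrix(P, counts=counts)


def _is_irreducible(P: np.ndarray) -> bool:
    """Strong connectivity of the directed graph of positive entries."""
    k = P.shape[0]
    reach = (P > 0) | np.eye(k, dtype=bool)
    for _ in range(k):
        reach = reach | (reach @ reach)
    return bool(reach.all() and reach.T.all())


def stationary_distribution(P: TransitionMatrix | np.ndarray) -> np.ndarray:
    """Stationary probabilities pi with pi P = pi.

    Computed from the eigen-decomposition of P^T (the top right
    eigenvector of the transition matrix); falls back to power
    iteration if the eigen solve is ill-conditioned.  Raises for
    reducible matrices, where the stationary distribution is not
    unique.
    """
    M = P.matrix if isinstance(P, TransitionMatrix) else np.asarray(P, dtype=float)
    if not np.allclose(M.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("matrix is not row-stochastic")
    if not _is_irreducible(M):
        raise ValueError("transition matrix is reducible: stationary distribution not unique")
    w, v = np.linalg.eig(M.T)
    idx = int(np.argmin(np.abs(w - 1.0)))
    if abs(w[idx] - 1.0) > 1e-6:
        # ill-conditioned eigen solve; power iteration fallback
        pi = np.full(M.shape[0], 1.0 / M.shape[0])
        for _ in range(100_000):
            nxt = pi @ M
            if np.max(np.abs(nxt - pi)) < 1e-14:
                pi = nxt
                break
            pi = nxt
        return pi / pi.sum()
    pi = np.real(v[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def empirical_frequencies(sequences: list[StateSequence], k: int = 3) -> np.ndarray:
    """Fraction of bouts in each state, pooled over sequences."""
    counts = np.zeros(k)
    for seq in sequences:
        np.add.at(counts, seq.states, 1.0)
    total = counts.sum()
    if total == 0:
        raise ValueError("no bouts supplied")
    return counts / total
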