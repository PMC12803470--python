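"""Streak statistics, memory quantification, and the stubbornness factor.

A streak is a maximal run of identical consecutive states within one
trajectory; turning streaks are runs of same-direction turns (a
direction change breaks the run), pooled over L and R.  The
stubbornness factor f_q is the ratio of same- to opposite-direction
turn pairs separated by exactly q forward bouts; for a non-handed
(left-right symmetric) 3-state Markov chain f_q = 1 for every q >= 1.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .types import StateSequence, TransitionMatrix

TURN_GROUP = "turn"
FORWARD_GROUP = "forward"


def _runs(states: np.ndarray) -> list[tuple[int, int]]:
    """(state, length) of each maximal run."""
    if len(states) == 0:
        return []
    change = np.flatnonzero(np.diff(states) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [len(states)]])
    return [(int(states[s]), int(e - s)) for s, e in zip(starts, ends)]


@dataclass
class StreakHistogram:
    """Counts of maximal run lengths, grouped into forward and
    same-direction turning streaks."""

    forward: Counter
    turn: Counter

    def counts(self, group: str) -> Counter:
        return self.forward if group == FORWARD_GROUP else self.turn


def streak_histogram(
    sequences: list[StateSequence], include_truncated: bool = True
) -> StreakHistogram:
    """Histogram of maximal-run lengths pooled over trajectories.

    Runs touching a trajectory boundary are included by default; set
    ``include_truncated=False`` to drop them (sensitivity mode).
    """
    fwd: Counter = Counter()
    trn: Counter = Counter()
    for seq in sequences:
        runs = _runs(seq.states)
        for i, (s, length) in enumerate(runs):
            if not include_truncated and (i == 0 or i == len(runs) - 1):
                continue
            (fwd if s == 0 else trn)[length] += 1
    return StreakHistogram(fwd, trn)


def fit_streak_length(hist: StreakHistogram | Counter, group: str = TURN_GROUP,
                      min_count: int = 5) -> float:
    """Characteristic streak length ell_1 from an exponential fit.

    Least-squares slope of log-counts vs length over bins with at
    least ``min_count`` observations; ell_1 = -1/slope.
    """
    counts = hist.counts(group) if isinstance(hist, StreakHistogram) else hist
    items = sorted((l, c) for l, c in counts.items() if c >= min_count)
    if len(items) < 3:
        raise ValueError("need at least 3 occupied length bins with sufficient counts")
    ell = np.array([l for l, _ in items], dtype=float)
    logc = np.log([c for _, c in items])
    slope = np.polyfit(ell, logc, 1)[0]
    if slope >= 0:
        raise ValueError("streak histogram does not decay; exponential fit invalid")
    return float(-1.0 / slope)


def theoretical_lengths(
    P: TransitionMatrix | np.ndarray, pi: np.ndarray
) -> dict[str, dict[str, float]]:
    """Closed-form persistence lengths per state.

    ell_1(s) = -1/ln P(s->s) is the model streak length;
    ell_0(s) = -1/ln P(s) is the memoryless-null length; their ratio
    is the memory index (1 for a memoryless chain).
    """
    M = P.matrix if isinstance(P, TransitionMatrix) else np.asarray(P, dtype=float)
    pi = np.asarray(pi, dtype=float)
    out: dict[str, dict[str, float]] = {}
    for i, name in enumerate(("F", "L", "R")):
        p_self = M[i, i]
        p_stat = pi[i]
        if not (0 < p_self < 1):
            raise ValueError(f"self-transition of {name} must lie in (0,1)")
        if not (0 < p_stat < 1):
            raise ValueError(f"stationary probability of {name} must lie in (0,1)")
        l1 = -1.0 / np.log(p_self)
        l0 = -1.0 / np.log(p_stat)
        out[name] = {"ell1": l1, "ell0": l0, "ratio": l1 / l0}
    return out


@dataclass
class StubbornnessResult:
    """Empirical stubbornness at q intermediary forward bouts.

    f_q = N_same / N_diff over all (possibly overlapping) q-plets
    T1 -> F^q -> T2 with T1, T2 turns; delta_f_q is the binomial
    delta-method uncertainty.  f_q is NaN (``defined`` False) when
    N_diff = 0.
    """

    q: int
    n_same: int
    n_diff: int

    @property
    def defined(self) -> bool:
        return self.n_diff > 0 and self.n_same > 0

    @property
    def f_q(self) -> float:
        return self.n_same / self.n_diff if self.n_diff > 0 else float("nan")

    @property
    def delta_f_q(self) -> float:
        if not self.defined:
            return float("nan")
        n = self.n_same + self.n_diff
        ratio = self.n_same / self.n_diff + self.n_diff / self.n_same
        return self.f_q * np.sqrt(ratio / n)


def stubbornness_empirical(sequences: list[StateSequence], q: int) -> StubbornnessResult:
    """Count q-plets T1 -> F^q -> T2 pooled over trajectories.

    q = 0 means adjacent turns.  Overlapping occurrences all count (a
    turn may end one plet and start the next).
    """
    if q < 0:
        raise ValueError("q must be non-negative")
    n_same = n_diff = 0
    for seq in sequences:
        s = seq.states
        if len(s) < q + 2:
            continue
        t1 = s[: len(s) - q - 1]
        t2 = s[q + 1:]
        ok = (t1 != 0) & (t2 != 0)
        if q > 0:
            mid = np.ones(len(t1), dtype=bool)
            for j in range(1, q + 1):
                mid &= s[j: j + len(t1)] == 0
            ok &= mid
        n_same += int(np.sum(ok & (t1 == t2)))
        n_diff += int(np.sum(ok & (t1 != t2)))
    return StubbornnessResult(q, n_same, n_diff)


def stubbornness_theoretical(
    P: TransitionMatrix | np.ndarray, pi: np.ndarray, q: int
) -> float:
    """Stubbornness from the transition matrix.

    q = 0: (P(L->L)+P(R->R)) / (P(L->R)+P(R->L)).
    q >= 1: ratio of stay vs switch q-plet path probabilities, in which
    the P(F->F)^q factor cancels:
        [pi_L P(L->F) P(F->L) + pi_R P(R->F) P(F->R)] /
        [pi_L P(L->F) P(F->R) + pi_R P(R->F) P(F->L)].
    Returns NaN when the denominator vanishes.
    """
    M = P.matrix if isinstance(P, TransitionMatrix) else np.asarray(P, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if q < 0:
        raise ValueError("q must be non-negative")
    if q == 0:
        denom = M[1, 2] + M[2, 1]
        if denom <= 0:
            return float("nan")
        return float((M[1, 1] + M[2, 2]) / denom)
    same = pi[1] * M[1, 0] * M[0, 1] + pi[2] * M[2, 0] * M[0, 2]
    diff = pi[1] * M[1, 0] * M[0, 2] + pi[2] * M[2, 0] * M[0, 1]
    if diff <= 0:
        return float("nan")
    return float(same / diff)


def persistence_report(
    sequences: list[StateSequence],
    P: TransitionMatrix | np.ndarray,
    pi: np.ndarray,
    q_values: tuple[int, ...] = (0, 1, 2),
):
    """Tabular summary: per-state lengths plus f_q +- delta f_q per q."""
    import pandas as pd

    lengths = theoretical_lengths(P, pi)
    rows = []
    for name, d in lengths.items():
        rows.append({"kind": "lengths", "state": name, **d})
    for q in q_values:
        emp = stubbornness_empirical(sequences, q)
        rows.append(
            {
                "kind": "stubbornness",
                "q": q,
                "f_q": emp.f_q,
                "delta_f_q": emp.delta_f_q,
                "n_same": emp.n_same,
                "n_diff": emp.n_diff,
                "f_q_theory": stubbornness_theoretical(P, pi, q),
            }
        )
    return pd.DataFrame(rows)
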