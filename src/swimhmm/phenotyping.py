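"""Individual phenotyping from long single-fish sessions.

A session (many trajectories spanning ~2 h) is split into contiguous
time chunks; per-chunk HMMs quantify intra-individual variability, and
likelihood comparison between per-fish models identifies individuals:
fish i is identified by model j when its test data attains the maximum
relative likelihood under model j.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .behavior import dataset_loglik, fit_behavior_hmm
from .config import FitConfig
from .types import BehaviorHMM, BoutSequence


def split_chunks(
    session: list[BoutSequence],
    n_chunks: int = 10,
    session_start_times: np.ndarray | None = None,
) -> list[list[BoutSequence]]:
    """Split a session into contiguous equal-duration time windows.

    Each trajectory is assigned whole to the chunk containing its
    start time (trajectories are never split).  Empty chunks are
    dropped with a warning.  ``session_start_times`` gives each
    trajectory's absolute start time; without it trajectories are
    assumed back-to-back (start = cumulative duration so far).
    """
    if n_chunks < 1:
        raise ValueError("n_chunks must be at least 1")
    if not session:
        raise ValueError("empty session")
    if session_start_times is None:
        durations = [float(b.dt.sum()) if b.dt is not None else float(len(b)) for b in session]
        session_start_times = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    else:
        session_start_times = np.asarray(session_start_times, dtype=float)
    span = session_start_times.max() - session_start_times.min()
    if span <= 0:
        raise ValueError("session span must exceed the number of chunks")
    t0 = session_start_times.min()
    width = span / n_chunks * (1 + 1e-12)
    idx = np.minimum(((session_start_times - t0) / width).astype(int), n_chunks - 1)
    chunks = [[] for _ in range(n_chunks)]
    for traj, ci in zip(session, idx):
        chunks[ci].append(traj)
    kept = [c for c in chunks if c]
    if len(kept) < n_chunks:
        warnings.warn(f"{n_chunks - len(kept)} empty chunk(s) dropped", stacklevel=2)
    return kept


@dataclass
class ConfusionResult:
    """Relative log-likelihood matrix over (data fish i, model fish j).

    rel_loglik[i, j] = log L(data_i | model_j) - log L(data_i | model_i),
    so the diagonal is 0 (relative likelihood 1).  identified[j] is the
    fish whose data maximizes the relative likelihood under model j;
    n_correct counts identified[j] == j.  Ties leave the column flagged
    in ``tied`` and do not count as correct.
    """

    loglik: np.ndarray
    rel_loglik: np.ndarray
    identified: np.ndarray
    tied: np.ndarray

    @property
    def n_correct(self) -> int:
        ok = self.identified == np.arange(len(self.identified))
        return int(np.sum(ok & ~self.tied))


def likelihood_confusion(
    models: list[BehaviorHMM],
    test_sets: list[list[np.ndarray]],
) -> ConfusionResult:
    """Total test log-likelihood of each fish's data under each model."""
    if len(models) != len(test_sets):
        raise ValueError("models and test sets must share the fish index space")
    n = len(models)
    keep = [i for i in range(n) if test_sets[i]]
    if len(keep) < n:
        warnings.warn(f"{n - len(keep)} fish with empty test sets excluded", stacklevel=2)
    L = np.full((n, n), np.nan)
    for i in keep:
        for j in range(n):
            L[i, j] = dataset_loglik(test_sets[i], models[j])
    rel = L - np.diag(L)[:, None]
    identified = np.full(n, -1)
    tied = np.zeros(n, dtype=bool)
    for j in range(n):
        col = rel[keep, j]
        best = np.max(col)
        winners = [keep[m] for m in np.flatnonzero(np.isclose(col, best, atol=1e-9))]
        identified[j] = winners[0]
        tied[j] = len(winners) > 1
    return ConfusionResult(L, rel, identified, tied)


def identification_curve(
    sessions: list[list[np.ndarray]],
    fractions: list[float],
    n_trials: int = 100,
    seed: int = 0,
    config: FitConfig | None = None,
    symmetric: bool = True,
) -> dict[float, tuple[float, float]]:
    """Correct identifications vs test-data fraction (mean +- sd).

    Per trial: each fish's trajectories are randomly split 50/50 into
    train and test; a model is fitted per fish on its train half; for
    each fraction, a random subset of the test trajectories is scored
    and the number of correctly identified fish counted.
    """
    if not all(0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    config = config or FitConfig()
    rng = np.random.default_rng(seed)
    counts: dict[float, list[int]] = {f: [] for f in fractions}
    for _ in range(n_trials):
        models, tests = [], []
        for fish in sessions:
            perm = rng.permutation(len(fish))
            half = max(len(fish) // 2, 1)
            train = [fish[k] for k in perm[:half]]
            test = [fish[k] for k in perm[half:]] or [fish[k] for k in perm[:half]]
            trial_cfg = FitConfig(
                max_iter=config.max_iter, tol=config.tol,
                restarts=config.restarts,
                seed=int(rng.integers(2**31)),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model, _ = fit_behavior_hmm(train, trial_cfg, symmetric=symmetric)
            models.append(model)
            tests.append(test)
        for f in fractions:
            sub = []
            skip = False
            for test in tests:
                k = int(round(f * len(test)))
                if k == 0:
                    skip = True
                    break
                pick = rng.choice(len(test), size=k, replace=False)
                sub.append([test[m] for m in pick])
            if skip:
                warnings.warn(f"fraction {f} yields zero trajectories; skipped", stacklevel=2)
                continue
            res = likelihood_confusion(models, sub)
            counts[f].append(res.n_correct)
    return {
        f: (float(np.mean(v)), float(np.std(v))) if v else (float("nan"), float("nan"))
        for f, v in counts.items()
    }
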