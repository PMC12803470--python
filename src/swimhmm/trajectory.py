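"""Neural-state-driven trajectory synthesis and orientation diffusion.

State sequences on the neural clock (decoded or sampled) are turned
into planar swim trajectories: bout times are drawn from the
behavioral inter-bout-interval pool stretched onto the slower neural
clock (each interval divided by the scaling factor f_N/B), each bout
inherits the neural state active at its time, angles come from the
behavioral emission law of that state, and distances from the
empirical pool.  Trajectories are quantified by the Mean Square
Reorientation MSR(q) = <(theta_{n+q} - theta_n)^2> with the dataset
mean angle subtracted first (bias correction).
"""

from __future__ import annotations

import numpy as np

from .types import BehaviorHMM, StateSequence, Trajectory2D


def sample_bout_times(
    interval_pool: np.ndarray,
    f: float,
    duration: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Cumulative bout times on the neural clock.

    Behavioral intervals are drawn i.i.d. from the pool and divided by
    f (neural dynamics are slower by 1/f), then summed; bouts beyond
    ``duration`` are discarded.
    """
    pool = np.asarray(interval_pool, dtype=float)
    if pool.size == 0:
        raise ValueError("empty interval pool")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not (0 < f <= 1):
        raise ValueError("scaling factor must lie in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mean_dt = pool.mean() / f
    n_guess = max(int(duration / mean_dt * 1.5) + 20, 20)
    times = np.cumsum(rng.choice(pool, size=n_guess) / f)
    while times[-1] < duration:
        times = np.concatenate([times, times[-1] + np.cumsum(rng.choice(pool, size=n_guess) / f)])
    return times[times <= duration]


def assign_bout_states(neural_states: StateSequence, bout_times: np.ndarray) -> np.ndarray:
    """State of the nearest frame at or before each bout time."""
    if neural_states.times is None:
        raise ValueError("neural state sequence must carry frame times")
    bout_times = np.asarray(bout_times, dtype=float)
    ft = neural_states.times
    if bout_times.size and bout_times.min() < ft[0]:
        raise ValueError("bout time precedes first frame")
    idx = np.searchsorted(ft, bout_times, side="right") - 1
    return neural_states.states[idx]


def synthesize_trajectory(
    bout_states: np.ndarray,
    behavior_model: BehaviorHMM,
    distance_pool: np.ndarray,
    seed: int | np.random.Generator,
    bout_times: np.ndarray | None = None,
) -> Trajectory2D:
    """Sample angles/distances per bout and integrate the planar path.

    Angle of bout n is drawn from the behavioral emission of its state;
    distance i.i.d. from the pool (pools are not conditioned on state).
    Heading theta_n includes bout n's own reorientation before its
    displacement: x_k = sum_n d_n cos(theta_n).
    """
    states = np.asarray(bout_states, dtype=np.int64)
    pool = np.asarray(distance_pool, dtype=float)
    if pool.size == 0:
        raise ValueError("empty distance pool")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(states)
    dtheta = np.empty(n)
    m = states == 0
    dtheta[m] = rng.normal(0.0, behavior_model.sigma_f, m.sum())
    m = states == 1
    dtheta[m] = rng.gamma(behavior_model.alpha, behavior_model.theta, m.sum())
    m = states == 2
    dtheta[m] = -rng.gamma(behavior_model.alpha, behavior_model.theta, m.sum())
    d = rng.choice(pool, size=n)
    theta = np.cumsum(dtheta)
    rad = np.deg2rad(theta)
    x = np.cumsum(d * np.cos(rad))
    y = np.cumsum(d * np.sin(rad))
    if bout_times is None:
        bout_times = np.arange(1, n + 1, dtype=float)
    return Trajectory2D(states, np.asarray(bout_times, dtype=float), dtheta, d, theta, x, y)


def _angle_arrays(trajectories) -> list[np.ndarray]:
    out = []
    for tr in trajectories:
        a = tr.dtheta if isinstance(tr, Trajectory2D) else np.asarray(tr, dtype=float)
        out.append(np.asarray(a, dtype=float))
    return out


def _dataset_mean(angles: list[np.ndarray]) -> float:
    return float(np.concatenate(angles).mean())


def msr(trajectories, q_max: int) -> np.ndarray:
    """Mean Square Reorientation for q = 1..q_max (degrees^2).

    The dataset-mean angle is subtracted first; averages run over all
    valid start bouts within each trajectory, then over trajectories
    (never across trajectory boundaries).  Entries with no valid
    window at that q are NaN.
    """
    angles = _angle_arrays(trajectories)
    mu = _dataset_mean(angles)
    out = np.full(q_max, np.nan)
    for qi, q in enumerate(range(1, q_max + 1)):
        per_traj = []
        for a in angles:
            if len(a) < q:
                continue
            w = np.convolve(a - mu, np.ones(q), mode="valid")
            per_traj.append(np.mean(w**2))
        if per_traj:
            out[qi] = float(np.mean(per_traj))
    return out


def msr_decomposition(trajectories, q: int) -> tuple[float, float]:
    """Split MSR(q) into diffusive and correlation contributions.

    diffusive: window-averaged sum of squared (mean-subtracted) angles,
    i.e. q times the angle variance over the windows actually used;
    correlation: twice the summed lagged cross-products over the same
    windows.  Their sum equals msr(q) identically.
    """
    angles = _angle_arrays(trajectories)
    mu = _dataset_mean(angles)
    diff_t, corr_t = [], []
    for a in angles:
        if len(a) < q:
            continue
        c = a - mu
        sq = np.convolve(c**2, np.ones(q), mode="valid")
        cross = np.zeros(len(c) - q + 1)
        for lag in range(1, q):
            prod = c[:-lag] * c[lag:]
            cross += np.convolve(prod, np.ones(q - lag), mode="valid")[: len(cross)]
        diff_t.append(np.mean(sq))
        corr_t.append(np.mean(2.0 * cross))
    if not diff_t:
        raise ValueError(f"no trajectory long enough for q={q}")
    return float(np.mean(diff_t)), float(np.mean(corr_t))


def shuffle_control(trajectories, seed: int | np.random.Generator) -> list[np.ndarray]:
    """Permute angles uniformly within each trajectory (lengths kept)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [rng.permutation(a) for a in _angle_arrays(trajectories)]
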