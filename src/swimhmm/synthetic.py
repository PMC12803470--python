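"""Synthetic behavioral and neural datasets with known ground truth.

The generators emulate the statistical structure of free-swimming bout
sequences (trimodal angle distribution: central Normal plus two signed
Gammas, Markov hidden-state dynamics, exponential-like streaks) and of
binarized ARTR rasters (Bernoulli emissions with lateralized fields),
linked by a known neural-to-behavioral temporal scaling factor.  Every
downstream stage is testable against the returned ground truth.

Seeding: one root seed spawns independent substreams per trajectory /
session, so changing the number of trajectories does not perturb
earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy.linalg import fractional_matrix_power

from ._hmm_core import sample_chain
from .markov import stationary_distribution
from .neural import logistic
from .types import BehaviorHMM, BoutSequence, NeuralHMM, NeuralRaster, StateSequence

# Default behavioral transition matrix: persistent forward state,
# moderately persistent turns, rare direct L<->R switches (the
# switch-path ratio is well below 1), left-right symmetric.
DEFAULT_BEHAVIOR_TRANSITION = np.array(
    [
        [0.70, 0.15, 0.15],
        [0.45, 0.49, 0.06],
        [0.45, 0.06, 0.49],
    ]
)

#: Default emission parameters: forward angles ~ N(0, 15 deg); turn
#: magnitudes ~ Gamma(shape 2, scale 10 deg), mean 20 deg.
DEFAULT_SIGMA_F = 15.0
DEFAULT_ALPHA = 2.0
DEFAULT_THETA = 10.0

#: Per-side base fields (K x [left, right]): the forward state is a
#: balanced low-activity state; turn states are strongly lateralized.
DEFAULT_FIELD_BASE = np.array(
    [
        [-1.0, -1.0],  # F
        [2.0, -2.0],   # L
        [-2.0, 2.0],   # R
    ]
)

DEFAULT_SCALING = 0.44
DEFAULT_FRAME_RATE = 5.9

#: Interval / distance distribution defaults: positive, right-skewed.
DEFAULT_INTERVAL_DIST = {"name": "gamma", "mean": 1.0, "shape": 4.0}
DEFAULT_DISTANCE_DIST = {"name": "lognormal", "median": 1.0, "sigma_log": 0.5}


def sample_dist(dist: dict, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw from a named positive distribution."""
    name = dist["name"]
    if name == "gamma":
        shape = dist["shape"]
        scale = dist["mean"] / shape
        if shape <= 0 or dist["mean"] <= 0:
            raise ValueError("gamma interval distribution needs positive mean and shape")
        return rng.gamma(shape, scale, size)
    if name == "lognormal":
        if dist["median"] <= 0 or dist["sigma_log"] <= 0:
            raise ValueError("lognormal distribution needs positive median and sigma_log")
        return rng.lognormal(np.log(dist["median"]), dist["sigma_log"], size)
    if name == "constant":
        if dist["value"] <= 0:
            raise ValueError("constant distribution needs a positive value")
        return np.full(size, float(dist["value"]))
    raise ValueError(f"unknown distribution {name!r}")


def dist_mean(dist: dict) -> float:
    """Mean of a named distribution; validates its parameters."""
    name = dist["name"]
    if name == "gamma":
        if dist["mean"] <= 0 or dist["shape"] <= 0:
            raise ValueError("gamma distribution needs positive mean and shape")
        return float(dist["mean"])
    if name == "lognormal":
        if dist["median"] <= 0 or dist["sigma_log"] <= 0:
            raise ValueError("lognormal distribution needs positive median and sigma_log")
        return float(dist["median"] * np.exp(dist["sigma_log"] ** 2 / 2))
    if name == "constant":
        if dist["value"] <= 0:
            raise ValueError("constant distribution needs a positive value")
        return float(dist["value"])
    raise ValueError(f"unknown distribution {name!r}")


def make_lateralized_fields(
    n_neurons: int,
    left_fraction: float,
    rng: np.random.Generator,
    base: np.ndarray = DEFAULT_FIELD_BASE,
    jitter: float = 0.3,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-neuron fields from per-side base values plus Gaussian jitter.

    The first ceil(left_fraction * N) neurons are labeled left.
    Returns (fields K x N, side labels).
    """
    if not (0 < left_fraction < 1):
        raise ValueError("left_fraction must lie strictly between 0 and 1")
    n_left = int(np.ceil(left_fraction * n_neurons))
    side = np.array(["left"] * n_left + ["right"] * (n_neurons - n_left))
    K = base.shape[0]
    fields = np.empty((K, n_neurons))
    fields[:, :n_left] = base[:, [0]]
    fields[:, n_left:] = base[:, [1]]
    fields += rng.normal(0.0, jitter, size=fields.shape)
    return fields, side


def default_behavior_model() -> BehaviorHMM:
    pi = stationary_distribution(DEFAULT_BEHAVIOR_TRANSITION)
    return BehaviorHMM(
        DEFAULT_BEHAVIOR_TRANSITION.copy(), pi, DEFAULT_SIGMA_F, DEFAULT_ALPHA,
        DEFAULT_THETA, symmetric=True,
    )


def derive_neural_transition(
    P_behavior: np.ndarray, nu: float, f: float
) -> np.ndarray:
    """Per-frame neural transition matrix from the per-bout behavioral one.

    Inverse of the matrix-power temporal rescaling: P_n = P_b^(1/k)
    with k = round(nu * f).  The fractional matrix power can carry
    tiny negative entries; these are clipped and rows renormalized.
    """
    k = int(np.floor(nu * f + 0.5))
    if k < 1:
        raise ValueError(
            f"scaling/frame-rate combination yields exponent round({nu}*{f}) = {k}"
        )
    if k == 1:
        return np.asarray(P_behavior, dtype=float).copy()
    root = fractional_matrix_power(np.asarray(P_behavior, dtype=float), 1.0 / k)
    root = np.real(root)
    root = np.clip(root, 0.0, None)
    root /= root.sum(axis=1, keepdims=True)
    return root


def default_neural_model(
    nu: float = DEFAULT_FRAME_RATE,
    f: float = DEFAULT_SCALING,
    n_neurons: int = 60,
    left_fraction: float = 0.5,
    seed: int = 0,
) -> NeuralHMM:
    P_n = derive_neural_transition(DEFAULT_BEHAVIOR_TRANSITION, nu, f)
    rng = np.random.default_rng(seed)
    fields, _ = make_lateralized_fields(n_neurons, left_fraction, rng)
    pi = stationary_distribution(P_n)
    return NeuralHMM(P_n, pi, fields, state_labels=np.array([0, 1, 2]))


@dataclass
class GroundTruth:
    """All generating parameters of a linked synthetic experiment."""

    behavior_params: BehaviorHMM = dataclass_field(default_factory=default_behavior_model)
    neural_params: NeuralHMM = dataclass_field(default_factory=default_neural_model)
    scaling_factor: float = DEFAULT_SCALING
    frame_rate_hz: float = DEFAULT_FRAME_RATE
    interval_dist: dict = dataclass_field(default_factory=lambda: dict(DEFAULT_INTERVAL_DIST))
    distance_dist: dict = dataclass_field(default_factory=lambda: dict(DEFAULT_DISTANCE_DIST))
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.scaling_factor <= 1):
            raise ValueError("scaling_factor must lie in (0, 1]")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        dist_mean(self.interval_dist)  # validates parameters
        dist_mean(self.distance_dist)


def _resolve_length_law(length_law) -> callable:
    if isinstance(length_law, (int, np.integer)):
        n = int(length_law)
        if n < 2:
            raise ValueError("length_law must yield at least 2 bouts")
        return lambda rng: n
    if callable(length_law):
        return length_law
    raise ValueError("length_law must be an int or a callable(rng) -> int")


def gen_behavior_sessions(
    truth: GroundTruth,
    n_traj: int,
    length_law=60,
    seed: int | None = None,
) -> list[tuple[BoutSequence, StateSequence]]:
    """Sample bout trajectories with their true hidden states.

    States follow the behavioral transition matrix from its initial
    distribution; angles come from the active state's emission law;
    intervals and distances are i.i.d. from the configured
    distributions (independent of state).
    """
    if n_traj < 1:
        raise ValueError("n_traj must be at least 1")
    law = _resolve_length_law(length_law)
    model = truth.behavior_params
    root = np.random.SeedSequence(truth.seed if seed is None else seed)
    out = []
    for i, ss in enumerate(root.spawn(n_traj)):
        rng = np.random.default_rng(ss)
        n = int(law(rng))
        if n < 2:
            raise ValueError("length_law produced a trajectory shorter than 2 bouts")
        states = sample_chain(model.transition, model.initial, n, rng.random(n))
        angles = np.empty(n)
        m = states == 0
        angles[m] = rng.normal(0.0, model.sigma_f, m.sum())
        m = states == 1
        angles[m] = rng.gamma(model.alpha, model.theta, m.sum())
        m = states == 2
        angles[m] = -rng.gamma(model.alpha, model.theta, m.sum())
        dt = sample_dist(truth.interval_dist, n, rng)
        d = sample_dist(truth.distance_dist, n, rng)
        bouts = BoutSequence(angles, dt=dt, d=d, trajectory_id=i)
        out.append((bouts, StateSequence(states, times=bouts.times)))
    return out


def gen_neural_session(
    truth: GroundTruth,
    n_neurons: int,
    n_frames: int,
    left_fraction: float = 0.5,
    seed: int | None = None,
) -> tuple[NeuralRaster, StateSequence]:
    """Sample a binarized raster with its true frame-state sequence."""
    if n_neurons < 2 or n_frames < 2:
        raise ValueError("need at least 2 neurons and 2 frames")
    root = np.random.SeedSequence(truth.seed if seed is None else seed)
    rng_states, rng_fields, rng_spikes = (
        np.random.default_rng(s) for s in root.spawn(3)
    )
    model = truth.neural_params
    if n_neurons == model.n_neurons:
        fields = model.fields
        n_left = int(np.ceil(left_fraction * n_neurons))
        side = np.array(["left"] * n_left + ["right"] * (n_neurons - n_left))
    else:
        fields, side = make_lateralized_fields(n_neurons, left_fraction, rng_fields)
    states = sample_chain(model.transition, model.initial, n_frames, rng_states.random(n_frames))
    p = logistic(fields)[states]  # (T, N)
    act = (rng_spikes.random(p.shape) < p).astype(np.int8).T
    raster = NeuralRaster(act, side, truth.frame_rate_hz)
    return raster, StateSequence(states, times=raster.frame_times)


def _chain_run_lengths(
    P: np.ndarray, pi: np.ndarray, seq_len: int, n_seq: int, rng: np.random.Generator
) -> np.ndarray:
    """Maximal-run lengths over n_seq finite chains (truncation included)."""
    out = []
    for _ in range(n_seq):
        s = sample_chain(P, pi, seq_len, rng.random(seq_len))
        change = np.flatnonzero(np.diff(s) != 0)
        starts = np.concatenate([[0], change + 1])
        ends = np.concatenate([change + 1, [seq_len]])
        out.append(ends - starts)
    return np.concatenate(out)


def linked_interval_mean(
    P_behavior: np.ndarray,
    nu: float,
    f: float,
    bouts_per_traj: int,
    n_traj: int,
    n_frames: int,
    n_neural_sessions: int,
    interval_shape: float = 4.0,
    n_quantiles: int = 101,
    n_replicates: int = 100,
) -> float:
    """Mean inter-bout interval making the sojourn-time scaling hold.

    The neural chain (per-frame matrix P_b^(1/k), k = round(nu f))
    dwells in each state for a geometric number of frames; a run of m
    frames spans (m-1)/nu seconds, while a behavioral run of m bouts
    spans the sum of m-1 Gamma-distributed intervals.  Because the two
    run-duration families differ in shape, no interval scale makes the
    distributions match exactly; the scale is instead calibrated so
    that the quantile-matching functional defining the temporal
    scaling factor (argmin_f RMSE(Q_b, f Q_n)) has expectation f under
    the study conditions.  The expectation is evaluated by simulating
    finite state chains of the actual lengths with a fixed internal
    stream (sojourn quantiles depend on sample size and on run
    truncation at sequence boundaries, so matched simulation is
    essential).  Behavioral sojourn quantiles scale linearly in the
    interval mean, so the calibration is a one-shot ratio.
    """
    from .bridge import quantile_grid

    P_b = np.asarray(P_behavior, dtype=float)
    P_n = derive_neural_transition(P_b, nu, f)
    pi_b = stationary_distribution(P_b)
    pi_n = stationary_distribution(P_n)
    rng = np.random.default_rng(20_240_101)  # internal calibration stream
    p = quantile_grid(n_quantiles)
    ratios = np.empty(n_replicates)
    for r in range(n_replicates):
        m_b = _chain_run_lengths(P_b, pi_b, bouts_per_traj, n_traj, rng)
        m_n = _chain_run_lengths(P_n, pi_n, n_frames, n_neural_sessions, rng)
        # behavioral durations at unit interval mean: Gamma(shape*(m-1), 1/shape)
        dur_b = np.zeros(len(m_b))
        multi = m_b > 1
        dur_b[multi] = rng.gamma(interval_shape * (m_b[multi] - 1), 1.0 / interval_shape)
        dur_n = (m_n - 1) / nu
        qb = np.quantile(dur_b, p)
        qn = np.quantile(dur_n, p)
        ratios[r] = np.sum(qb * qn) / np.sum(qn**2)
    # E[f_hat] = dt_mean * mean(ratios) = f  =>  dt_mean = f / mean(ratios)
    return f / float(np.mean(ratios))


@dataclass
class LinkedDataset:
    """A behavioral session and several neural recordings from one truth."""

    truth: GroundTruth
    behavior: list[tuple[BoutSequence, StateSequence]]
    rasters: list[NeuralRaster]
    neural_states: list[StateSequence]
    neural_transition: np.ndarray


def gen_linked_dataset(
    truth: GroundTruth,
    seed: int | None = None,
    n_traj: int = 1148,
    bouts_per_traj: int = 60,
    neural_duration_s: float = 23 * 60.0,
    n_neural_sessions: int = 6,
    n_neurons: int = 60,
    left_fraction: float = 0.5,
) -> LinkedDataset:
    """Generate linked behavioral and neural sessions.

    The neural transition matrix is the matrix root of the behavioral
    one (inverse temporal rescaling), and the inter-bout-interval scale
    is calibrated so that neural state dwell times are, in
    distribution, behavioral dwell times divided by the scaling
    factor.  Several neural recordings are generated (sojourn
    statistics are pooled across recordings downstream, as is done
    with multi-recording datasets).
    """
    seed = truth.seed if seed is None else seed
    model_b = truth.behavior_params
    nu, f = truth.frame_rate_hz, truth.scaling_factor
    P_n = derive_neural_transition(model_b.transition, nu, f)
    n_frames = int(neural_duration_s * nu)
    dt_mean = linked_interval_mean(
        model_b.transition, nu, f, bouts_per_traj, n_traj, n_frames, n_neural_sessions
    )
    interval = dict(truth.interval_dist)
    if interval["name"] == "gamma":
        interval["mean"] = dt_mean
    elif interval["name"] == "constant":
        interval["value"] = dt_mean
    else:  # rescale by the mean for any other family
        scale = dt_mean / dist_mean(interval)
        if interval["name"] == "lognormal":
            interval["median"] *= scale
    linked_truth = GroundTruth(
        behavior_params=model_b,
        neural_params=NeuralHMM(
            P_n,
            stationary_distribution(P_n),
            truth.neural_params.fields,
            state_labels=np.array([0, 1, 2]),
        ),
        scaling_factor=f,
        frame_rate_hz=nu,
        interval_dist=interval,
        distance_dist=truth.distance_dist,
        seed=seed,
    )
    # independent integer sub-seeds for each modality / recording
    sub = np.random.SeedSequence(seed).generate_state(1 + n_neural_sessions) % (2**31)
    behavior = gen_behavior_sessions(linked_truth, n_traj, bouts_per_traj, seed=int(sub[0]))
    rasters, states_list = [], []
    for j in range(n_neural_sessions):
        raster, neural_states = gen_neural_session(
            linked_truth, n_neurons, n_frames, left_fraction, seed=int(sub[1 + j])
        )
        rasters.append(raster)
        states_list.append(neural_states)
    return LinkedDataset(linked_truth, behavior, rasters, states_list, P_n)
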