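"""Core data containers shared across the package.

States are encoded as small integers throughout: 0 = F (forward),
1 = L (left turn), 2 = R (right turn).  Positive reorientation angles
are left turns.  Angles are degrees, times seconds, distances mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

STATE_F, STATE_L, STATE_R = 0, 1, 2
STATE_NAMES = ("F", "L", "R")
STATE_INDEX = {"F": 0, "L": 1, "R": 2}

_ROW_SUM_TOL = 1e-12


def states_to_names(states: np.ndarray) -> list[str]:
    return [STATE_NAMES[s] for s in np.asarray(states, dtype=int)]


def names_to_states(names: Sequence[str]) -> np.ndarray:
    return np.array([STATE_INDEX[n] for n in names], dtype=np.int64)


@dataclass
class StateSequence:
    """Ordered hidden-state labels, optionally time-stamped.

    ``states`` holds integer codes (0=F, 1=L, 2=R); ``times`` (seconds),
    if present, must be strictly increasing and of matching length.
    """

    states: np.ndarray
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != self.states.shape:
                raise ValueError("times and states must have the same length")
            if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
                raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def names(self) -> list[str]:
        return states_to_names(self.states)


@dataclass
class BoutSequence:
    """One trajectory's ordered bout kinematics.

    dtheta: reorientation angles (degrees, positive = left turn)
    dt: inter-bout intervals (seconds); dt[n] = t[n+1] - t[n] is stored
        aligned so that times = cumulative sum starting at 0.
    d: per-bout travel distances (mm).
    """

    dtheta: np.ndarray
    dt: np.ndarray | None = None
    d: np.ndarray | None = None
    trajectory_id: int | str = 0

    def __post_init__(self) -> None:
        self.dtheta = np.asarray(self.dtheta, dtype=float)
        if self.dt is not None:
            self.dt = np.asarray(self.dt, dtype=float)
            if self.dt.shape != self.dtheta.shape:
                raise ValueError("dt must match dtheta length")
        if self.d is not None:
            self.d = np.asarray(self.d, dtype=float)
            if self.d.shape != self.dtheta.shape:
                raise ValueError("d must match dtheta length")

    def __len__(self) -> int:
        return len(self.dtheta)

    @property
    def times(self) -> np.ndarray:
        """Bout times: t_0 = 0, t_n = sum of preceding intervals."""
        if self.dt is None:
            raise ValueError("no inter-bout intervals on this sequence")
        t = np.concatenate([[0.0], np.cumsum(self.dt[:-1])])
        return t


def validate_stochastic(P: np.ndarray, k: int | None = None) -> np.ndarray:
    """Validate and return a row-stochastic matrix as float64."""
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("transition matrix must be square")
    if k is not None and P.shape[0] != k:
        raise ValueError(f"expected a {k}x{k} transition matrix")
    if np.any(P < -_ROW_SUM_TOL) or np.any(P > 1 + 1e-9):
        raise ValueError("transition probabilities must lie in [0, 1]")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition-matrix rows must sum to 1")
    return P


@dataclass
class TransitionMatrix:
    """Row-stochastic matrix over {F, L, R} with optional raw counts."""

    P: np.ndarray
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.P = validate_stochastic(self.P, 3)
        if self.counts is not None:
            self.counts = np.asarray(self.counts, dtype=float)

    def __getitem__(self, idx) -> float:
        return self.P[idx]

    @property
    def matrix(self) -> np.ndarray:
        return self.P


@dataclass
class BehaviorHMM:
    """Symmetric 3-state behavioral HMM.

    Emissions: F ~ Normal(0, sigma_f); L ~ Gamma(alpha, theta) on +angle;
    R ~ Gamma(alpha, theta) on -angle.  The symmetry flag ties
    P(F->L)=P(F->R), P(L->L)=P(R->R), P(L->R)=P(R->L), P(L->F)=P(R->F)
    and shares (alpha, theta) between the turn states.
    """

    transition: np.ndarray
    initial: np.ndarray
    sigma_f: float
    alpha: float
    theta: float
    symmetric: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.transition = validate_stochastic(self.transition, 3)
        self.initial = np.asarray(self.initial, dtype=float)
        if self.initial.shape != (3,) or not np.isclose(self.initial.sum(), 1.0):
            raise ValueError("initial distribution must be a probability triple")
        if self.sigma_f <= 0:
            raise ValueError("sigma_f must be positive")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.alpha <= 1:
            raise ValueError("alpha must exceed 1")
        if self.symmetric:
            P = self.transition
            pairs = [((0, 1), (0, 2)), ((1, 1), (2, 2)), ((1, 2), (2, 1)), ((1, 0), (2, 0))]
            for a, b in pairs:
                if not np.isclose(P[a], P[b], atol=1e-8):
                    raise ValueError("transition matrix violates left-right symmetry")


@dataclass
class NeuralRaster:
    """Binarized spike raster: activity (neurons x frames) in {0,1}.

    ``side`` labels each neuron 'left' or 'right'; ``frame_rate_hz`` is
    the acquisition rate nu.
    """

    activity: np.ndarray
    side: np.ndarray
    frame_rate_hz: float

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity)
        if not np.isin(self.activity, (0, 1)).all():
            raise ValueError("raster entries must be 0/1")
        self.activity = self.activity.astype(np.int8)
        self.side = np.asarray(self.side)
        if self.side.shape[0] != self.activity.shape[0]:
            raise ValueError("one side label per neuron required")
        if not set(np.unique(self.side)) <= {"left", "right"}:
            raise ValueError("side labels must be 'left' or 'right'")
        for lab in ("left", "right"):
            if not np.any(self.side == lab):
                raise ValueError(f"at least one {lab} neuron required")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def n_neurons(self) -> int:
        return self.activity.shape[0]

    @property
    def n_frames(self) -> int:
        return self.activity.shape[1]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz


@dataclass
class NeuralHMM:
    """K-state HMM with independent per-neuron Bernoulli emissions.

    ``fields`` is the K x N matrix of local fields h_i^s: neuron i fires
    in state s with probability logistic(h_i^s).  ``state_labels`` maps
    model state index -> behavioral label index (0=F,1=L,2=R) once the
    lateralized-excitability labeling has been applied.
    """

    transition: np.ndarray
    initial: np.ndarray
    fields: np.ndarray
    state_labels: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.transition = validate_stochastic(self.transition)
        K = self.transition.shape[0]
        if K < 1:
            raise ValueError("need at least one state")
        self.initial = np.asarray(self.initial, dtype=float)
        if self.initial.shape != (K,) or not np.isclose(self.initial.sum(), 1.0):
            raise ValueError("initial distribution must be a length-K probability vector")
        self.fields = np.asarray(self.fields, dtype=float)
        if self.fields.ndim != 2 or self.fields.shape[0] != K:
            raise ValueError("fields must be K x N")
        if not np.all(np.isfinite(self.fields)):
            raise ValueError("fields must be finite")
        if self.state_labels is not None:
            self.state_labels = np.asarray(self.state_labels, dtype=np.int64)

    @property
    def n_states(self) -> int:
        return self.transition.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.fields.shape[1]


@dataclass
class Trajectory2D:
    """Reconstructed planar swim path with per-bout metadata.

    Heading theta_n is the cumulative sum of reorientation angles
    including bout n; the displacement of bout n uses theta_n.
    """

    states: np.ndarray
    t: np.ndarray
    dtheta: np.ndarray
    d: np.ndarray
    theta: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __len__(self) -> int:
        return len(self.dtheta)
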