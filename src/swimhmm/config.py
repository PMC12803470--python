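"""Run configuration shared across fitting and pipeline stages."""

from __future__ import annotations

import dataclasses
import json
import hashlib
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class FitConfig:
    """Expectation-maximization training settings.

    max_iter / tol follow the study convention: at most 500 EM
    iterations, stopping once the total log-likelihood gain in one
    iteration drops below 1e-6.  ``restarts`` random re-initializations
    are run and the best final log-likelihood kept.
    """

    max_iter: int = 500
    tol: float = 1e-6
    restarts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")
        if self.restarts < 1:
            raise ValueError("restarts must be at least 1")


@dataclass
class RunConfig:
    """Top-level pipeline configuration.

    threshold_deg: angular threshold for the Markov-chain baseline.
    quantile_grid: number of evenly spaced probabilities used in the
        sojourn-quantile comparison.
    scaling_step: grid step for the temporal scaling-factor search.
    n_chunks: chunks per session in phenotyping.
    """

    seed: int = 0
    threshold_deg: float = 10.0
    fit: FitConfig = dataclasses.field(default_factory=FitConfig)
    symmetric: bool = True
    quantile_grid: int = 101
    scaling_step: float = 0.001
    n_chunks: int = 10

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) if path.suffix in (".yaml", ".yml") else json.load(fh)
        fit = FitConfig(**raw.pop("fit", {}))
        return cls(fit=fit, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def hash(self) -> str:
        """Stable short hash of the configuration, embedded in artifacts."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
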