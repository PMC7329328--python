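"""Run configuration and seeding for the pipeline.

All defaults match the analysis protocol: read-depth and detection
filters are strict inequalities at 5,000 reads and 5 samples, a
pseudocount of 1 precedes normalisation, Gompertz fits use 100 random
restarts, permutation tests use 10,000 shuffles, and the kinetics-mode
growth threshold is 1.48 ln-units.  The endpoint-mode threshold has no
default — it must be calibrated against reference data.

Randomness flows from a single top-level seed: each pipeline stage draws
its generator from a named substream so stages are individually
reproducible regardless of execution order.
"""

from __future__ import annotations

import dataclasses
import zlib
from pathlib import Path

import numpy as np
import yaml

__all__ = ["RunConfig", "substream_seed", "substream_rng"]


def substream_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed derived from the top-level seed."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def substream_rng(seed: int, stage: str) -> np.random.Generator:
    """Generator for a named pipeline stage."""
    return np.random.default_rng(substream_seed(seed, stage))


@dataclasses.dataclass
class RunConfig:
    """Pipeline configuration with protocol defaults."""

    seed: int
    pseudocount: float = 1.0
    min_reads: int = 5000
    min_samples: int = 5
    n_restarts: int = 100
    n_perm: int = 10_000
    kinetics_threshold: float = 1.48
    endpoint_threshold: float | None = None
    no_carbon: str = "none"
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for any stochastic step")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.min_reads < 0 or self.min_samples < 0:
            raise ValueError("filter thresholds must be >= 0")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config file; keyword overrides (e.g. CLI flags) win."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
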