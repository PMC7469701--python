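"""Structured run configuration with YAML round-trip and a content hash.

Every source of randomness in a run flows from the single mandatory ``seed``;
per-stage generators derive from it deterministically, so identical configs
produce bitwise-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError


@dataclass
class RunConfig:
    seed: int
    transcriptome: dict = field(
        default_factory=lambda: {
            "n_genes": 60,
            "length_range": [400, 1500],
            "gc_target": 0.5,
            "target_length": 720,
            "target_weight": 0.12,
        }
    )
    crrna: dict = field(default_factory=lambda: {"protospacer_start": 300})
    cleavage: dict = field(
        default_factory=lambda: {
            "cut_prob": 0.9,
            "cut_offsets": [0],
            "stagger": 6,
            "five_prime_survival": 0.05,
            "degradation_to_completion_prob": 0.9,
        }
    )
    design: dict = field(
        default_factory=lambda: {
            "n_batches": 3,
            "timepoints": ["128cell", "5hpf"],
            "conditions": ["injected", "mock"],
        }
    )
    batch_factors: dict = field(default_factory=lambda: {"b1": 1.0, "b2": 1.8, "b3": 0.6})
    depth: int = 30_000
    fraglen: list = field(default_factory=lambda: [180, 320])
    dispersion: float = 0.05
    contamination: dict = field(default_factory=lambda: {"128cell": 0.003, "5hpf": 0.0012})
    complementarity_spectrum: dict = field(default_factory=lambda: {22: 2, 18: 5})
    analysis: dict = field(
        default_factory=lambda: {
            "epsilon": 1e-6,
            "min_z": 4.0,
            "n_offsets": 3,
            "which_ends": "both",
            "ci_method": "t",
            "thresholds": [22, 20, 18, 16, 15, 14, 13],
            "min_mean": 5.0,
            "test_method": "lrt",
            "gating_fold": 50.0,
            "depth_floor": 1.0e7,
        }
    )
    facs: dict = field(
        default_factory=lambda: {
            "n": 50_000,
            "high_frac": 0.002,
            "high_multiplier": 2000.0,
            "knockdown_factor": 20.0,
        }
    )
    plots: bool = False

    def __post_init__(self):
        if self.seed is None:
            raise ParameterError("config must set a seed")
        self.seed = int(self.seed)
        self.complementarity_spectrum = {int(k): int(v) for k, v in self.complementarity_spectrum.items()}

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if "seed" not in data:
            raise ParameterError("config must set a seed")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def content_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
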