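"""Run configuration for the assembly pipeline.

Precedence: explicit overrides (CLI flags) > config-file values >
built-in defaults. The effective configuration is echoed to the run log
for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields
from typing import List, Optional

import yaml


class ConfigError(ValueError):
    """Invalid assembly configuration."""


@dataclass
class AssemblyConfig:
    """All tunable parameters of the assembler.

    ``k_list`` is the ascending schedule of odd k-mer sizes for the
    iterative contig generation; the step between consecutive values is
    the amount by which contig-derived k-mers grow each iteration.
    ``alpha`` controls the adaptive extension threshold
    t_hq(c) = max(min_count, ceil(alpha * c)) used during de Bruijn
    traversal, so high-coverage genomes demand proportionally stronger
    extension evidence while low-coverage genomes can still assemble.
    """

    k_list: List[int] = field(default_factory=lambda: [21, 33, 55])
    qual_floor: int = 20
    min_count: int = 2
    alpha: float = 0.1
    hair_len_factor: int = 2
    bubble_len_factor: int = 3
    prune_ratio: float = 0.1
    prune_max_iters: int = 10
    seed_len: int = 31
    min_edge_support: int = 2
    fork_search_depth: int = 5
    depth_similarity_ratio: float = 2.0
    scaffold_rounds: int = 2
    insert_mu: float = 270.0
    insert_sigma: float = 30.0
    rng_seed: int = 1

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        ks = self.k_list
        if not ks:
            raise ConfigError("k_list must not be empty")
        if any(k % 2 == 0 for k in ks):
            raise ConfigError(f"k_list values must be odd, got {ks}")
        if any(k < 15 for k in ks):
            raise ConfigError(f"k_list values must be >= 15, got {ks}")
        if any(b >= a for a, b in zip(ks[1:], ks[:-1])):
            raise ConfigError(f"k_list must be strictly increasing, got {ks}")
        if self.min_count < 2:
            raise ConfigError("min_count must be >= 2")
        if self.scaffold_rounds < 1:
            raise ConfigError("scaffold_rounds must be >= 1")
        if not 0.0 < self.prune_ratio < 1.0:
            raise ConfigError("prune_ratio must lie in (0, 1)")
        if self.depth_similarity_ratio <= 1.0:
            raise ConfigError("depth_similarity_ratio must be > 1")
        if self.alpha <= 0:
            raise ConfigError("alpha must be positive")
        if self.insert_sigma <= 0 or self.insert_mu <= 0:
            raise ConfigError("insert size parameters must be positive")

    @classmethod
    def from_file(cls, path: str, **overrides) -> "AssemblyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping of parameters")
        return cls.from_dict({**data, **overrides})

    @classmethod
    def from_dict(cls, data: dict) -> "AssemblyConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown parameters: {sorted(unknown)}")
        if "k_list" in data and isinstance(data["k_list"], str):
            data = {**data, "k_list": [int(x) for x in data["k_list"].split(",")]}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def replace(self, **kwargs) -> "AssemblyConfig":
        d = self.to_dict()
        d.update(kwargs)
        return AssemblyConfig.from_dict(d)
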