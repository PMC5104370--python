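"""Analysis configuration: defaults, YAML round-trip, seed substreams.

The defaults encode the reference analysis settings: fixed sparsity 24% with a
24-50% sweep in 1% steps, 1000 degree-matched random networks, 1000 label
permutations, region-level FDR at 0.01, uncorrected edge-wise alpha 0.01, and
a 75 mm Euclidean cutoff between short- and long-range connections.

All stage randomness derives from one master seed through named substreams
(cohort, nulls, permutations, nodal), so individual stages can be re-run in
isolation and still reproduce the full pipeline's numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

SUBSTREAMS = ("cohort", "nulls", "permutations", "nodal")


@dataclass
class AnalysisConfig:
    cohort_csv: str | None = None
    regions_csv: str | None = None  # None -> packaged 90-region table
    output_dir: str = "metabnet_out"
    fixed_sparsity: float = 0.24
    sparsity_min: float = 0.24
    sparsity_max: float = 0.50
    sparsity_step: float = 0.01
    n_random_networks: int = 1000
    n_permutations: int = 1000
    fdr_alpha: float = 0.01
    edge_alpha: float = 0.01
    nodal_alpha: float = 0.05
    long_range_mm: float = 75.0
    normalization: str = "global-mean"
    ranking: str = "signed"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fixed_sparsity < 1:
            raise ValueError("fixed_sparsity must lie in (0, 1)")
        if not (0 < self.sparsity_min <= self.sparsity_max < 1):
            raise ValueError("sparsity range must satisfy 0 < min <= max < 1")
        if self.sparsity_step <= 0:
            raise ValueError("sparsity_step must be positive")
        if self.n_random_networks < 1 or self.n_permutations < 1:
            raise ValueError("replicate counts must be >= 1")

    def replace(self, **kwargs) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (output location excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("output_dir")
        text = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]

    # -- seeding ------------------------------------------------------------

    def substream_seed(self, name: str) -> int:
        """Deterministic child seed (< 2**31) for a named pipeline stage."""
        if name not in SUBSTREAMS:
            raise KeyError(f"unknown substream {name!r}; known: {SUBSTREAMS}")
        idx = SUBSTREAMS.index(name)
        state = np.random.SeedSequence(self.seed).generate_state(len(SUBSTREAMS))
        return int(state[idx] % (2**31))
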