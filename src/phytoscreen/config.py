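"""Run configuration: paths, thresholds and fingerprint parameters.

All thresholds default to the screen's published rules: edges at Tc >= 0.4,
candidate selection at average Tc > 0.4, target retention at mean score
> 0.1 from more than 2 compounds, and a top-5 cross-source overlap.
The config round-trips losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from phytoscreen.errors import ConfigurationError
from phytoscreen.network import ALL_KNOWNS, NEIGHBORS_ONLY


@dataclass
class RunConfig:
    # paths
    library: Optional[str] = None
    known_ids: Optional[str] = None        # text file, one compound_id per line
    predictions: Optional[str] = None      # long-format CSV
    predictions_glob: Optional[str] = None # per-compound CSVs, stem = compound_id
    gene_sets: dict = field(default_factory=dict)  # source label -> GMT path
    out_dir: str = "results"
    # thresholds
    edge_tc: float = 0.4
    selection_avg_tc: float = 0.4
    target_score: float = 0.1
    target_support: int = 2
    top_k: int = 5
    # fingerprints
    radius: int = 2
    n_bits: int = 2048
    use_chirality: bool = False
    # behavior
    averaging_mode: str = ALL_KNOWNS
    name_matcher: str = "normalized"
    strip_salts: bool = True
    dedup: bool = True
    seed: int = 0

    def validate(self) -> "RunConfig":
        for label, value in (("edge_tc", self.edge_tc),
                             ("selection_avg_tc", self.selection_avg_tc),
                             ("target_score", self.target_score)):
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{label} must be in [0, 1], got {value}")
        if self.target_support < 0:
            raise ConfigurationError("target_support must be >= 0")
        if self.top_k < 1:
            raise ConfigurationError("top_k must be >= 1")
        if self.radius < 0 or self.n_bits < 1:
            raise ConfigurationError("fingerprint parameters out of domain")
        if self.averaging_mode not in (ALL_KNOWNS, NEIGHBORS_ONLY):
            raise ConfigurationError(f"unknown averaging_mode {self.averaging_mode!r}")
        if self.name_matcher not in ("exact", "normalized"):
            raise ConfigurationError(f"unknown name_matcher {self.name_matcher!r}")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data).validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(Path(path)) as handle:
            data = yaml.safe_load(handle) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config root must be a mapping: {path}")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(Path(path), "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=True)
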