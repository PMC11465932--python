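"""Pipeline configuration: one object holding every tunable of the workflow."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .exceptions import ValidationError


@dataclass
class PipelineConfig:
    """All thresholds, weights and switches of the pipeline.

    The defaults encode the published analysis settings: attribute weights
    45/35/20, Criterion-1 threshold k=1, network-metric threshold k=1.5,
    collective-influence radius 3, all-shortest-paths extension, final
    [1,100] rescales on.
    """

    # input paths (filled per run)
    gene_table: str = ""
    edge_list: str = ""
    gene_map: str = ""
    gene_sets: str = ""
    out_dir: str = "results"

    weights: tuple = (0.45, 0.35, 0.20)
    criterion1_k: float = 1.0
    criterion2_k: float = 1.5
    ci_radius: int = 3
    path_policy: str = "all_shortest"
    final_rescale_score: bool = True
    final_rescale_ivi: bool = True
    enrichment_mode: str = "hypergeometric"
    genome_wide_p: float = 5e-8
    hub_threshold: int = 300
    seed: int = 0

    def __post_init__(self):
        self.weights = tuple(self.weights)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["weights"] = list(self.weights)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    def digest(self) -> str:
        """Stable hash of the configuration (used in the run manifest)."""
        data = asdict(self)
        data["weights"] = list(self.weights)
        blob = json.dumps(data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def default_config() -> PipelineConfig:
    return PipelineConfig()
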