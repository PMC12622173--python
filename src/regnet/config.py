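"""Pipeline configuration: one JSON document with per-stage sections.

All numeric defaults are the analysis constants the pipeline ships with:
low-signal tag-count floor 4, fold-change cutoff 2, adjusted-p cutoff 0.05,
co-occurrence edge p threshold 0.001, minimum clique size 3, hub degree 10.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

DEFAULTS: dict[str, Any] = {
    "min_tag_count": 4,
    "fc_threshold": 2.0,
    "alpha": 0.05,
    "edge_alpha": 0.001,
    "min_clique_size": 3,
    "hub_degree": 10,
    "rrho_step": None,  # auto: <=100x100 grid
    "seed": 0,
}


@dataclass
class PipelineConfig:
    """Validated run configuration; paths may be None for unused stages."""

    fasta: str | None = None
    bed: str | None = None
    counts: str | None = None
    groups: str | None = None
    motifs: str | None = None
    tss: str | None = None
    de_a: str | None = None
    de_b: str | None = None
    expression: str | None = None
    clusters: str | None = None
    signature: str | None = None
    min_tag_count: int = DEFAULTS["min_tag_count"]
    fc_threshold: float = DEFAULTS["fc_threshold"]
    alpha: float = DEFAULTS["alpha"]
    edge_alpha: float = DEFAULTS["edge_alpha"]
    min_clique_size: int = DEFAULTS["min_clique_size"]
    hub_degree: int = DEFAULTS["hub_degree"]
    rrho_step: int | None = DEFAULTS["rrho_step"]
    seed: int = DEFAULTS["seed"]
    simulate: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0,1)")
        if not 0.0 <= self.edge_alpha <= 1.0:
            raise ValueError("edge_alpha must be in [0,1]")
        if self.fc_threshold <= 1.0:
            raise ValueError("fc_threshold must exceed 1")
        if self.min_clique_size < 2:
            raise ValueError("min_clique_size must be >= 2")
        if self.hub_degree < 0 or self.min_tag_count < 0:
            raise ValueError("hub_degree and min_tag_count must be non-negative")

    def validate_paths(self, required: list[str]) -> None:
        for key in required:
            value = getattr(self, key)
            if value is None:
                raise ValueError(f"config path {key!r} is not set")
            if not Path(value).exists():
                raise FileNotFoundError(f"config path {key!r} missing: {value}")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def default_config() -> dict[str, Any]:
    """The shipped default constants (a copy)."""
    return dict(DEFAULTS)
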