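"""Pipeline configuration: every tunable of the analysis in one place.

Defaults are the values used throughout the study this pipeline reproduces:
>= 4 supporting probes per lncRNA, Z.K/Z.C outlier cuts of -2/+2, a power
grid 1..20 with a scale-free R^2 threshold of 0.80, minimum module size 30,
a dual 0.8 hub-correlation rule, and FDR < 0.05.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    seed: int = 0
    # probe reannotation
    min_probes: int = 4
    probe_length: int = 25
    # sample QC
    zk_cut: float = -2.0
    zc_cut: float = 2.0
    quantile_normalize: bool = True
    # network
    power: int | None = None  # None = pick automatically from the scan
    power_grid: tuple[int, ...] = tuple(range(1, 21))
    r2_threshold: float = 0.80
    min_module_size: int = 30
    cut_quantile: float = 0.99
    # hubs
    hub_threshold: float = 0.8
    mix_weight: float = 0.5
    # enrichment / survival
    fdr_cutoff: float = 0.05

    def __post_init__(self) -> None:
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")
        if not 0 < self.cut_quantile <= 1:
            raise ValueError("cut_quantile must lie in (0, 1]")
        if not 0 < self.hub_threshold < 1:
            raise ValueError("hub_threshold must lie in (0, 1)")
        if not 0 <= self.mix_weight <= 1:
            raise ValueError("mix_weight must lie in [0, 1]")
        if not 0 < self.fdr_cutoff < 1:
            raise ValueError("fdr_cutoff must lie in (0, 1)")
        self.power_grid = tuple(int(p) for p in self.power_grid)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config file, rejecting unknown keys."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["power_grid"] = list(self.power_grid)
        return d
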