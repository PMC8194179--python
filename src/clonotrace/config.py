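"""Pipeline configuration.

Defaults are the published cut-offs of the study design: FDR < 0.05,
log2CPM > 2 abundance filter, significance in at least 3 of 5 contrasts,
overrepresentation retained when > 3-fold enriched in at least 2 analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

import yaml

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class PipelineConfig:
    fdr_max: float = 0.05
    min_log2cpm: float = 2.0
    min_datasets: int = 3
    ora_min_fold: float = 3.0
    ora_min_analyses: int = 2
    onset_rel_threshold: float = 0.05
    onset_consecutive: int = 2
    junction_align: str = "midpoint"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.fdr_max <= 1:
            raise ValueError("fdr_max must lie in (0, 1]")
        if not 1 <= self.min_datasets <= 5:
            raise ValueError("min_datasets must lie in 1..5")
        if self.ora_min_fold <= 0:
            raise ValueError("ora_min_fold must be positive")
        if self.ora_min_analyses < 1:
            raise ValueError("ora_min_analyses must be >= 1")
        if self.onset_rel_threshold <= 0:
            raise ValueError("onset_rel_threshold must be positive")
        if self.onset_consecutive < 1:
            raise ValueError("onset_consecutive must be >= 1")
        if self.junction_align not in ("midpoint", "peak"):
            raise ValueError("junction_align must be 'midpoint' or 'peak'")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


def load_config(path) -> PipelineConfig:
    """Read a YAML config; unknown keys are rejected, defaults fill gaps."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    valid = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}; "
                         f"valid keys: {sorted(valid)}")
    return PipelineConfig(**raw)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
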