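"""Pipeline thresholds.

Every numeric cut used anywhere in the pipeline lives in
:class:`PipelineConfig`; no stage carries hidden defaults.  The config can be
round-tripped through a flat YAML mapping.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised for an inconsistent or unknown configuration."""


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds of the CNA → SV → promoter-substitution → expression screen.

    Log2-ratio state boundaries (``homdel_max`` .. ``gain_max``) partition the
    real line into the five copy-number states HOMDEL / HEMIDEL / NEUTRAL /
    GAIN / AMP.  Distances are in base pairs on 1-based closed intervals.
    """

    # log2-ratio state boundaries
    homdel_max: float = -1.0
    hemidel_max: float = -0.2
    neutral_max: float = 0.3
    gain_max: float = 0.7
    # segment hygiene
    merge_gap_max: int = 100_000
    nodata_gap_min: int = 100_000
    # SV filters
    sv_min_size: int = 15_000
    telocent_excl: int = 2_000_000
    # promoter-substitution rules
    upstream_window: int = 200_000
    stronger_promoter_fold: float = 2.0
    recurrence_min: int = 2
    fdr_level: float = 0.10
    # WGS concordance
    wgs_match_tol: int = 100_000

    def __post_init__(self) -> None:
        if not (self.homdel_max < self.hemidel_max < self.neutral_max < self.gain_max):
            raise ConfigError("state thresholds must be strictly increasing")
        for name in ("merge_gap_max", "nodata_gap_min", "sv_min_size",
                     "telocent_excl", "wgs_match_tol"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        # 0 is meaningful for the upstream window: it disables UPSTREAM events.
        if self.upstream_window < 0:
            raise ConfigError("upstream_window must be non-negative")
        if self.stronger_promoter_fold <= 0:
            raise ConfigError("stronger_promoter_fold must be positive")
        if self.recurrence_min < 1:
            raise ConfigError("recurrence_min must be at least 1")
        if not 0 < self.fdr_level <= 1:
            raise ConfigError("fdr_level must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a flat key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))
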