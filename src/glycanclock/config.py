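"""Run configuration: schema-validated YAML/JSON settings for the CLI."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

_KNOWN_KEYS = {
    "cohorts", "excluded_peaks", "eb_covariates", "seed", "bootstrap",
    "grid", "output_dir", "batch_correction", "children", "pca_components",
}


class ConfigError(ValueError):
    """Invalid or unknown configuration."""


@dataclass
class RunConfig:
    cohorts: list[str] = field(default_factory=lambda: ["FRA", "ITA", "UK"])
    excluded_peaks: list[str] = field(default_factory=lambda: ["GP20", "GP21"])
    eb_covariates: list[str] = field(default_factory=lambda: ["group", "age", "sex"])
    seed: int = 0
    bootstrap: int = 0
    grid: list[float] | None = None
    output_dir: str = "glycanclock_out"
    batch_correction: bool = True
    children: bool = True
    pca_components: int = 3

    def __post_init__(self) -> None:
        from .simulate import DEFAULT_COHORTS
        from .traits import PEAKS

        unknown = [c for c in self.cohorts if c not in DEFAULT_COHORTS]
        if unknown:
            raise ConfigError(f"unknown cohort(s): {unknown}")
        bad = [p for p in self.excluded_peaks if p not in PEAKS]
        if bad:
            raise ConfigError(f"unknown excluded peak(s): {bad}")
        if self.seed < 0:
            raise ConfigError("seed must be non-negative")
        if self.bootstrap and self.bootstrap < 200:
            raise ConfigError("bootstrap must be 0 or >= 200 replicates")
        if self.pca_components < 1:
            raise ConfigError("pca_components must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError("config must be a mapping")
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
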