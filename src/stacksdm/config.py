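"""Run configuration: one flat YAML file drives the whole pipeline.

Every protocol constant is explicit in the config with its standard default —
10,000 background/pseudo-absence points, 70/30 train/test split, five
replicates per model family, the 4% contribution and |r| ≥ 0.7 correlation
screening rules with a three-predictor floor, the TSS < 0.7 ensemble exclusion
cutoff, Jenks k = 5 — so a run directory records exactly what it was run with.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .grid import GridSpec
from .models import FAMILIES
from .synthetic import ScenarioConfig


@dataclass
class WorldConfig:
    n_rows: int = 360
    n_cols: int = 720
    lon_min: float = -180.0
    lat_min: float = -90.0
    cell_size: float = 0.5
    sst_anomaly_2050: float = 1.2
    sst_anomaly_2100: float = 2.4
    arctic_lat_min: float = 60.0

    def scenario_config(self, seed: int) -> ScenarioConfig:
        return ScenarioConfig(
            grid=GridSpec(self.n_rows, self.n_cols, self.lon_min, self.lat_min, self.cell_size),
            sst_anomaly_2050=self.sst_anomaly_2050,
            sst_anomaly_2100=self.sst_anomaly_2100,
            arctic_lat_min=self.arctic_lat_min,
            seed=seed,
        )


@dataclass
class RunConfig:
    """Full pipeline configuration with the standard protocol defaults."""

    seed: int = 0
    world: WorldConfig = field(default_factory=WorldConfig)
    species: str = "default_roster"  # or a directory of occurrence CSVs
    n_presences: int = 500
    contamination: float = 0.0
    families: list[str] = field(default_factory=lambda: list(FAMILIES))
    n_background: int = 10_000
    n_replicates: int = 5
    train_fraction: float = 0.7
    contribution_threshold: float = 4.0
    correlation_threshold: float = 0.7
    min_predictors: int = 3
    tss_exclusion: float = 0.7
    exclusion_rule: str = "or"  # "or" | "and"
    jenks_k: int = 5
    screen_jackknife: bool = True

    def __post_init__(self) -> None:
        unknown = set(self.families) - set(FAMILIES)
        if unknown:
            raise ValueError(f"unknown model families: {sorted(unknown)}")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.exclusion_rule not in ("or", "and"):
            raise ValueError("exclusion_rule must be 'or' or 'and'")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        world = d.pop("world", {})
        return cls(world=WorldConfig(**world), **d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
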