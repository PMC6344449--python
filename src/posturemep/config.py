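"""Run configuration: one YAML file governs generation, pipelines and stats.

Every stochastic step is seeded from the config; serializing and re-loading a
config reproduces the run exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synth import PopulationConfig

__all__ = ["PipelineConfig", "StatsConfig", "RunConfig", "default_config"]


@dataclass
class PipelineConfig:
    #: re-apply the 15-1000 Hz band-pass digitally before analysis (the
    #: acquisition chain is assumed to have applied it in hardware, so the
    #: default is off)
    refilter: bool = False
    filter_low_hz: float = 15.0
    filter_high_hz: float = 1000.0
    quartile_method: str = "tukey"  # "tukey" | "linear"
    onset_bga_window_ms: float = 100.0
    onset_hold_ms: float = 10.0
    onset_search_ms: float = 300.0
    iemg_window_ms: float = 100.0


@dataclass
class StatsConfig:
    alpha: float = 0.05
    sphericity_policy: str = "mauchly"  # "mauchly" | "always" | "never"
    mauchly_alpha: float = 0.05


@dataclass
class RunConfig:
    generator: PopulationConfig = field(default_factory=PopulationConfig)
    cohort_seed: int = 2019
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    write_trials: bool = False  # write the raw trial CSVs alongside tables

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"]["mmax_sweep_fractions"] = list(
            self.generator.mmax_sweep_fractions
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        gen = dict(d.get("generator", {}))
        if "mmax_sweep_fractions" in gen:
            gen["mmax_sweep_fractions"] = tuple(gen["mmax_sweep_fractions"])
        return cls(
            generator=PopulationConfig(**gen),
            cohort_seed=d.get("cohort_seed", 2019),
            pipeline=PipelineConfig(**d.get("pipeline", {})),
            stats=StatsConfig(**d.get("stats", {})),
            write_trials=d.get("write_trials", False),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_config() -> RunConfig:
    """The packaged calibrated default configuration (12-subject cohort)."""
    return RunConfig()
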