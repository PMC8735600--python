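"""Declarative pipeline configuration.

One YAML file drives an end-to-end run.  Defaults are the study parameters:
the 120 m / 4.5 km coastal window, 2% prevalence, 300% over-range, -0.25
tide and 0.2 / 5 km coherence correlation cutoffs, the 13% fractional-cover
binarization, consensus 8 of 15 annotators, the 25% composite completeness
rule, July–June annual intervals, trend/correlation significance at 0.01,
and environmental lags of at most one year.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid pipeline configuration; lists the offending keys."""


@dataclass
class PipelineConfig:
    # global
    seed: int = 0
    out_dir: str = "kelpcanopy_run"
    stages: list[str] = field(default_factory=lambda: [
        "simulate", "classify", "filter", "consensus",
        "validate", "timeseries", "env",
    ])

    # synthetic scene generation
    grid_rows: int = 120
    grid_cols: int = 120
    pixel_size: float = 30.0
    n_dates: int = 24
    span_days: float = 3650.0
    noise_sd: float = 0.005
    n_beds: int = 5
    tide_amplitude: float = 0.5

    # spectral classifier
    n_water_endmembers: int = 30
    tree_max_depth: int = 5
    candidate_label_fraction: float = 0.05
    threshold_fraction: float = 0.13

    # post-processing filters
    d_min: float = 120.0
    d_max: float = 4500.0
    p_min: float = 0.02
    f_max: float = 3.0
    tide_r_min: float = -0.25
    coherence_r_min: float = 0.2
    coherence_radius: float = 5000.0

    # citizen-science consensus
    n_users: int = 15
    consensus_tau: int = 8
    min_completeness: float = 0.25
    excluded_tiles: list[int] = field(default_factory=list)

    # timeseries / environment
    interval: str = "annual"
    trend_alpha: float = 0.01
    env_lag: int = 1
    n_env_years: int = 35
    driver_noise_var: float = 1.367

    def validate(self) -> None:
        problems = []
        if not 1 <= self.consensus_tau <= self.n_users:
            problems.append(
                f"consensus_tau={self.consensus_tau} outside [1, {self.n_users}]")
        if self.env_lag not in (0, 1):
            problems.append(f"env_lag={self.env_lag} not in {{0, 1}}")
        if not 0 < self.threshold_fraction < 1:
            problems.append(f"threshold_fraction={self.threshold_fraction}")
        if self.d_min < 0 or self.d_max <= self.d_min:
            problems.append(f"distance window [{self.d_min}, {self.d_max}]")
        if not 0 <= self.p_min <= 1:
            problems.append(f"p_min={self.p_min}")
        if not 0 <= self.min_completeness <= 1:
            problems.append(f"min_completeness={self.min_completeness}")
        if self.interval not in ("annual", "seasonal"):
            problems.append(f"interval={self.interval!r}")
        if self.n_dates < 2:
            problems.append(f"n_dates={self.n_dates}")
        unknown = set(self.stages) - {"simulate", "classify", "filter",
                                      "consensus", "validate", "timeseries", "env"}
        if unknown:
            problems.append(f"unknown stages {sorted(unknown)}")
        if problems:
            raise ConfigError("invalid configuration: " + "; ".join(problems))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg
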