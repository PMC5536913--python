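"""Run configuration: every tunable default of the pipeline in one
YAML-loadable object."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    """Tunable defaults of the analysis stages.

    band_depth : dorsal sampling band, as fractions of the semi-minor
        axis inward from the dorsal boundary.
    dip_prominence : minimum dip prominence as a fraction of the
        amplitude maximum.
    cycle14_window_start : minutes after the 13th division at which the
        plateau-averaging window opens.
    lambda_bounds / hill_n_bounds : box constraints of the Hill fit.
    noise_* : synthetic imaging-noise defaults.
    """

    n_positions: int = 100
    band_depth: tuple[float, float] = (0.05, 0.15)
    n_depths: int = 5
    polarity: str = "keep"
    dip_prominence: float = 0.15
    dip_smooth_window: int = 3
    cycle14_window_start: float = 20.0
    lambda_bounds: tuple[float, float] = (0.01, 0.39)
    hill_n_bounds: tuple[float, float] = (0.5, 30.0)
    variance_mode: str = "pooled"
    noise_additive_sd: float = 2.0
    noise_multiplicative_cv: float = 0.05
    grid_step: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("band_depth", "lambda_bounds", "hill_n_bounds"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))
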