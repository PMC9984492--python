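"""Run configuration: schema-validated blocks, YAML round-trip, config hash."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

__all__ = ["RunConfig", "load_config", "default_config"]


class GeometryConfig(BaseModel):
    """Initial disc geometry in units of the initial DP thickness."""

    outer_radius: float = 2.5
    h_dp: float = 1.0
    h_ecm: float = 0.1

    @field_validator("outer_radius", "h_dp", "h_ecm")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("geometry lengths must be positive")
        return v


class MaterialConfig(BaseModel):
    mu_ratio: float = 25.0  # mu_ECM / mu_DP
    bulk_to_shear: float = 1000.0

    @field_validator("mu_ratio")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("mu_ratio must be positive")
        return v

    @field_validator("bulk_to_shear")
    @classmethod
    def _nearly_incompressible(cls, v: float) -> float:
        if v < 100:
            raise ValueError("bulk_to_shear must be >= 100")
        return v


class GrowthFitConfig(BaseModel):
    mode: str = "log-linear"  # or "linear"
    rho: float = 0.45
    dp_series: str | None = None  # CSV paths; packaged fixtures when None
    ecm_series: str | None = None

    @field_validator("mode")
    @classmethod
    def _mode(cls, v: str) -> str:
        if v not in ("log-linear", "linear"):
            raise ValueError("mode must be 'log-linear' or 'linear'")
        return v

    @field_validator("rho")
    @classmethod
    def _rho(cls, v: float) -> float:
        if v < 0:
            raise ValueError("rho must be non-negative")
        return v


class SimulationConfig(BaseModel):
    times: list[float] = Field(default_factory=lambda: [72.0, 80.0, 96.0, 118.0])
    resolution: int = 2
    n_increments: int = 8

    @field_validator("resolution")
    @classmethod
    def _res(cls, v: int) -> int:
        if v < 2:
            raise ValueError("resolution must be >= 2")
        return v


class PhaseDiagramConfig(BaseModel):
    rho_grid: list[float] = Field(
        default_factory=lambda: [round(0.05 * i, 2) for i in range(21)]
    )
    mu_grid: list[float] = Field(
        default_factory=lambda: [1.0, 1.8, 3.2, 5.6, 10.0, 14.0, 18.0, 25.0, 32.0, 56.0, 100.0]
    )
    tolerance: float = 0.224

    @field_validator("tolerance")
    @classmethod
    def _tol(cls, v: float) -> float:
        if not (0 < v < 1):
            raise ValueError("tolerance must be in (0, 1)")
        return v


class RunConfig(BaseModel):
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    material: MaterialConfig = Field(default_factory=MaterialConfig)
    growth_fit: GrowthFitConfig = Field(default_factory=GrowthFitConfig)
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    phase_diagram: PhaseDiagramConfig = Field(default_factory=PhaseDiagramConfig)
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def write_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))
        return path


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(data)


def default_config() -> RunConfig:
    return RunConfig()
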