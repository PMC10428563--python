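"""Validated run configuration for the end-to-end pipeline."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .simulate import CohortConfig, FrequencyGrid


class GridSettings(BaseModel):
    f_min_mhz: float = 70.0
    f_max_mhz: float = 90.0
    n_points: int = Field(default=201, ge=2)

    @model_validator(mode="after")
    def _range_ok(self):
        if self.f_max_mhz <= self.f_min_mhz:
            raise ValueError("f_max_mhz must exceed f_min_mhz")
        return self


class CohortSettings(BaseModel):
    n_experimental: int = Field(default=8, ge=1)
    n_control: int = Field(default=5, ge=1)
    eta_range_h: tuple[float, float] = (5.0, 7.0)
    nadir_depth_mean_deg: float = Field(default=-36.0, lt=0)
    nadir_depth_sd_deg: float = Field(default=6.0, ge=0)
    recovery_fraction_mean: float = Field(default=0.7, ge=0, le=1)
    recovery_fraction_sd: float = Field(default=0.08, ge=0)
    recovery_fast_hours: float = Field(default=8.0, gt=0)
    recovery_fast_weight: float = Field(default=0.5, ge=0, le=1)
    control_drift_mean_deg: float = -0.12
    control_drift_sd_deg: float = Field(default=0.05, ge=0)
    noise_sd_deg: float = Field(default=1.0, ge=0)
    hemisphere_asym_sd_deg: float = Field(default=0.3, ge=0)

    @field_validator("eta_range_h")
    @classmethod
    def _eta_ok(cls, v):
        lo, hi = v
        if not 0 < lo <= hi:
            raise ValueError(f"invalid eta range {v}")
        return v


class ProtocolSettings(BaseModel):
    combinations: list[str] = ["a", "b", "ab", "ad", "abg"]
    c_min: float = Field(default=0.1, gt=0)
    c_max: float = Field(default=10.0, gt=0)
    c_step: float = Field(default=0.1, gt=0)
    folds: int = Field(default=10, ge=2)
    states: list[int] = [1, 2, 3, 4, 5]
    split_ratio: tuple[int, int, int] = (6, 2, 2)
    standardize: bool = False

    def c_grid(self) -> list[float]:
        n = int(round((self.c_max - self.c_min) / self.c_step)) + 1
        return [round(self.c_min + i * self.c_step, 10) for i in range(n)]


class RunConfig(BaseModel):
    """Fully resolved pipeline configuration; written alongside every run."""

    master_seed: int = Field(default=0, ge=0, lt=2**31)
    grid: GridSettings = Field(default_factory=GridSettings)
    band_mhz: tuple[float, float] = (83.0, 87.0)
    cohort: CohortSettings = Field(default_factory=CohortSettings)
    protocol: ProtocolSettings = Field(default_factory=ProtocolSettings)

    def cohort_config(self) -> CohortConfig:
        g = self.grid
        c = self.cohort
        return CohortConfig(
            n_experimental=c.n_experimental,
            n_control=c.n_control,
            grid=FrequencyGrid(g.f_min_mhz, g.f_max_mhz, g.n_points),
            band_mhz=self.band_mhz,
            eta_range_h=c.eta_range_h,
            nadir_depth_mean_deg=c.nadir_depth_mean_deg,
            nadir_depth_sd_deg=c.nadir_depth_sd_deg,
            recovery_fraction_mean=c.recovery_fraction_mean,
            recovery_fraction_sd=c.recovery_fraction_sd,
            recovery_fast_hours=c.recovery_fast_hours,
            recovery_fast_weight=c.recovery_fast_weight,
            control_drift_mean_deg=c.control_drift_mean_deg,
            control_drift_sd_deg=c.control_drift_sd_deg,
            noise_sd_deg=c.noise_sd_deg,
            hemisphere_asym_sd_deg=c.hemisphere_asym_sd_deg,
        )

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} else json.loads(text)
        return cls.model_validate(data or {})

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.model_dump(), indent=1, sort_keys=True))
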