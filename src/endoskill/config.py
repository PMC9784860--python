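"""Run configuration.

All constants of the scoring model live here with their published defaults:
the frame-difference threshold ``DTh = 50`` grayscale units, the saturation
threshold 245, the 0.3 s differencing interval, the 5 min time budget
``Tmax``, the normality-test alpha 0.05 and the significance level 0.01.
The coverage band cutoffs ``eps_low``/``eps_high`` are calibration
parameters of the simulator deployment (the model fixes their role, not
their values); the defaults below are the package's calibration.

Configs are pydantic models; a full :class:`RunConfig` can be loaded from a
YAML file and selectively overridden by the CLI.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, model_validator

from .errors import SchemaError


class MotionConfig(BaseModel):
    """Parameters of the fine-movement (frame-differencing) metric."""

    diff_threshold: int = Field(default=50, gt=0, lt=255,
                                description="DTh, grayscale units")
    eps_low: float = Field(default=0.5, ge=0.0, le=100.0,
                           description="lower coverage cutoff, % of frame")
    eps_high: float = Field(default=20.0, ge=0.0, le=100.0,
                            description="upper coverage cutoff, % of frame")
    interval: float = Field(default=0.3, gt=0.0,
                            description="frame-differencing interval, s")

    @model_validator(mode="after")
    def _check_band(self) -> "MotionConfig":
        if not self.eps_low < self.eps_high:
            raise ValueError("eps_low must be strictly below eps_high")
        return self


class ExposureConfig(BaseModel):
    """Parameters of the visualization (over-exposure) metric."""

    saturation_threshold: int = Field(default=245, gt=0, lt=255)
    min_blob_area: float = Field(default=0.02, ge=0.0,
                                 description="denoise area floor, % of frame")
    opening_size: int = Field(default=3, ge=1,
                              description="square opening footprint, px")
    interval: float = Field(default=0.3, gt=0.0,
                            description="frame sampling cadence, s")
    full_rate: bool = Field(default=False,
                            description="evaluate every frame instead of the 0.3 s cadence")
    # Annulus breaks and weights of the centre-distance weighting, in units
    # of the half-diagonal r: weight 1 inside r/3, 2/3 up to 2r/3, 1/3 beyond.
    weight_breaks: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)
    weights: tuple[float, float, float] = (1.0, 2.0 / 3.0, 1.0 / 3.0)

    @model_validator(mode="after")
    def _check_breaks(self) -> "ExposureConfig":
        lo, hi = self.weight_breaks
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("weight_breaks must satisfy 0 < lo < hi < 1")
        return self


class EfficiencyConfig(BaseModel):
    """Parameters of the efficiency metric."""

    t_max: float = Field(default=5.0, gt=0.0,
                         description="maximum allowed procedure time, min")
    clamp_negative: bool = Field(default=True,
                                 description="clamp the duration score at 0 when T >= t_max")


class StatsConfig(BaseModel):
    """Group-comparison settings."""

    alpha: float = Field(default=0.05, gt=0.0, lt=1.0,
                         description="normality-test level")
    p_threshold: float = Field(default=0.01, gt=0.0, lt=1.0,
                               description="significance level for the group test")
    test: str = Field(default="welch", pattern="^(welch|pooled|ranksum)$")
    normality: str = Field(default="ks", pattern="^(ks|lilliefors)$")


class RunConfig(BaseModel):
    """Everything a scoring run needs, with full provenance."""

    motion: MotionConfig = Field(default_factory=MotionConfig)
    exposure: ExposureConfig = Field(default_factory=ExposureConfig)
    efficiency: EfficiencyConfig = Field(default_factory=EfficiencyConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)
    fps: float = Field(default=60.0, gt=0.0,
                       description="fallback fps for frame directories without metadata")
    log_level: str = Field(default="INFO")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            with open(path) as fh:
                payload = yaml.safe_load(fh) or {}
        except OSError as exc:
            raise SchemaError(f"cannot read config file {path}: {exc}") from exc
        try:
            return cls.model_validate(payload)
        except ValueError as exc:
            raise SchemaError(f"invalid config {path}: {exc}") from exc

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)
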