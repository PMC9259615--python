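"""Validated pipeline configuration (JSON or YAML).

A config file may specify as little as ``{"seed": 1}``; every other field has
a materialized default.  Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import pydantic
import yaml
from pydantic import BaseModel, Field, model_validator

from .errors import ConfigError, InputError


class _Strict(BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")


class ModelBlock(_Strict):
    """Overrides for the reaction-model rate constants."""
    k_pol: float = 5.0e-3
    K_m: float = 50.0
    K_i: float = 100.0
    k_exo: float = 0.4
    K_exo: float = 50.0
    k_ex: float = 0.03
    P: float = 1.0
    E: float = 0.6
    seq: float = 5.7
    alpha: float = 10.0
    F0: float = 50.0
    c_ext: float = 0.1


class SimulateBlock(_Strict):
    enabled: bool = True
    n_compartments: int = Field(6, ge=1)
    mean_radius_um: float = Field(10.0, gt=0)
    radius_rsd_pct: float = Field(5.0, ge=0, lt=100)
    radius_shape: Literal["normal", "lognormal"] = "normal"
    volume_fraction: float = Field(0.005, gt=0, lt=1)
    template_uM: float = Field(0.12, ge=0)
    primer0_nM: float = Field(1.0, ge=0)
    duration_min: float = Field(480.0, gt=0)
    dt_min: float = Field(3.0, gt=0)
    noise_sd_rfu: float = Field(5.0, ge=0)


class SegmentBlock(_Strict):
    pixel_size_um: float = Field(0.5, gt=0)
    blur_sigma_px: float = Field(2.0, ge=0)
    threshold_method: str = "otsu"
    circularity_range: tuple[float, float] = (0.7, 1.0)
    diameter_range_um: tuple[float, float] = (17.0, 25.0)
    frame_shape: tuple[int, int] = (300, 300)
    frame_interval_min: float = Field(3.0, gt=0)

    @model_validator(mode="after")
    def _ranges(self):
        lo, hi = self.circularity_range
        if not (0 <= lo <= hi <= 1.1):
            raise ValueError("circularity_range must be ordered within [0, 1.1]")
        lo, hi = self.diameter_range_um
        if not (0 < lo <= hi):
            raise ValueError("diameter_range_um must be ordered and positive")
        return self


class KineticsBlock(_Strict):
    fallback_fraction: float = Field(0.6, gt=0, le=1)
    rate_mode: Literal["k", "slope"] = "slope"
    normalize: Optional[Literal["minmax", "to_point"]] = None
    smooth_differences: bool = False


class FrapBlock(_Strict):
    enabled: bool = False
    input_csv: Optional[str] = None
    spot_radius_um: float = Field(2.0, gt=0)
    mode: Literal["standard", "whole_droplet"] = "standard"
    t0_s: float = 0.0


class PipelineConfig(_Strict):
    seed: int = 0
    outdir: str = "results/pipeline"
    stack_tiff: Optional[str] = None   # input stack when simulate.enabled=False
    model: ModelBlock = ModelBlock()
    simulate: SimulateBlock = SimulateBlock()
    segment: SegmentBlock = SegmentBlock()
    kinetics: KineticsBlock = KineticsBlock()
    frap: FrapBlock = FrapBlock()

    def to_dict(self) -> dict:
        return json.loads(self.model_dump_json())


def load_config(path) -> PipelineConfig:
    """Load and validate a JSON or YAML config, filling defaults."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"config file not found: {path}")
    text = path.read_text()
    try:
        if path.suffix.lower() in (".yaml", ".yml"):
            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise InputError(f"cannot parse config {path}: {exc}") from None
    return validate_config(data)


def validate_config(data: dict) -> PipelineConfig:
    try:
        return PipelineConfig.model_validate(data)
    except pydantic.ValidationError as exc:
        problems = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors())
        raise ConfigError(f"invalid configuration: {problems}") from None


def save_config(config: PipelineConfig, path) -> None:
    path = Path(path)
    data = config.to_dict()
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2))
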