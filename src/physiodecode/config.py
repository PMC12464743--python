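"""Pipeline configuration: YAML file + dotted-path overrides, validated.

Defaults follow the study conditions: 6-s extraction window, 0.01-0.15 Hz
band, hidden state 2000, batch 16, dropout 0.3, lr 1e-3 with plateau decay
0.5 / patience 2, DMN seed at MNI (2, -58, 30).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = ["PipelineConfig", "load_config"]


class PhysioParams(BaseModel):
    model_config = ConfigDict(extra="forbid")

    window: float = Field(6.0, gt=0)
    band: tuple[float, float] = (0.01, 0.15)
    fs: float = Field(400.0, gt=0)
    dt_out: float = Field(1.44, gt=0)

    @field_validator("band")
    @classmethod
    def _band_ordered(cls, v):
        if not (0 < v[0] < v[1]):
            raise ValueError("band must satisfy 0 < f_lo < f_hi")
        return v


class ModelParams(BaseModel):
    model_config = ConfigDict(extra="forbid")

    hidden_size: int = Field(2000, ge=1)
    batch_size: int = Field(16, ge=1)
    dropout: float = Field(0.3, ge=0, lt=1)
    lr: float = Field(1e-3, gt=0)
    lr_decay: float = Field(0.5, gt=0, lt=1)
    patience: int = Field(2, ge=1)
    max_epochs: int = Field(100, ge=1)
    early_stop: int = Field(6, ge=1)
    input_rois: Optional[list[int]] = None


class AnalysisParams(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed_coordinate: tuple[float, float, float] = (2.0, -58.0, 30.0)
    seed_radius_mm: float = Field(0.0, ge=0)
    include_motion: bool = True
    kernel_support: float = Field(60.0, gt=0)


class SimulateParams(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_scans: int = Field(8, ge=1)
    n_rois: int = Field(50, ge=1)
    n_frames: int = Field(300, ge=10)
    dt: float = Field(1.44, gt=0)
    rho: float = Field(0.275, gt=-1, lt=1)
    varexp_target: Optional[float] = Field(None, gt=0, lt=1)
    noise_sd: float = Field(1.7, ge=0)
    scans_per_subject: int = Field(4, ge=1)
    with_raw: bool = False


class PathParams(BaseModel):
    model_config = ConfigDict(extra="forbid")

    output_dir: Path = Path("physiodecode_out")
    atlas_manifest: Optional[Path] = None


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    paths: PathParams = PathParams()
    physio: PhysioParams = PhysioParams()
    model: ModelParams = ModelParams()
    analysis: AnalysisParams = AnalysisParams()
    simulate: SimulateParams = SimulateParams()
    seed: int = 0
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _check_log_level(self):
        if self.log_level.upper() not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ValueError(f"invalid log level {self.log_level!r}")
        return self


def _coerce(value: str):
    try:
        return yaml.safe_load(value)
    except yaml.YAMLError:
        return value


def _apply_override(data: dict, dotted: str, value) -> None:
    keys = dotted.split(".")
    node = data
    for k in keys[:-1]:
        node = node.setdefault(k, {})
        if not isinstance(node, dict):
            raise ValueError(f"cannot descend into non-mapping at {k!r}")
    node[keys[-1]] = value


def load_config(
    path: str | Path | None = None, overrides: dict[str, object] | None = None
) -> PipelineConfig:
    """Build a validated config: defaults < file values < overrides.

    ``overrides`` maps dotted paths (e.g. ``model.hidden_size``) to values;
    string values are YAML-coerced.  Unknown keys raise, listing the field.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError("config file must contain a mapping")
            data = loaded
    for dotted, value in (overrides or {}).items():
        if isinstance(value, str):
            value = _coerce(value)
        _apply_override(data, dotted, value)
    return PipelineConfig(**data)
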