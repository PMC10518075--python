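"""Run configuration: YAML/JSON config files validated with pydantic.

The same keys are accepted as CLI flags; flags override config-file values.
A static JSON Schema for this model ships as ``data/config.schema.json``.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator
from pydantic import ValidationError as PydanticValidationError


class ColorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    vmax: float | None = Field(None, gt=0)
    palette: str = "RdBu_r"
    na_color: str = "#bfbfbf"


class SizeConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    cap: float | None = Field(None, gt=0)
    rmin: float = Field(0.08, gt=0)
    rmax: float = Field(0.42, gt=0)
    transform: str = "area"

    @field_validator("transform")
    @classmethod
    def _check_transform(cls, v):
        if v not in ("area", "radius"):
            raise ValueError("size.transform must be 'area' or 'radius'")
        return v


class StyleConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pitch: float = Field(1.0, gt=0)
    font_size: float = Field(0.34, gt=0)
    title_size: float = Field(0.42, gt=0)
    label_rotation: float = 60.0
    max_label_chars: int = Field(22, ge=4)
    margins: float = Field(0.4, ge=0)
    title: str = ""
    footnote: str = ""
    missing_dot: bool = False
    unit_px: float = Field(22.0, gt=0)
    background: str = "#ffffff"


class ColumnMapConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    id: str = "id"
    estimate: str = "estimate"
    se: str = "se"
    p: str = "p"
    neglogp: str = "neglogp"


class RunConfig(BaseModel):
    """Everything one figure run needs; see the CLI for flag equivalents."""

    model_config = ConfigDict(extra="forbid")
    input: str | None = None
    template: str | None = None
    catalog: str | None = None
    keyspace: str = "nh_name"
    keymap: str | None = None
    columns: ColumnMapConfig = ColumnMapConfig()
    color: ColorConfig = ColorConfig()
    size: SizeConfig = SizeConfig()
    style: StyleConfig = StyleConfig()
    output: str | None = None
    format: str | None = None
    dpi: int = Field(96, gt=0)
    report: str | None = None


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML (or JSON) config file; None gives defaults.

    Schema violations raise ``ValueError`` listing every offending key.
    """
    if path is None:
        return RunConfig()
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    try:
        return RunConfig.model_validate(doc)
    except PydanticValidationError as e:
        raise ValueError(f"invalid config {path}:\n{e}") from None


def config_schema() -> dict:
    """The shipped JSON Schema for config files."""
    with resources.files("bubbleheatmap").joinpath(
            "data", "config.schema.json").open(encoding="utf-8") as fh:
        return json.load(fh)


def style_options(cfg: RunConfig):
    from .render import StyleOptions
    return StyleOptions(**cfg.style.model_dump())


def scale_options(cfg: RunConfig) -> dict:
    return {
        "vmax": cfg.color.vmax,
        "palette": cfg.color.palette,
        "na_color": cfg.color.na_color,
        "cap": cfg.size.cap,
        "rmin": cfg.size.rmin,
        "rmax": cfg.size.rmax,
        "transform": cfg.size.transform,
    }
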