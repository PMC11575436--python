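"""Run configuration: schema-validated YAML consumed by the command line.

The configuration is a nested key/value file validated before any
computation; unknown keys and type errors are reported with their field
path. CLI flags override config values; every run writes the resolved
configuration alongside its outputs so results are reproducible from the
emitted files alone.
"""

from __future__ import annotations

from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .familiarity import GridSpec
from .movement_kernel import KernelParams

__all__ = ["RunConfig", "ConfigError", "load_config", "resolved_yaml"]


class ConfigError(ValueError):
    """Configuration schema violation with field-level context."""


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class KernelBlock(_Model):
    gamma_shape: float = Field(gt=0)
    gamma_scale: float = Field(gt=0)
    vm_kappa: float = Field(ge=0)

    def to_params(self) -> KernelParams:
        return KernelParams(self.gamma_shape, self.gamma_scale, self.vm_kappa)


class GridBlock(_Model):
    x0: float
    y0: float
    res: float = Field(gt=0)
    n_rows: int = Field(ge=1)
    n_cols: int = Field(ge=1)

    def to_spec(self) -> GridSpec:
        return GridSpec(self.x0, self.y0, self.res, self.n_rows, self.n_cols)


class SimulateBlock(_Model):
    n_steps: int = Field(ge=1)
    memory_mode: Literal["none", "od_window", "tslv", "migration"] = "none"
    beta_w: dict[str, float] = Field(default_factory=dict)
    beta_f: dict[str, float] = Field(default_factory=dict)
    window: Optional[float] = None
    stride: int = Field(default=1, ge=1)
    bandwidth: Optional[float] = None
    default_tslv: float = Field(default=365.0, gt=0)
    n_candidates: int = Field(default=200, ge=10)
    fix_interval: float = Field(default=1.0, gt=0)
    start_xy: tuple[float, float] = (0.0, 0.0)
    start_bearing: Optional[float] = None
    seed: int = 0
    rasters: dict[str, str] = Field(default_factory=dict)
    familiarity_rasters: dict[str, str] = Field(default_factory=dict)
    previous_path: Optional[str] = None
    target_centroid: Optional[tuple[float, float]] = None


class CovariatesBlock(_Model):
    mode: Literal["tslv", "od_window", "stratified_od", "migration", "static"] = "tslv"
    n_avail: int = Field(default=20, ge=1)
    seed: int = 0
    burn_in: float = Field(default=0.0, ge=0)
    include_movement: bool = True
    window: Optional[float] = None
    stride: int = Field(default=1, ge=1)
    bandwidth: Optional[float] = None
    short_window: float = Field(default=3.0, gt=0)
    day_hours: tuple[float, float] = (6.0, 18.0)
    default_tslv: float = Field(default=365.0, gt=0)
    rasters: dict[str, str] = Field(default_factory=dict)
    familiarity_rasters: dict[str, str] = Field(default_factory=dict)
    previous_path: Optional[str] = None
    target_centroid: Optional[tuple[float, float]] = None

    @model_validator(mode="after")
    def _mode_requirements(self):
        # a missing bandwidth for the OD modes is resolved at run time as
        # max(grid resolution, 0.5 * median step length of the track)
        if self.mode == "migration" and self.previous_path is None and self.target_centroid is None:
            raise ValueError("covariates mode 'migration' needs previous_path and/or target_centroid")
        return self


class TermBlock(_Model):
    name: str
    quadratic: bool = False


class FitBlock(_Model):
    terms: list[TermBlock] = Field(default_factory=list)
    tol: float = Field(default=1e-8, gt=0)


class RunConfig(_Model):
    """Top-level run configuration; blocks are read per subcommand."""

    scenario: Optional[dict] = None  # free-form provenance block (name, seed, notes)
    kernel: Optional[KernelBlock] = None
    grid: Optional[GridBlock] = None
    simulate: Optional[SimulateBlock] = None
    covariates: Optional[CovariatesBlock] = None
    fit: Optional[FitBlock] = None


def load_config(path, overrides: Optional[dict] = None) -> RunConfig:
    """Load and validate a YAML config; ``overrides`` (dotted-path -> value)
    take precedence over file values (CLI flags beat config)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    for dotted, value in (overrides or {}).items():
        node = data
        *parents, leaf = dotted.split(".")
        for key in parents:
            node = node.setdefault(key, {})
        node[leaf] = value
    try:
        return RunConfig.model_validate(data)
    except ValidationError as e:
        lines = [f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in e.errors()]
        raise ConfigError(f"invalid configuration {path}:\n  " + "\n  ".join(lines)) from e


def resolved_yaml(cfg: RunConfig) -> str:
    """Canonical YAML of the resolved configuration (deterministic ordering)."""
    return yaml.safe_dump(cfg.model_dump(exclude_none=True), sort_keys=True)
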