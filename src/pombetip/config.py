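"""Run configuration: validated parameter sets mirroring the CLI flags.

Configurations are YAML mappings with a ``module`` selector and a
``params`` block validated against the module's schema; unknown keys are
rejected and out-of-range values produce errors naming the offending key.
"""
from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = [
    "ConfigError",
    "TipParams",
    "StabilityParams",
    "Cell2DParams",
    "PhaseParams",
    "FixtureParams",
    "RunConfig",
    "load_config",
    "save_config",
]


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TipParams(_Strict):
    """Axisymmetric tip-growth run (deterministic)."""

    sigma_lambda: float = Field(1.0, gt=0)
    nu: float = Field(0.5, ge=0.0, le=0.5)
    pressure: float = Field(0.85, gt=0)  # MPa
    modulus: float = Field(101.0, gt=0)  # MPa
    thickness: float = Field(0.2, gt=0)  # um
    gmax: float = Field(1.0, gt=0)  # 1/s
    signal_family: Literal["gaussian", "exponential_power"] = "gaussian"
    kurtosis: Optional[float] = None
    dt: Optional[float] = Field(None, gt=0)
    spacing: Optional[float] = Field(None, gt=0)
    tolerance: float = Field(1e-4, gt=0)


class StabilityParams(_Strict):
    form: Literal["constant", "linearized", "geometric_mt", "tabulated"] = "linearized"
    beta: float = 0.0
    gamma: float = 0.0
    alpha: float = Field(3.2, gt=0)
    w0: float = Field(3.2, gt=0)
    L0: Optional[float] = Field(None, gt=0)
    delta_mt: float = 0.0
    w_init: Optional[float] = Field(None, gt=0)
    generations: int = Field(11, ge=1)
    mode: Literal["monopolar", "bipolar"] = "monopolar"


class Cell2DParams(_Strict):
    dgz: float = Field(0.05, ge=0)  # um^2/min
    sigma_mt: float = Field(0.5, gt=0)  # um
    u0: float = Field(0.2, ge=0)  # um^2/min
    zones: int = Field(1, ge=1, le=2)
    length: float = Field(8.0, gt=0)  # um
    sigma_gz: Optional[float] = Field(None, gt=0)
    nu: float = Field(0.5, ge=0.0, le=0.5)
    generation_minutes: float = Field(150.0, gt=0)
    eps: float = Field(0.01, gt=0)
    frames: int = Field(0, ge=0)


class PhaseParams(Cell2DParams):
    dgz_grid: list[float] = [0.01, 0.046, 0.22, 1.0]
    sigma_mt_grid: list[float] = [0.5, 1.0, 2.0, 4.0]
    reps: int = Field(3, ge=1)


class FixtureParams(_Strict):
    kind: Literal[
        "initial_meridian_contour",
        "spherocylinder_outline",
        "mt_tip_sample",
        "sigma_mt_curve",
    ]
    params: dict = {}


_SCHEMAS = {
    "tip3d": TipParams,
    "stability": StabilityParams,
    "cell2d": Cell2DParams,
    "phase": PhaseParams,
    "fixture": FixtureParams,
}


class RunConfig(_Strict):
    """Top-level run description: module, parameters, seed, output."""

    module: Literal["tip3d", "stability", "cell2d", "phase", "fixture"]
    params: dict = {}
    seed: int = 0
    out: Optional[str] = None
    log_level: str = "INFO"

    def validated_params(self):
        try:
            return _SCHEMAS[self.module](**self.params)
        except ValidationError as err:
            raise ConfigError(_format_validation(err)) from err


def _format_validation(err: ValidationError) -> str:
    lines = []
    for e in err.errors():
        key = ".".join(str(p) for p in e["loc"]) or "<root>"
        lines.append(f"{key}: {e['msg']}")
    return "invalid configuration: " + "; ".join(lines)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        cfg = RunConfig(**raw)
    except ValidationError as err:
        raise ConfigError(_format_validation(err)) from err
    cfg.validated_params()  # fail early on the params block
    return cfg


def save_config(path, cfg: RunConfig) -> None:
    data = cfg.model_dump(exclude_none=True)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
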