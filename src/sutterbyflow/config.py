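"""Run configuration: YAML/JSON schema, defaults, and run metadata.

An empty config resolves to the baseline operating point used throughout
the profile and sweep studies.  Unknown keys are rejected with the
offending key path; angles accept ``"pi/3"``-style fraction strings.
"""

from __future__ import annotations

import hashlib
import json
import math
import re
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .geometry import ChannelGeometry, DimensionlessParams
from .hpm import HPMConfig

__all__ = ["RunConfig", "load_config", "dump_config", "parse_angle", "write_run_metadata"]

_PI_FRACTION = re.compile(r"^\s*(-?\d*\.?\d*)\s*\*?\s*pi\s*(?:/\s*(\d+\.?\d*))?\s*$")


def parse_angle(value) -> float:
    """Accept plain numbers or 'pi/3' / '2*pi/5' / '-pi' style strings (radians)."""
    if isinstance(value, (int, float)):
        return float(value)
    match = _PI_FRACTION.match(str(value))
    if not match:
        raise ValueError(f"cannot parse angle {value!r}; use radians or 'pi/n'")
    num = match.group(1)
    factor = float(num) if num not in ("", "-") else (-1.0 if num == "-" else 1.0)
    denom = float(match.group(2)) if match.group(2) else 1.0
    return factor * math.pi / denom


class _AngleMixin:
    @classmethod
    def _angle(cls, v):
        return parse_angle(v)


class ParamsBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    beta_F: float = 0.1
    M: float = Field(default=2.0, ge=0)
    beta_e: float = 0.5
    beta_i: float = 0.4
    G_R: float = 0.2
    G_C: float = 0.2
    Pr: float = Field(default=21.0, gt=0)
    N_T: float = 1.0
    N_B: float = Field(default=0.5, gt=0,
                       description="strictly positive: the species equation divides by N_B")
    E_C: float = 0.1
    Sc: float = Field(default=0.6, ge=0)
    K_R: float = Field(default=0.5, ge=0)
    Ra: float = 0.5
    Fr: float = Field(default=0.5, gt=0)
    Lambda: float = math.pi / 2

    _parse_Lambda = field_validator("Lambda", mode="before")(lambda v: parse_angle(v))

    def to_params(self) -> DimensionlessParams:
        return DimensionlessParams(**self.model_dump())


class GeometryBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    a: float = 0.3
    b: float = 0.3
    m: float = 0.2
    omega: float = math.pi / 2
    Theta: float = 1.4
    xi: float = 0.4
    t: float = 0.2

    _parse_omega = field_validator("omega", mode="before")(lambda v: parse_angle(v))

    def to_geometry(self) -> ChannelGeometry:
        return ChannelGeometry(a=self.a, b=self.b, m=self.m, omega=self.omega, Theta=self.Theta)


class SolverBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    order: int = Field(default=2, ge=0, le=2)
    bc_allocation: str = "full_at_zeroth"
    residual_grid_size: int = Field(default=201, ge=2)

    def to_hpm_config(self) -> HPMConfig:
        return HPMConfig(order=self.order, bc_allocation=self.bc_allocation,
                         residual_grid_size=self.residual_grid_size)


class ObservablesBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    eta_eval: str | float = "centre"
    nu_wall: str = "h2"
    nu_sign: int = 1
    quadrature_n: int = Field(default=64, ge=2)


class SweepBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    parameter: str
    values: list[float]


class AnnBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    restarts: int = Field(default=20, ge=1)
    max_iter: int = Field(default=200, ge=1)
    lambda0: float = Field(default=1e-3, gt=0)
    lambda_factor: float = Field(default=10.0, gt=1)
    grid: dict[str, list[float]] = Field(default_factory=dict)
    use_table: bool = False


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    params: ParamsBlock = Field(default_factory=ParamsBlock)
    geometry: GeometryBlock = Field(default_factory=GeometryBlock)
    solver: SolverBlock = Field(default_factory=SolverBlock)
    observables: ObservablesBlock = Field(default_factory=ObservablesBlock)
    sweeps: list[SweepBlock] = Field(default_factory=list)
    ann: AnnBlock = Field(default_factory=AnnBlock)
    output_dir: str = "runs"
    seed: int = 0
    log_level: str = "INFO"


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML/JSON config; missing file content -> defaults."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return RunConfig.model_validate(data)


def dump_config(config: RunConfig) -> str:
    """Resolved config as YAML (round-trips through load)."""
    return yaml.safe_dump(json.loads(config.model_dump_json()), sort_keys=False)


def write_run_metadata(outdir: str | Path, config: RunConfig, extra: dict | None = None) -> Path:
    """Write the resolved config, seed, package version and config hash.

    Every CLI run drops these next to its outputs so that reruns with an
    identical config are reproducible bit for bit on deterministic paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    resolved = dump_config(config)
    (outdir / "config.resolved.yaml").write_text(resolved)
    meta = {
        "package": "sutterbyflow",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(resolved.encode()).hexdigest(),
    }
    if extra:
        meta.update(extra)
    path = outdir / "run_metadata.json"
    path.write_text(json.dumps(meta, indent=2))
    return path
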