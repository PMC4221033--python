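"""Run configuration: a single YAML file drives everything.

The config has nested blocks (``grid``, ``flow``, ``scenario``, ``bio``,
``numerics``, ``output``) mapped onto the corresponding dataclasses; unknown
keys are rejected with an error naming the key, defaults fill everything
else, and a sha256 hash of the canonical config provides provenance for
output files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .bio import BioParams
from .flow import FlowConfig, make_jet_gyre_flow
from .grid import Grid
from .scenario import ScenarioConfig

__all__ = [
    "ConfigError",
    "GridConfig",
    "NumericsConfig",
    "OutputConfig",
    "RunConfig",
    "load_config",
    "config_hash",
    "build_grid",
    "build_flow",
]


class ConfigError(ValueError):
    """Invalid or unknown configuration entry."""


@dataclass
class GridConfig:
    """Reduced-domain mesh (defaults: 400x300 km at 10 km, 20 layers over
    300 m refined toward the surface; a 5 km run is nx=80, ny=60)."""

    nx: int = 40
    ny: int = 30
    nz: int = 20
    dx_km: float = 10.0
    dy_km: float = 10.0
    depth_m: float = 300.0
    surface_dz_m: float = 6.0


@dataclass
class NumericsConfig:
    dt_transport: float = 1800.0  #: transport step (s)
    dt_bio_days: float = 0.01     #: biology sub-step (days)
    kappa_h: float = 10.0         #: horizontal diffusivity (m^2/s)
    kappa_v: float = 1.0e-6       #: interior (minimum) vertical diffusivity (m^2/s)
    kappa_v_ml: float = 5.0e-3    #: turbulent mixed-layer vertical diffusivity (m^2/s)
    ml_depth_m: float = 40.0      #: mixed-layer depth of the diffusivity profile (m)
    ml_transition_m: float = 15.0  #: transition scale below the mixed layer (m)
    limiter: str = "superbee"
    sinking: bool = True


@dataclass
class OutputConfig:
    path: str = "alborun_run.nc"
    budget_csv: str = ""          #: default: alongside the NetCDF


@dataclass
class RunConfig:
    grid: GridConfig = field(default_factory=GridConfig)
    flow: FlowConfig = field(default_factory=FlowConfig)
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    bio: BioParams = field(default_factory=BioParams)
    numerics: NumericsConfig = field(default_factory=NumericsConfig)
    output: OutputConfig = field(default_factory=OutputConfig)
    flow_path: str = ""           #: optional external NetCDF flow field
    seed: int = 0


def _build(cls, data: dict, where: str):
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config section '{where}' must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    for key in data:
        if key not in names:
            raise ConfigError(f"unknown config key '{where}.{key}'")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in section '{where}': {exc}") from exc


_SECTIONS = {
    "grid": GridConfig,
    "flow": FlowConfig,
    "scenario": ScenarioConfig,
    "bio": BioParams,
    "numerics": NumericsConfig,
    "output": OutputConfig,
}


def config_from_dict(data: dict | None) -> RunConfig:
    data = dict(data or {})
    kwargs = {}
    for name, cls in _SECTIONS.items():
        kwargs[name] = _build(cls, data.pop(name, {}), name)
    flow_path = data.pop("flow_path", "")
    seed = data.pop("seed", 0)
    if data:
        raise ConfigError(f"unknown config key '{next(iter(data))}'")
    if not isinstance(seed, int):
        raise ConfigError("'seed' must be an integer")
    return RunConfig(flow_path=str(flow_path), seed=seed, **kwargs)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Read and validate a YAML config file (``None`` or empty file: all
    defaults)."""
    if path is None:
        return config_from_dict({})
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return config_from_dict(data)


def config_hash(cfg: RunConfig) -> str:
    """sha256 of the canonical JSON form of the full configuration."""
    canon = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=float)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def build_grid(gc: GridConfig) -> Grid:
    return Grid.regular(
        nx=gc.nx, ny=gc.ny, nz=gc.nz,
        dx=gc.dx_km * 1e3, dy=gc.dy_km * 1e3,
        depth=gc.depth_m, surface_dz=gc.surface_dz_m,
    )


def build_flow(cfg: RunConfig, g: Grid):
    """The run's flow field: external NetCDF if configured, else synthesized
    with the run seed."""
    if cfg.flow_path:
        from .output import read_flow

        return read_flow(cfg.flow_path)
    fc = dataclasses.replace(cfg.flow, seed=cfg.seed)
    return make_jet_gyre_flow(fc, g)
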