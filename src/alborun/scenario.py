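"""Biological initial conditions: the nutrient-starved winter setup.

Nitrate is zero throughout the upper layer (default 100 m) and ramps
linearly to a deep climatological value, so that any euphotic-layer
(0-75 m) production during a run is attributable to vertical transport
from below - the attribution logic of the frontal-fertilization
experiment.  Phytoplankton and zooplankton are seeded at trace
concentrations in the upper layer; detritus starts at zero.  Lateral
boundaries are closed for all biological fields (no nutrient import).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import Grid
from .transport import TracerFields

__all__ = ["ScenarioConfig", "initial_nitrate_profile", "initial_state"]


@dataclass
class ScenarioConfig:
    """Initial-state and run-reporting configuration (depths m, conc.
    mmol N m^-3, times days)."""

    euphotic_depth: float = 75.0    #: integration depth of the diagnostics
    nitrate_zero_depth: float = 100.0  #: nitrate is exactly 0 above this
    deep_nitrate: float = 8.0       #: deep climatological nitrate value
    nitrate_ramp_depth: float = 250.0  #: depth at which the deep value is reached
    seed_plankton: float = 0.05     #: initial P and Z concentration
    seed_depth: float = 100.0       #: depth extent of the plankton seed
    initial_detritus: float = 0.0
    run_days: float = 120.0
    snapshot_days: list = field(default_factory=lambda: [30.0, 60.0, 90.0, 120.0])

    def __post_init__(self) -> None:
        if self.nitrate_ramp_depth <= self.nitrate_zero_depth:
            raise ValueError("nitrate_ramp_depth must exceed nitrate_zero_depth")
        for name in ("deep_nitrate", "seed_plankton", "initial_detritus"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def initial_nitrate_profile(depths, cfg: ScenarioConfig) -> np.ndarray:
    """Nitrate at the given depths (m, sorted, positive down): exactly zero
    above ``nitrate_zero_depth``, linear ramp to ``deep_nitrate`` at
    ``nitrate_ramp_depth``, constant below."""
    z = np.asarray(depths, dtype=float)
    if np.any(np.diff(z) < 0):
        raise ValueError("depths must be sorted increasing")
    frac = (z - cfg.nitrate_zero_depth) / (cfg.nitrate_ramp_depth - cfg.nitrate_zero_depth)
    return cfg.deep_nitrate * np.clip(frac, 0.0, 1.0)


def initial_state(g: Grid, cfg: ScenarioConfig) -> TracerFields:
    """The initial tracer fields on the grid (zero on land)."""
    state = TracerFields.zeros(g)
    N_prof = initial_nitrate_profile(g.z_mid, cfg)
    state.N[:] = N_prof[:, None, None]
    seed_layers = g.z_mid <= cfg.seed_depth
    state.P[seed_layers] = cfg.seed_plankton
    state.Z[seed_layers] = cfg.seed_plankton
    state.D[:] = cfg.initial_detritus
    for _, C in state.items():
        C[~g.mask] = 0.0
    return state
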