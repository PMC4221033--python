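"""Observables computed from run output: depth integrals, transects,
surface fields, region masks, and the nitrogen budget.

The reporting conventions follow the frontal-production analysis: euphotic
inventories are 0-75 m depth integrals (mmol N m^-2); "plankton biomass" is
phytoplankton plus zooplankton (detritus excluded); sections are taken along
a polyline that crosses the western gyre diagonally and then runs zonally
across the eastern gyre.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .flow import FlowConfig
from .grid import Grid
from .transport import FlowField, TracerFields

__all__ = [
    "TransectSpec",
    "depth_integrate",
    "extract_transect",
    "plankton_biomass",
    "nitrogen_budget",
    "jet_core_mask",
    "gyre_interior_mask",
    "default_transect",
    "plot_map",
    "plot_section",
]


@dataclass
class TransectSpec:
    """Sampling polyline in domain coordinates (km)."""

    vertices: list  #: [[x_km, y_km], ...], at least 2
    interval: float = 5.0  #: sampling interval along the line (km)

    def __post_init__(self) -> None:
        if len(self.vertices) < 2:
            raise ValueError("a transect needs at least 2 vertices")
        if self.interval <= 0:
            raise ValueError("sampling interval must be positive")


def depth_integrate(field: np.ndarray, g: Grid, z_max: float) -> np.ndarray:
    """Depth integral from the surface to ``z_max`` (mmol N m^-2 map).

    The layer straddling ``z_max`` contributes its top fraction.
    """
    if z_max > g.z_w[-1]:
        raise ValueError(f"z_max={z_max} m exceeds the water column ({g.z_w[-1]} m)")
    frac = np.clip((z_max - g.z_w[:-1]) / g.dz, 0.0, 1.0)
    weights = frac * g.dz
    return np.tensordot(weights, field, axes=(0, 0))


def extract_transect(field: np.ndarray, g: Grid, t: TransectSpec):
    """Sample a 3-D field along the polyline at all depths.

    Returns ``(distance_km, section)`` with ``section`` of shape
    ``(nz, n_points)``; horizontal sampling is bilinear (exact for fields
    linear in x and y).
    """
    verts = np.asarray(t.vertices, dtype=float) * 1e3
    Lx, Ly = g.nx * g.dx, g.ny * g.dy
    if np.any(verts[:, 0] < 0) or np.any(verts[:, 0] > Lx) or np.any(verts[:, 1] < 0) or np.any(verts[:, 1] > Ly):
        raise ValueError("transect vertex outside the domain")

    seg = np.diff(verts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    if total == 0.0:
        dist = np.array([0.0])
    else:
        dist = np.arange(0.0, total + 0.5 * t.interval * 1e3, t.interval * 1e3)
        dist = dist[dist <= total]
        if dist[-1] < total:
            dist = np.append(dist, total)
    xs = np.interp(dist, cum, verts[:, 0])
    ys = np.interp(dist, cum, verts[:, 1])

    xc, yc = g.x_centers(), g.y_centers()
    # clip to the cell-centre hull: constant extrapolation in the edge half-cell
    xi = np.clip(xs, xc[0], xc[-1])
    yi = np.clip(ys, yc[0], yc[-1])
    pts = np.column_stack([yi, xi])
    section = np.empty((g.nz, len(dist)))
    for k in range(g.nz):
        interp = RegularGridInterpolator((yc, xc), field[k], method="linear")
        section[k] = interp(pts)
    return dist / 1e3, section


def plankton_biomass(fields: TracerFields) -> np.ndarray:
    """Plankton biomass P + Z (detritus excluded by definition)."""
    return fields.P + fields.Z


def nitrogen_budget(run, g: Grid) -> pd.DataFrame:
    """Budget series with closure residuals.

    Columns: inventories (mmol), cumulative bottom export and closure loss,
    and the residual (inventory change + losses), absolute and relative to
    the initial inventory.
    """
    b = run.budget.copy()
    total0 = b["total"].iloc[0]
    resid = (b["total"] - total0) + b["cum_bottom_export"] + b["cum_closure_loss"]
    b["residual"] = resid
    b["residual_rel"] = np.abs(resid) / total0 if total0 > 0 else np.abs(resid)
    return b


def jet_core_mask(flow: FlowField, g: Grid, speed_threshold: float = 0.3) -> np.ndarray:
    """Columns whose surface speed exceeds the threshold (default 0.3 m/s)."""
    uc = 0.5 * (flow.u[0, :, 1:] + flow.u[0, :, :-1])
    vc = 0.5 * (flow.v[0, 1:, :] + flow.v[0, :-1, :])
    return np.hypot(uc, vc) > speed_threshold


def gyre_interior_mask(cfg: FlowConfig, g: Grid, radius_fraction: float = 0.5) -> np.ndarray:
    """Columns within ``radius_fraction`` of a gyre radius of either
    configured gyre centre."""
    Xc, Yc = np.meshgrid(g.x_centers(), g.y_centers())
    mask = np.zeros((g.ny, g.nx), dtype=bool)
    for (cx, cy), R in zip(cfg.gyre_centers, cfg.gyre_radii):
        r = np.hypot(Xc - cx * 1e3, Yc - cy * 1e3)
        mask |= r < radius_fraction * R * 1e3
    return mask


def plot_map(field2d: np.ndarray, g: Grid, path, title: str = "", units: str = "") -> None:
    """Render a horizontal map to ``path`` (presentation only; all
    quantitative output goes through the numeric diagnostics)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    pm = ax.pcolormesh(g.x_centers() / 1e3, g.y_centers() / 1e3, field2d, shading="auto")
    fig.colorbar(pm, ax=ax, label=units)
    ax.set_xlabel("x (km)")
    ax.set_ylabel("y (km)")
    ax.set_title(title)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_section(dist_km: np.ndarray, section: np.ndarray, g: Grid, path,
                 title: str = "", units: str = "") -> None:
    """Render a distance-depth section (presentation only)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    pm = ax.pcolormesh(dist_km, g.z_mid, section, shading="auto")
    fig.colorbar(pm, ax=ax, label=units)
    ax.invert_yaxis()
    ax.set_xlabel("distance along transect (km)")
    ax.set_ylabel("depth (m)")
    ax.set_title(title)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def default_transect(cfg: FlowConfig, g: Grid, interval: float = 5.0) -> TransectSpec:
    """The reporting transect: diagonally across the western gyre, then
    zonally across the eastern gyre toward the basin exit."""
    (wx, wy), (ex, ey) = cfg.gyre_centers[0], cfg.gyre_centers[1]
    rw = cfg.gyre_radii[0]
    Lx = g.nx * g.dx / 1e3
    x_end = min(Lx - g.dx / 1e3, ex + cfg.gyre_radii[1] + 30.0)
    verts = [
        [max(g.dx / 1e3, wx - rw), max(g.dy / 1e3, wy - rw)],
        [wx + 0.7 * rw, wy + 0.7 * rw],
        [wx + rw, ey],
        [x_end, ey],
    ]
    return TransectSpec(vertices=verts, interval=interval)
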