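"""Synthetic divergence-free jet / double-gyre flow fields.

The Alboran-like circulation is emulated, not solved: a streamfunction builds
the non-divergent horizontal flow (an eastward meandering jet wrapped around
two anticyclonic gyres, tapering eastward and decaying with depth), and an
analytic velocity potential adds localized divergent cells on the jet flanks
(surface divergence over upwelling sites, convergence over downwelling).
The vertical velocity is then obtained by discrete vertical integration of
the horizontal divergence from the rigid lid, so every generated field
satisfies discrete continuity cell-by-cell to rounding error, with zero
normal flow through the walls, the surface and the bottom.

Amplitudes are calibrated so the maximum surface speed and the maximum
vertical speed at the configured depth hit their targets (defaults: the
observed 0.7 m s^-1 inflow jet and 50 m day^-1 ageostrophic cells at 50 m).

Distances in ``FlowConfig`` are kilometres; speeds m s^-1; vertical
velocities m day^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import Grid
from .transport import FlowField, SECONDS_PER_DAY

__all__ = [
    "FlowConfig",
    "make_jet_gyre_flow",
    "relative_vorticity",
    "fixture_flows",
    "F_CORIOLIS",
]

#: f-plane Coriolis parameter at 36 N (s^-1)
F_CORIOLIS = 8.6e-5


@dataclass
class FlowConfig:
    """Geometry and calibration targets of the synthetic circulation.

    Distances in km, speeds in m/s, vertical velocities in m/day.
    """

    jet_speed: float = 0.7          #: target max surface speed (m/s)
    jet_width: float = 18.0         #: nominal jet width (km)
    jet_y0: float = 150.0           #: jet axis at the inflow (km)
    meander_amplitude: float = 45.0  #: meander amplitude (km)
    meander_wavelength: float = 180.0  #: meander wavelength (km)
    taper_x: float = 225.0          #: speed-halving longitude (EAG, km)
    #: anticyclone centres sit inside the meander loops (under the crests),
    #: so the jet wraps around them tangentially and their interiors stay
    #: away from the jet axis
    gyre_centers: list = field(default_factory=lambda: [[45.0, 130.0], [225.0, 130.0]])
    gyre_radii: list = field(default_factory=lambda: [55.0, 50.0])
    gyre_speeds: list = field(default_factory=lambda: [0.4, 0.25])  #: peak speeds (m/s)
    z_decay: float = 50.0           #: vertical decay of horizontal flow (m)
    w_max: float = 50.0             #: target max |w| (m/day)
    w_depth: float = 50.0           #: depth of the |w| maximum (m)
    w_cell_radius: float = 15.0     #: velocity-potential cell radius (km)
    #: optional weak downwelling over the gyre interiors (m/day).  Off by
    #: default: in a prescribed flow the accompanying surface convergence
    #: imports rim water into the cores, the opposite of the isopycnal
    #: isolation it is meant to mimic (see docs/methods.md).
    gyre_w: float = 0.0
    edge_margin: float = 40.0       #: boundary taper width (km)
    perturbation: float = 0.0       #: random streamfunction noise (rel.)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jet_width <= 0 or self.meander_wavelength <= 0:
            raise ValueError("jet width and wavelength must be positive")
        if self.jet_speed < 0 or self.w_max < 0:
            raise ValueError("speeds must be >= 0")
        if any(r <= 0 for r in self.gyre_radii):
            raise ValueError("gyre radii must be positive")


def _ramp(x: np.ndarray, L: float, margin: float) -> np.ndarray:
    """Cosine taper from 0 at the walls to 1 beyond ``margin``."""
    r = np.ones_like(x)
    m = max(margin, 1e-9)
    left = x < m
    right = x > L - m
    r[left] = 0.5 * (1 - np.cos(np.pi * x[left] / m))
    r[right] = 0.5 * (1 - np.cos(np.pi * (L - x[right]) / m))
    return r


def _psi_to_faces(psi: np.ndarray, g: Grid):
    """Exactly non-divergent face velocities from a corner streamfunction."""
    u = -(psi[1:, :] - psi[:-1, :]) / g.dy  # (ny, nx+1)
    v = (psi[:, 1:] - psi[:, :-1]) / g.dx   # (ny+1, nx)
    return u, v


def _jet_axis(x_m: np.ndarray, cfg: FlowConfig) -> np.ndarray:
    return cfg.jet_y0 * 1e3 + cfg.meander_amplitude * 1e3 * np.sin(
        2 * np.pi * x_m / (cfg.meander_wavelength * 1e3)
    )


def _surface_streamfunction(cfg: FlowConfig, g: Grid) -> np.ndarray:
    """Unit-scale streamfunction at cell corners (ny+1, nx+1)."""
    x = np.arange(g.nx + 1) * g.dx
    y = np.arange(g.ny + 1) * g.dy
    X, Y = np.meshgrid(x, y)

    a = cfg.jet_width * 1e3 / 1.7627  # sech^2 FWHM equals the nominal width
    yc = _jet_axis(X, cfg)
    taper = 2.0 ** (-X / (cfg.taper_x * 1e3))
    psi = -cfg.jet_speed * a * np.tanh((Y - yc) / a) * taper

    for (cx, cy), R_km, spd in zip(cfg.gyre_centers, cfg.gyre_radii, cfg.gyre_speeds):
        R = R_km * 1e3
        r2 = (X - cx * 1e3) ** 2 + (Y - cy * 1e3) ** 2
        # positive amplitude -> anticyclonic; peak azimuthal speed spd at r=R
        psi += spd * R * np.exp(0.5) * np.exp(-r2 / (2 * R**2))

    if cfg.perturbation > 0:
        rng = np.random.default_rng(cfg.seed)
        Lx, Ly = (g.nx) * g.dx, (g.ny) * g.dy
        noise = np.zeros_like(psi)
        for _ in range(8):
            kx = rng.integers(1, 5) * 2 * np.pi / Lx
            ky = rng.integers(1, 5) * 2 * np.pi / Ly
            ph1, ph2 = rng.uniform(0, 2 * np.pi, 2)
            noise += np.sin(kx * X + ph1) * np.sin(ky * Y + ph2)
        scale = cfg.perturbation * cfg.jet_speed * cfg.jet_width * 1e3
        psi += scale * noise / 8.0

    Lx, Ly = g.nx * g.dx, g.ny * g.dy
    window = _ramp(X, Lx, cfg.edge_margin * 1e3) * _ramp(Y, Ly, cfg.edge_margin * 1e3)
    return psi * window


def _cell_sites(cfg: FlowConfig, g: Grid):
    """(x, y, sign) of the ageostrophic cells: upwelling (+w, sign -1 in the
    potential) on the anticyclonic (south) flank at trough-to-crest segments,
    downwelling on the cyclonic (north) flank at crest-to-trough segments."""
    lam = cfg.meander_wavelength * 1e3
    Lx = g.nx * g.dx
    margin = cfg.edge_margin * 1e3
    off = 0.5 * cfg.jet_width * 1e3
    sites = []
    # rising (trough->crest) segment midpoints: x = k*lam; falling: lam/2 + k*lam
    k = 0
    while k * lam / 2 <= Lx:
        xc = k * lam / 2
        if margin < xc < Lx - margin:
            rising = k % 2 == 0
            yc = float(_jet_axis(np.array(xc), cfg))
            if rising:
                sites.append((xc, yc - off, -1.0))  # surface divergence -> upwelling
            else:
                sites.append((xc, yc + off, +1.0))
        k += 1
    return sites


def _w_shape(cfg: FlowConfig, g: Grid):
    """Vertical profiles: G at interfaces (target w shape, 0 at lid and
    bottom) and s = dG/dz per layer (shape of the divergent horizontal
    flow)."""
    zw = g.z_w
    H = zw[-1]
    z0 = cfg.w_depth
    G = (zw / z0) * np.exp(1.0 - zw / z0)
    G = G - G[-1] * zw / H  # force exactly zero bottom flow
    s = np.diff(G) / np.diff(zw)
    return G, s


def make_jet_gyre_flow(cfg: FlowConfig, g: Grid) -> FlowField:
    """Construct the calibrated, discretely divergence-free jet-gyre flow.

    Requires the grid to resolve the jet core (>= 3 cells across its
    dynamical span) and a flat-bottom (column-wise) mask.
    """
    a = cfg.jet_width * 1e3 / 1.7627
    if 4 * a < 3 * min(g.dx, g.dy):
        raise ValueError(
            f"grid too coarse to resolve the jet: span {4 * a / 1e3:.0f} km "
            f"needs >= 3 cells at dx={g.dx / 1e3:.0f} km"
        )
    if not np.all(g.mask == g.mask[:1]):
        raise ValueError("flow synthesis requires a column-wise (flat-bottom) mask")

    nz, ny, nx = g.nz, g.ny, g.nx
    h = np.exp(-g.z_mid / cfg.z_decay)  # vertical decay of the psi part

    # --- non-divergent part ------------------------------------------------
    psi = _surface_streamfunction(cfg, g)
    u_psi2d, v_psi2d = _psi_to_faces(psi, g)
    u_psi = u_psi2d[None, :, :] * h[:, None, None]
    v_psi = v_psi2d[None, :, :] * h[:, None, None]

    # --- divergent part ----------------------------------------------------
    xc = g.x_centers()
    yc = g.y_centers()
    Xc, Yc = np.meshgrid(xc, yc)
    phi = np.zeros((ny, nx))
    taper_x = cfg.taper_x * 1e3
    for sx, sy, sign in _cell_sites(cfg, g):
        sig = cfg.w_cell_radius * 1e3
        r2 = (Xc - sx) ** 2 + (Yc - sy) ** 2
        phi += sign * 2.0 ** (-sx / taper_x) * np.exp(-r2 / (2 * sig**2))

    # weak quasigeostrophic downwelling over the anticyclone interiors
    phi_gyre = np.zeros((ny, nx))
    for (cx, cy), R_km in zip(cfg.gyre_centers, cfg.gyre_radii):
        sig_g = 0.5 * R_km * 1e3
        r2 = (Xc - cx * 1e3) ** 2 + (Yc - cy * 1e3) ** 2
        phi_gyre += np.exp(-r2 / (2 * sig_g**2))  # +: convergence -> downwelling

    _, s_prof = _w_shape(cfg, g)

    def _phi_to_faces(phi2d):
        u = np.zeros((nz, ny, nx + 1))
        v = np.zeros((nz, ny + 1, nx))
        u[:, :, 1:-1] = ((phi2d[:, 1:] - phi2d[:, :-1]) / g.dx)[None] * s_prof[:, None, None]
        v[:, 1:-1, :] = ((phi2d[1:, :] - phi2d[:-1, :]) / g.dy)[None] * s_prof[:, None, None]
        return u, v

    def _w_from(u, v):
        div_h = (np.diff(u, axis=2) / g.dx + np.diff(v, axis=1) / g.dy)
        w = np.zeros((nz + 1, ny, nx))
        w[1:] = np.cumsum(div_h * g.dz[:, None, None], axis=0)
        return w

    # calibrate |w| at the interface closest to the configured depth:
    # the frontal cells hit w_max there, the gyre interiors gyre_w (downward)
    k_w = int(np.argmin(np.abs(g.z_w - cfg.w_depth)))
    u_phi = np.zeros((nz, ny, nx + 1))
    v_phi = np.zeros((nz, ny + 1, nx))
    if cfg.w_max > 0:
        u_jet, v_jet = _phi_to_faces(phi)
        w_jet = _w_from(u_jet, v_jet)
        c_jet = (cfg.w_max / SECONDS_PER_DAY) / float(np.max(np.abs(w_jet[k_w])))
        u_g = v_g = None
        c_g = 0.0
        if cfg.gyre_w > 0:
            u_g, v_g = _phi_to_faces(phi_gyre)
            w_g = _w_from(u_g, v_g)
            c_g = (cfg.gyre_w / SECONDS_PER_DAY) / float(np.max(np.abs(w_g[k_w])))
        # a few fixed-point passes keep the combined |w| maximum on target
        for _ in range(5):
            u_phi = c_jet * u_jet + (c_g * u_g if u_g is not None else 0.0)
            v_phi = c_jet * v_jet + (c_g * v_g if v_g is not None else 0.0)
            w_tot = _w_from(u_phi, v_phi)
            peak = float(np.max(np.abs(w_tot[k_w])))
            if peak > 0:
                c_jet *= (cfg.w_max / SECONDS_PER_DAY) / peak

    # calibrate the max surface speed of the combined field
    alpha = 0.0
    if cfg.jet_speed > 0:
        base = max(np.abs(u_psi).max(), np.abs(v_psi).max())
        alpha = cfg.jet_speed / base if base > 0 else 0.0
        for _ in range(30):
            spd = max(
                np.abs(alpha * u_psi + u_phi).max(),
                np.abs(alpha * v_psi + v_phi).max(),
            )
            if spd == 0:
                break
            alpha *= cfg.jet_speed / spd
    u = alpha * u_psi + u_phi
    v = alpha * v_psi + v_phi

    flow = FlowField(u=u, v=v, w=np.zeros((nz + 1, ny, nx))).masked(g)
    flow.w[:] = _w_from(flow.u, flow.v)
    flow.w[np.abs(flow.w) < 1e-300] = 0.0
    return flow


def relative_vorticity(flow: FlowField, g: Grid, f: float = F_CORIOLIS) -> np.ndarray:
    """Surface relative vorticity (dv/dx - du/dy)/f at cell centres (ny, nx),
    from centred differences of the face-averaged velocities."""
    uc = 0.5 * (flow.u[0, :, 1:] + flow.u[0, :, :-1])
    vc = 0.5 * (flow.v[0, 1:, :] + flow.v[0, :-1, :])
    dvdx = np.gradient(vc, g.dx, axis=1)
    dudy = np.gradient(uc, g.dy, axis=0)
    return (dvdx - dudy) / f


def fixture_flows(g: Grid) -> dict[str, FlowField]:
    """Simple analytic flows for transport tests: zero flow, a uniform 1-D
    channel, solid-body rotation, and a single Gaussian gyre."""
    nz, ny, nx = g.nz, g.ny, g.nx
    zero = FlowField(
        u=np.zeros((nz, ny, nx + 1)),
        v=np.zeros((nz, ny + 1, nx)),
        w=np.zeros((nz + 1, ny, nx)),
    )

    channel = FlowField(
        u=np.full((nz, ny, nx + 1), 0.1),
        v=np.zeros((nz, ny + 1, nx)),
        w=np.zeros((nz + 1, ny, nx)),
    )

    x = np.arange(nx + 1) * g.dx
    y = np.arange(ny + 1) * g.dy
    X, Y = np.meshgrid(x, y)
    cx, cy = 0.5 * nx * g.dx, 0.5 * ny * g.dy
    omega = 1e-5
    psi_rot = 0.5 * omega * ((X - cx) ** 2 + (Y - cy) ** 2)
    u2, v2 = _psi_to_faces(psi_rot, g)
    rotation = FlowField(
        u=np.broadcast_to(u2, (nz,) + u2.shape).copy(),
        v=np.broadcast_to(v2, (nz,) + v2.shape).copy(),
        w=np.zeros((nz + 1, ny, nx)),
    )

    R = 0.2 * min(nx * g.dx, ny * g.dy)
    psi_gyre = 0.3 * R * np.exp(0.5) * np.exp(
        -((X - cx) ** 2 + (Y - cy) ** 2) / (2 * R**2)
    )
    # close the walls exactly so the gyre serves closed-domain conservation tests
    psi_gyre *= _ramp(X, nx * g.dx, 0.15 * nx * g.dx) * _ramp(Y, ny * g.dy, 0.15 * ny * g.dy)
    u3, v3 = _psi_to_faces(psi_gyre, g)
    gyre = FlowField(
        u=np.broadcast_to(u3, (nz,) + u3.shape).copy(),
        v=np.broadcast_to(v3, (nz,) + v3.shape).copy(),
        w=np.zeros((nz + 1, ny, nx)),
    )

    return {"zero": zero, "channel": channel, "rotation": rotation, "gyre": gyre}
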