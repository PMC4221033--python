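"""Conservative tracer transport on the C-grid: advection, diffusion, sinking.

The advection operator is a finite-volume flux-form scheme: first-order upwind
fluxes plus a superbee-limited second-order antidiffusive correction, clipped
by a Zalesak flux-corrected-transport (FCT) limiter.  The unsplit flux-form
update makes three properties exact on a closed domain, independent of the
flow: total mass conservation, preservation of a uniform tracer under any
discretely divergence-free flow, and no new extrema (hence positivity).

Diffusion is explicit flux-form with no-flux boundaries; detritus sinking is
an upwind vertical flux with the concentration-dependent speed of
:func:`alborun.bio.sinking_velocity`, accumulating the export through the
sea floor for the nitrogen budget.

Velocities are in m s^-1 (``w`` positive upward); time steps in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import bio
from .grid import Grid

__all__ = [
    "FlowField",
    "TracerFields",
    "CFLError",
    "StabilityError",
    "advect",
    "diffuse",
    "sink",
]

SECONDS_PER_DAY = 86400.0


class CFLError(ValueError):
    """Advective CFL limit exceeded; reduce dt or sub-step the update."""


class StabilityError(ValueError):
    """Explicit diffusion stability limit exceeded; reduce dt or sub-step."""


@dataclass
class FlowField:
    """C-grid velocity field.

    u : (nz, ny, nx+1) m/s on x-faces; v : (nz, ny+1, nx) m/s on y-faces;
    w : (nz+1, ny, nx) m/s on z-interfaces, positive upward, w[0] is the
    surface (rigid lid, normally 0).
    """

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        nz, ny, nxp = self.u.shape
        if self.v.shape != (nz, ny + 1, nxp - 1) or self.w.shape != (nz + 1, ny, nxp - 1):
            raise ValueError("inconsistent staggered array shapes")

    @property
    def shape(self) -> tuple[int, int, int]:
        nz, ny, nxp = self.u.shape
        return nz, ny, nxp - 1

    def masked(self, g: Grid) -> "FlowField":
        """Copy with zero normal flow through land faces, domain walls,
        surface and bottom."""
        u, v, w = self.u.copy(), self.v.copy(), self.w.copy()
        m = g.mask
        u[:, :, 0] = 0.0
        u[:, :, -1] = 0.0
        u[:, :, 1:-1] *= m[:, :, :-1] & m[:, :, 1:]
        v[:, 0, :] = 0.0
        v[:, -1, :] = 0.0
        v[:, 1:-1, :] *= m[:, :-1, :] & m[:, 1:, :]
        w[0] = 0.0
        w[-1] = 0.0
        w[1:-1] *= m[:-1] & m[1:]
        return FlowField(u=u, v=v, w=w)

    def volume_fluxes(self, g: Grid):
        """Face volume fluxes (m^3/s), positive in the +index direction of
        each axis; the vertical flux is positive *downward* (+k)."""
        dz = g.dz
        Qx = self.u * (g.dy * dz)[:, None, None]
        Qy = self.v * (g.dx * dz)[:, None, None]
        Qz = -self.w * (g.dx * g.dy)  # w positive up -> downward flux is -w
        return Qx, Qy, Qz

    def divergence(self, g: Grid) -> np.ndarray:
        """Per-cell net volume outflow divided by cell volume (s^-1)."""
        Qx, Qy, Qz = self.volume_fluxes(g)
        net = (
            np.diff(Qx, axis=2)
            + np.diff(Qy, axis=1)
            + np.diff(Qz, axis=0)
        )
        return net / np.broadcast_to(g.cell_volume, net.shape)

    def max_speed(self) -> float:
        """Maximum horizontal speed from face magnitudes (m/s)."""
        return float(max(np.abs(self.u).max(), np.abs(self.v).max()))


@dataclass
class TracerFields:
    """The four tracer concentration fields (nz, ny, nx), mmol N m^-3."""

    N: np.ndarray
    P: np.ndarray
    Z: np.ndarray
    D: np.ndarray

    _NAMES = ("N", "P", "Z", "D")

    def __post_init__(self) -> None:
        shapes = {getattr(self, k).shape for k in self._NAMES}
        if len(shapes) != 1:
            raise ValueError("tracer fields must share one shape")

    @classmethod
    def zeros(cls, g: Grid) -> "TracerFields":
        shape = (g.nz, g.ny, g.nx)
        return cls(*(np.zeros(shape) for _ in cls._NAMES))

    def items(self):
        return [(k, getattr(self, k)) for k in self._NAMES]

    def copy(self) -> "TracerFields":
        return TracerFields(*(getattr(self, k).copy() for k in self._NAMES))

    def total_nitrogen(self, g: Grid) -> float:
        """Volume-integrated N+P+Z+D (mmol)."""
        return sum(g.total_mass(C) for _, C in self.items())


def _superbee(r: np.ndarray) -> np.ndarray:
    return np.maximum(0.0, np.maximum(np.minimum(2.0 * r, 1.0), np.minimum(r, 2.0)))


def _minmod(r: np.ndarray) -> np.ndarray:
    return np.maximum(0.0, np.minimum(r, 1.0))


_LIMITERS = {"superbee": _superbee, "minmod": _minmod}


def _axis_fluxes(C, Q, V, dt, limiter):
    """Low-order and limited antidiffusive fluxes along the last axis.

    C, V: (..., n); Q: (..., n+1) with zero boundary faces.
    Returns (F_low, A), both (..., n+1) with zero boundary entries.
    """
    CL, CR = C[..., :-1], C[..., 1:]
    Qi = Q[..., 1:-1]
    up = Qi >= 0.0
    Cup = np.where(up, CL, CR)
    F_low_i = Qi * Cup

    dC = CR - CL
    zeros = np.zeros_like(dC[..., :1])
    dC_left = np.concatenate([zeros, dC[..., :-1]], axis=-1)
    dC_right = np.concatenate([dC[..., 1:], zeros], axis=-1)
    num = np.where(up, dC_left, dC_right)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(dC != 0.0, num / np.where(dC != 0.0, dC, 1.0), 0.0)
    phi = limiter(r)
    V_up = np.where(up, V[..., :-1], V[..., 1:])
    nu = np.abs(Qi) * dt / V_up
    sgn = np.where(up, 1.0, -1.0)
    A_i = Qi * 0.5 * phi * (1.0 - nu) * dC * sgn

    pad = np.zeros(np.broadcast_shapes(F_low_i.shape, A_i.shape)[:-1] + (1,))
    F_low = np.concatenate([pad, np.broadcast_to(F_low_i, pad.shape[:-1] + F_low_i.shape[-1:]), pad], axis=-1)
    A = np.concatenate([pad, np.broadcast_to(A_i, pad.shape[:-1] + A_i.shape[-1:]), pad], axis=-1)
    return F_low, A


def _sl(a, axis, s):
    """Slice array ``a`` with ``s`` along (possibly negative) ``axis``."""
    idx = [slice(None)] * a.ndim
    idx[axis] = s
    return a[tuple(idx)]


def _neighbor_extrema(field, mask):
    """Per-cell min/max over the cell and its sea face-neighbours (the grid
    occupies the trailing three axes)."""
    big = np.where(mask, field, -np.inf)
    small = np.where(mask, field, np.inf)
    fmax = big.copy()
    fmin = small.copy()
    for axis in (-3, -2, -1):
        for shift in (1, -1):
            fmax = np.maximum(fmax, np.roll(_edge_pad(big, axis, shift, -np.inf), shift, axis=axis))
            fmin = np.minimum(fmin, np.roll(_edge_pad(small, axis, shift, np.inf), shift, axis=axis))
    # cells with no sea neighbour keep their own value
    fmax = np.where(np.isfinite(fmax), fmax, field)
    fmin = np.where(np.isfinite(fmin), fmin, field)
    return fmin, fmax


def _edge_pad(a, axis, shift, fill):
    """Neutralize the wrap-around slice of np.roll (closed boundaries)."""
    out = a.copy()
    idx = [slice(None)] * a.ndim
    idx[axis] = -1 if shift == 1 else 0
    out[tuple(idx)] = fill
    return out


def advect(C: np.ndarray, flow: FlowField, g: Grid, dt: float, limiter: str = "superbee") -> np.ndarray:
    """One conservative FCT advection step of tracer ``C`` (dt in seconds).

    ``C`` may carry leading batch axes (e.g. all four tracers stacked); the
    grid occupies the trailing three axes.  Raises :class:`CFLError` when
    the total outflow CFL number of any cell exceeds 1; callers should
    sub-step.
    """
    lim = _LIMITERS[limiter]
    C = np.where(g.mask, C, 0.0)
    V = np.broadcast_to(g.cell_volume, C.shape[-3:])
    Qx, Qy, Qz = flow.volume_fluxes(g)

    outflow = (
        np.maximum(Qx[:, :, 1:], 0.0) + np.maximum(-Qx[:, :, :-1], 0.0)
        + np.maximum(Qy[:, 1:, :], 0.0) + np.maximum(-Qy[:, :-1, :], 0.0)
        + np.maximum(Qz[1:, :, :], 0.0) + np.maximum(-Qz[:-1, :, :], 0.0)
    )
    cfl = float(np.max(outflow * dt / V))
    if cfl > 1.0:
        raise CFLError(
            f"advective CFL {cfl:.3f} > 1; sub-step the update (use a smaller dt)"
        )

    flows_axes = [(Qz, -3), (Qy, -2), (Qx, -1)]
    F_lows, As = [], []
    for Q, axis in flows_axes:
        Cm = np.moveaxis(C, axis, -1)
        Vm = np.moveaxis(V, axis, -1)
        Qm = np.moveaxis(Q, axis, -1)
        F_low, A = _axis_fluxes(Cm, Qm, Vm, dt, lim)
        F_lows.append(np.moveaxis(F_low, -1, axis))
        As.append(np.moveaxis(A, -1, axis))

    def _div(fluxes):
        return (
            np.diff(fluxes[0], axis=-3)
            + np.diff(fluxes[1], axis=-2)
            + np.diff(fluxes[2], axis=-1)
        )

    C_td = C - dt * _div(F_lows) / V
    C_td = np.where(g.mask, C_td, 0.0)

    # Zalesak clip of the antidiffusive fluxes
    lo1, hi1 = _neighbor_extrema(C, g.mask)
    lo2, hi2 = _neighbor_extrema(C_td, g.mask)
    C_min, C_max = np.minimum(lo1, lo2), np.maximum(hi1, hi2)

    Az, Ay, Ax = As
    P_plus = P_minus = 0.0
    for A, axis in ((Az, -3), (Ay, -2), (Ax, -1)):
        A_lo = _sl(A, axis, slice(None, -1))
        A_hi = _sl(A, axis, slice(1, None))
        P_plus = P_plus + np.maximum(A_lo, 0.0) + np.maximum(-A_hi, 0.0)
        P_minus = P_minus + np.maximum(-A_lo, 0.0) + np.maximum(A_hi, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        R_plus = np.where(P_plus > 0.0, np.minimum(1.0, (C_max - C_td) * V / (dt * P_plus)), 1.0)
        R_minus = np.where(P_minus > 0.0, np.minimum(1.0, (C_td - C_min) * V / (dt * P_minus)), 1.0)
    R_plus = np.clip(R_plus, 0.0, 1.0)
    R_minus = np.clip(R_minus, 0.0, 1.0)

    def _limit(A, axis):
        # interior faces: flux A>0 goes +axis: leaves lower cell, enters upper
        n = A.shape[axis] - 1
        Rp_hi = _sl(R_plus, axis, slice(1, n))
        Rm_hi = _sl(R_minus, axis, slice(1, n))
        Rp_lo = _sl(R_plus, axis, slice(0, n - 1))
        Rm_lo = _sl(R_minus, axis, slice(0, n - 1))
        Ai = _sl(A, axis, slice(1, n))
        coef = np.where(Ai >= 0.0, np.minimum(Rp_hi, Rm_lo), np.minimum(Rp_lo, Rm_hi))
        out = np.array(np.broadcast_to(A, coef.shape[:-3] + A.shape[-3:]))
        idx = [slice(None)] * out.ndim
        idx[axis] = slice(1, n)
        out[tuple(idx)] = coef * Ai
        return out

    A_lim = [_limit(Az, -3), _limit(Ay, -2), _limit(Ax, -1)]
    C_new = C_td - dt * _div(A_lim) / V
    return np.where(g.mask, C_new, 0.0)


def mixed_layer_diffusivity(
    g: Grid,
    kappa_min: float,
    kappa_ml: float,
    ml_depth: float,
    transition: float = 15.0,
) -> np.ndarray:
    """Vertical diffusivity at the interior interfaces (nz-1,).

    A turbulent surface layer (``kappa_ml`` down to ``ml_depth`` m, tanh
    transition over ``transition`` m) over the quiet interior value
    ``kappa_min`` - a fixed-profile stand-in for a turbulence closure in the
    weakly stratified winter column.
    """
    z = g.z_w[1:-1]
    frac = 0.5 * (1.0 - np.tanh((z - ml_depth) / max(transition, 1e-6)))
    return kappa_min + (kappa_ml - kappa_min) * frac


def diffuse(C: np.ndarray, kappa_h: float, kappa_v, g: Grid, dt: float) -> np.ndarray:
    """One explicit diffusion step with no-flux boundaries (dt in seconds).

    Horizontal Laplacian diffusivity ``kappa_h`` (m^2/s); ``kappa_v`` is a
    scalar or a per-interface profile of length nz-1.  Mass is conserved
    exactly (flux form); raises :class:`StabilityError` above the explicit
    stability limit.
    """
    dz = g.dz
    dzc = np.diff(g.z_mid)  # midpoint-to-midpoint distances, (nz-1,)
    kv = np.broadcast_to(np.asarray(kappa_v, dtype=float), (max(g.nz - 1, 0),))
    s = 2.0 * dt * (kappa_h / g.dx**2 + kappa_h / g.dy**2)
    if g.nz > 1:
        s += 2.0 * dt * float(np.max(kv / (dz[:-1] * dzc)))
    if s > 1.0:
        raise StabilityError(
            f"explicit diffusion number {s:.3f} > 1; sub-step the update"
        )

    C = np.where(g.mask, C, 0.0)
    m = g.mask
    div = np.zeros_like(C)

    # horizontal x: flux positive in +x through interior faces, masked at land
    grad = (C[..., 1:] - C[..., :-1]) / g.dx
    flux = -kappa_h * grad * (m[:, :, 1:] & m[:, :, :-1])
    div[..., :-1] -= flux / g.dx
    div[..., 1:] += flux / g.dx
    # horizontal y
    grad = (C[..., 1:, :] - C[..., :-1, :]) / g.dy
    flux = -kappa_h * grad * (m[:, 1:, :] & m[:, :-1, :])
    div[..., :-1, :] -= flux / g.dy
    div[..., 1:, :] += flux / g.dy
    # vertical (flux positive downward; layer volumes differ, mass conserved)
    if g.nz > 1:
        grad = (C[..., 1:, :, :] - C[..., :-1, :, :]) / dzc[:, None, None]
        flux = -kv[:, None, None] * grad * (m[1:, :, :] & m[:-1, :, :])
        div[..., :-1, :, :] -= flux / dz[:-1, None, None]
        div[..., 1:, :, :] += flux / dz[1:, None, None]
    out = C + dt * div
    return np.where(g.mask, out, 0.0)


def sink(D: np.ndarray, g: Grid, p: bio.BioParams, dt: float):
    """Advance detritus sinking over ``dt`` seconds (internally sub-stepped).

    Upwind downward flux with speed ``sinking_velocity(D)`` evaluated per
    cell.  Returns ``(D_new, bottom_export)`` where ``bottom_export`` is the
    column export through the sea floor (mmol N m^-2) accumulated over the
    step, so that ``delta(integral D dz) = -bottom_export`` exactly.
    """
    dz = g.dz[:, None, None]
    m = g.mask
    # face below each cell is the sea floor where the cell below is land/absent
    below_sea = np.concatenate([m[1:], np.zeros_like(m[:1])], axis=0)
    bottom_face = m & ~below_sea

    D = np.where(m, D, 0.0)
    export = np.zeros((g.ny, g.nx))

    w_max_ms = p.w_Dmax / SECONDS_PER_DAY
    n_sub = max(1, int(np.ceil(w_max_ms * dt / float(g.dz.min()))))
    sub = dt / n_sub
    for _ in range(n_sub):
        w_ms = bio.sinking_velocity(D, p) / SECONDS_PER_DAY
        F = w_ms * D * m  # downward flux out of each cell, mmol m^-2 s^-1
        into = np.concatenate([np.zeros_like(F[:1]), F[:-1]], axis=0) * m
        # flux from the last sea cell leaves the column
        leaving = F * bottom_face
        interior_out = F - leaving
        D = D + sub * (into - interior_out - leaving) / dz
        export += sub * leaving.sum(axis=0)
    return np.where(m, D, 0.0), export
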