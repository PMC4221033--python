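"""Rectangular z-coordinate grid with a rigid lid and static bathymetry.

Conventions (asserted throughout the package and in the tests):

* array axes are ``(z, y, x)``;
* depth is positive downward, layer index 0 at the surface;
* tracers live at cell centres; velocities on an Arakawa C-grid
  (``u`` on x-faces, ``v`` on y-faces, ``w`` on z-interfaces, positive up);
* land is marked by a boolean sea mask; domain boundaries are closed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Grid"]


def stretched_thicknesses(nz: int, depth: float, surface_dz: float) -> np.ndarray:
    """Geometrically stretched layer thicknesses, finest at the surface,
    summing exactly to ``depth``; first layer ~``surface_dz``."""
    if nz < 1 or depth <= 0 or surface_dz <= 0 or surface_dz * nz > depth:
        raise ValueError("inconsistent vertical grid request")
    if nz == 1 or abs(surface_dz * nz - depth) / depth < 1e-12:
        return np.full(nz, depth / nz)
    # solve surface_dz * (r^nz - 1)/(r - 1) = depth for the ratio r > 1
    lo, hi = 1.0 + 1e-12, 10.0
    for _ in range(200):
        r = 0.5 * (lo + hi)
        total = surface_dz * (r**nz - 1.0) / (r - 1.0)
        if total < depth:
            lo = r
        else:
            hi = r
    dz = surface_dz * r ** np.arange(nz)
    return dz * (depth / dz.sum())


@dataclass
class Grid:
    """Static rectangular mesh.

    Attributes
    ----------
    dx, dy : float
        Horizontal spacings (m), uniform.
    z_w : array (nz+1,)
        Layer interface depths (m, positive down), ``z_w[0] == 0``.
    mask : bool array (nz, ny, nx)
        True on sea cells.
    """

    dx: float
    dy: float
    z_w: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.z_w = np.asarray(self.z_w, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("grid spacings must be positive")
        if self.z_w[0] != 0 or np.any(np.diff(self.z_w) <= 0):
            raise ValueError("z_w must start at 0 and increase")
        if self.mask.ndim != 3 or self.mask.shape[0] != len(self.z_w) - 1:
            raise ValueError("mask must have shape (nz, ny, nx)")
        # water must be contiguous from the surface down
        if np.any(np.diff(self.mask.astype(int), axis=0) > 0):
            raise ValueError("sea cells must be contiguous from the surface")

    # ---- derived geometry -------------------------------------------------
    @property
    def nz(self) -> int:
        return self.mask.shape[0]

    @property
    def ny(self) -> int:
        return self.mask.shape[1]

    @property
    def nx(self) -> int:
        return self.mask.shape[2]

    @property
    def dz(self) -> np.ndarray:
        """Layer thicknesses (nz,), m."""
        return np.diff(self.z_w)

    @property
    def z_mid(self) -> np.ndarray:
        """Layer midpoint depths (nz,), m."""
        return 0.5 * (self.z_w[:-1] + self.z_w[1:])

    @property
    def cell_volume(self) -> np.ndarray:
        """Cell volumes (nz, 1, 1) broadcastable to fields, m^3."""
        return (self.dx * self.dy * self.dz)[:, None, None]

    @property
    def depth(self) -> np.ndarray:
        """Static water depth per column (ny, nx), m (0 on land columns)."""
        return np.sum(self.mask * self.dz[:, None, None], axis=0)

    @property
    def column_mask(self) -> np.ndarray:
        """True where the column has any sea cell (ny, nx)."""
        return self.mask[0]

    def x_centers(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.dx

    def y_centers(self) -> np.ndarray:
        return (np.arange(self.ny) + 0.5) * self.dy

    def total_mass(self, C: np.ndarray) -> float:
        """Volume integral of a tracer over sea cells (mmol if C in mmol m^-3)."""
        return float(np.sum(np.where(self.mask, C, 0.0) * self.cell_volume))

    # ---- constructors -----------------------------------------------------
    @classmethod
    def regular(
        cls,
        nx: int,
        ny: int,
        nz: int,
        dx: float,
        dy: float,
        depth: float,
        surface_dz: float | None = None,
    ) -> "Grid":
        """All-sea flat-bottom grid; surface-refined layers if ``surface_dz``
        is given, uniform otherwise."""
        if surface_dz is None:
            dz = np.full(nz, depth / nz)
        else:
            dz = stretched_thicknesses(nz, depth, surface_dz)
        z_w = np.concatenate([[0.0], np.cumsum(dz)])
        mask = np.ones((nz, ny, nx), dtype=bool)
        return cls(dx=dx, dy=dy, z_w=z_w, mask=mask)
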