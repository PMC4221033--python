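"""NetCDF and CSV output with provenance metadata.

Snapshots are written as a NetCDF dataset with dimensions
``(time, z, y, x)`` and units attributes; flow fields keep their native
C-grid staggering (``x_face``, ``y_face``, ``z_face`` dimensions).  Files
carry the config hash and package version as global attributes so a run can
be reproduced from its own output.  The scipy backend (NetCDF3 classic) is
used for portability.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import xarray as xr

from . import __version__
from .grid import Grid
from .simulate import RunOutput
from .transport import FlowField, SECONDS_PER_DAY

__all__ = [
    "run_to_dataset",
    "write_output",
    "read_output",
    "flow_to_dataset",
    "write_flow",
    "read_flow",
]

_ENGINE = "scipy"


def _coords(g: Grid) -> dict:
    return {
        "z": ("z", g.z_mid, {"units": "m", "positive": "down"}),
        "y": ("y", g.y_centers(), {"units": "m"}),
        "x": ("x", g.x_centers(), {"units": "m"}),
    }


def run_to_dataset(run: RunOutput) -> xr.Dataset:
    """Snapshot fields as an xarray Dataset (time in days)."""
    g = run.grid
    days = sorted(run.snapshots)
    stacked = {
        name: np.stack([getattr(run.snapshots[d], name) for d in days])
        for name in ("N", "P", "Z", "D")
    }
    data_vars = {
        name: (("time", "z", "y", "x"), arr, {"units": "mmol N m-3"})
        for name, arr in stacked.items()
    }
    ds = xr.Dataset(
        data_vars,
        coords={"time": ("time", np.asarray(days, dtype=float), {"units": "days"}), **_coords(g)},
        attrs={"config_hash": run.metadata.get("config_hash", ""), "alborun_version": __version__},
    )
    return ds


def write_output(run: RunOutput, path: str | Path):
    """Write snapshots (NetCDF) and the budget series (CSV alongside).

    Returns the two paths written.
    """
    path = Path(path)
    ds = run_to_dataset(run)
    ds.to_netcdf(path, engine=_ENGINE)
    csv_path = path.with_suffix(".budget.csv")
    run.budget.to_csv(csv_path, index=False)
    return path, csv_path


def read_output(path: str | Path) -> xr.Dataset:
    return xr.open_dataset(path, engine=_ENGINE).load()


def flow_to_dataset(flow: FlowField, g: Grid) -> xr.Dataset:
    """Native staggered flow field as a Dataset (w reported in m/day too)."""
    ds = xr.Dataset(
        {
            "u": (("z", "y", "x_face"), flow.u, {"units": "m s-1"}),
            "v": (("z", "y_face", "x"), flow.v, {"units": "m s-1"}),
            "w": (("z_face", "y", "x"), flow.w, {"units": "m s-1", "positive": "up"}),
            "w_mday": (("z_face", "y", "x"), flow.w * SECONDS_PER_DAY, {"units": "m day-1"}),
        },
        coords={
            "z": ("z", g.z_mid, {"units": "m", "positive": "down"}),
            "z_face": ("z_face", g.z_w, {"units": "m"}),
            "y": ("y", g.y_centers(), {"units": "m"}),
            "x": ("x", g.x_centers(), {"units": "m"}),
        },
        attrs={"alborun_version": __version__},
    )
    return ds


def write_flow(flow: FlowField, g: Grid, path: str | Path) -> Path:
    path = Path(path)
    flow_to_dataset(flow, g).to_netcdf(path, engine=_ENGINE)
    return path


def read_flow(path: str | Path) -> FlowField:
    ds = xr.open_dataset(path, engine=_ENGINE).load()
    return FlowField(u=ds["u"].values, v=ds["v"].values, w=ds["w"].values)
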