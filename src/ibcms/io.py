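"""File formats: HDF5 run containers, VTK legacy snapshots, CSV series,
plain-text fiber geometry interchange, and external velocity volumes.

The HDF5 container layout:

    /grid          attrs: ndim, n, extent
    /config_json   the full run configuration (canonical JSON) + sha256 attr
    /series/<col>  1-D diagnostic series (t, t_norm, Q_<port>, ke_max, ...)
    /fields/NNNNNN/u,p   field snapshots at the output cadence (t attr)
    /fibers/NNNNNN/X     boundary-point snapshots
    /checkpoint    u,p,X,F + step index for bitwise restart

External velocity volumes (e.g. resampled 4-D phase-contrast MRI) use a
minimal self-describing layout: dataset ``/u`` with shape (ndim, *n), attrs
``axis_order`` (e.g. "xyz") and ``spacing_cm``; NaN voxels mark masked
regions and propagate through the diagnostics.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core_fluid import FluidState, GridSpec
from .immersed_boundary import BoundaryState, FiberModel

__all__ = [
    "RunContainer",
    "write_vtk_structured",
    "save_fiber_csv",
    "load_fiber_csv",
    "save_velocity_volume",
    "load_velocity_volume",
    "series_to_csv",
]


def config_hash(config_json: str) -> str:
    return hashlib.sha256(config_json.encode()).hexdigest()


class RunContainer:
    """Append-oriented HDF5 container for one simulation run."""

    def __init__(self, path, grid: GridSpec, config_json: str = "{}",
                 mode: str = "w"):
        self.path = Path(path)
        self._h5 = h5py.File(self.path, mode)
        self.grid = grid
        if mode == "w":
            g = self._h5.create_group("grid")
            g.attrs["ndim"] = grid.ndim
            g.attrs["n"] = grid.n
            g.attrs["extent"] = grid.extent
            ds = self._h5.create_dataset(
                "config_json", data=np.bytes_(config_json.encode())
            )
            ds.attrs["sha256"] = config_hash(config_json)

    # -- fields -----------------------------------------------------------
    def write_fields(self, step: int, state: FluidState):
        g = self._h5.require_group("fields").create_group(f"{step:08d}")
        g.attrs["t"] = state.t
        g.create_dataset("u", data=state.u)
        g.create_dataset("p", data=state.p)

    def write_fibers(self, step: int, bstate: BoundaryState):
        g = self._h5.require_group("fibers").create_group(f"{step:08d}")
        g.attrs["t"] = bstate.t
        g.create_dataset("X", data=bstate.X)

    def field_steps(self):
        if "fields" not in self._h5:
            return []
        return sorted(int(k) for k in self._h5["fields"])

    def read_fields(self, step: int) -> FluidState:
        g = self._h5["fields"][f"{step:08d}"]
        return FluidState(g["u"][...], g["p"][...], float(g.attrs["t"]))

    # -- series -----------------------------------------------------------
    def write_series(self, series: dict):
        g = self._h5.require_group("series")
        for name, arr in series.items():
            if name in g:
                del g[name]
            g.create_dataset(name, data=np.asarray(arr))

    def read_series(self) -> dict:
        if "series" not in self._h5:
            return {}
        return {k: v[...] for k, v in self._h5["series"].items()}

    # -- checkpoint / restart ---------------------------------------------
    def write_checkpoint(self, istep: int, state: FluidState,
                         bstate: BoundaryState, port_rates=None):
        if "checkpoint" in self._h5:
            del self._h5["checkpoint"]
        g = self._h5.create_group("checkpoint")
        g.attrs["istep"] = istep
        g.create_dataset("u", data=state.u)
        g.create_dataset("p", data=state.p)
        g.attrs["t"] = state.t
        g.create_dataset("X", data=bstate.X)
        g.create_dataset("F", data=bstate.F)
        if port_rates is not None:
            g.create_dataset("port_rates", data=np.asarray(port_rates))
        self._h5.flush()

    def read_checkpoint(self):
        g = self._h5["checkpoint"]
        state = FluidState(g["u"][...], g["p"][...], float(g.attrs["t"]))
        bstate = BoundaryState(g["X"][...], g["F"][...], state.t)
        rates = g["port_rates"][...] if "port_rates" in g else None
        return int(g.attrs["istep"]), state, bstate, rates

    def close(self):
        self._h5.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    @classmethod
    def open(cls, path) -> "RunContainer":
        h5 = h5py.File(path, "r+")
        g = h5["grid"]
        grid = GridSpec(int(g.attrs["ndim"]), tuple(int(x) for x in g.attrs["n"]),
                        tuple(float(x) for x in g.attrs["extent"]))
        obj = cls.__new__(cls)
        obj.path = Path(path)
        obj._h5 = h5
        obj.grid = grid
        return obj


def write_vtk_structured(path, grid: GridSpec, fields: dict, title="ibcms"):
    """Write scalar/vector cell-centered fields as a VTK legacy
    STRUCTURED_POINTS ASCII file (readable by ParaView/VisIt).

    ``fields`` maps a name to an array of shape (*n) (scalar) or
    (ndim, *n) (vector).
    """
    n = grid.n + (1,) * (3 - grid.ndim)
    npts = int(np.prod(n))
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"{title}\nASCII\nDATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {n[0]} {n[1]} {n[2]}\n")
        f.write(f"ORIGIN {grid.h / 2} {grid.h / 2} {grid.h / 2}\n")
        f.write(f"SPACING {grid.h} {grid.h} {grid.h}\n")
        f.write(f"POINT_DATA {npts}\n")
        for name, arr in fields.items():
            arr = np.asarray(arr)
            if arr.shape == grid.shape:  # scalar
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                flat = arr.reshape(grid.n).transpose().ravel()
                np.savetxt(f, flat, fmt="%.10g")
            elif arr.shape == (grid.ndim, *grid.n):
                f.write(f"VECTORS {name} double\n")
                comps = [arr[c].transpose().ravel() for c in range(grid.ndim)]
                while len(comps) < 3:
                    comps.append(np.zeros_like(comps[0]))
                np.savetxt(f, np.column_stack(comps), fmt="%.10g")
            else:
                raise ValueError(f"field '{name}' has unexpected shape {arr.shape}")


# ---------------------------------------------------------------------------
# fiber geometry interchange

def save_fiber_csv(stem, model: FiberModel):
    """Write the fiber model as two CSV tables: <stem>.points.csv and
    <stem>.springs.csv (plus <stem>.tethers.csv when tethers exist)."""
    stem = Path(stem)
    nd = model.points.shape[1]
    cols = ["x", "y", "z"][:nd]
    pts = pd.DataFrame(model.points, columns=cols)
    pts.insert(0, "id", np.arange(model.n_points))
    pts["ds"] = model.ds
    pts.to_csv(stem.with_suffix(".points.csv"), index=False)
    spr = pd.DataFrame(
        {
            "i": model.spring_i,
            "j": model.spring_j,
            "k_ref": model.spring_k,
            "L0_ref": model.spring_L0,
            "group": [str(g) for g in model.spring_group],
        }
    )
    spr.to_csv(stem.with_suffix(".springs.csv"), index=False)
    if model.tether_idx.size:
        tdf = pd.DataFrame(model.tether_target, columns=[f"target_{c}" for c in cols])
        tdf.insert(0, "idx", model.tether_idx)
        tdf["k"] = model.tether_k
        tdf["slack"] = model.tether_slack
        tdf.to_csv(stem.with_suffix(".tethers.csv"), index=False)


def load_fiber_csv(stem) -> tuple[FiberModel, BoundaryState]:
    stem = Path(stem)
    pts = pd.read_csv(stem.with_suffix(".points.csv"))
    cols = [c for c in ("x", "y", "z") if c in pts.columns]
    spr = pd.read_csv(stem.with_suffix(".springs.csv"))
    tpath = stem.with_suffix(".tethers.csv")
    kwargs = {}
    if tpath.exists():
        tdf = pd.read_csv(tpath)
        kwargs = dict(
            tether_idx=tdf["idx"].to_numpy(),
            tether_target=tdf[[f"target_{c}" for c in cols]].to_numpy(),
            tether_k=tdf["k"].to_numpy(),
            tether_slack=tdf["slack"].to_numpy() if "slack" in tdf else None,
        )
    group = spr["group"].fillna("").to_numpy(dtype=object) if "group" in spr \
        else None
    model = FiberModel(
        points=pts[cols].to_numpy(),
        spring_i=spr["i"].to_numpy(),
        spring_j=spr["j"].to_numpy(),
        spring_k=spr["k_ref"].to_numpy(),
        spring_L0=spr["L0_ref"].to_numpy(),
        spring_group=group,
        ds=pts["ds"].to_numpy() if "ds" in pts else None,
        **kwargs,
    )
    return model, BoundaryState(model.points.copy())


# ---------------------------------------------------------------------------
# external velocity volumes

def save_velocity_volume(path, u: np.ndarray, spacing_cm: float,
                         axis_order: str | None = None):
    u = np.asarray(u, dtype=float)
    ndim = u.shape[0]
    if axis_order is None:
        axis_order = "xyz"[:ndim]
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("u", data=u)
        ds.attrs["axis_order"] = axis_order
        ds.attrs["spacing_cm"] = spacing_cm


def load_velocity_volume(path) -> tuple[np.ndarray, dict]:
    """Read a dense velocity array with grid metadata.

    Returns (u, meta): u with axes reordered to the package's canonical
    x, y[, z] order (component axis first) in cm/s; ``meta`` holds
    ``spacing_cm`` and the original ``axis_order``.  NaN entries (masked
    voxels) are preserved.

    Raises
    ------
    KeyError
        listing the required keys, when metadata is missing.
    """
    with h5py.File(path, "r") as f:
        if "u" not in f:
            raise KeyError("velocity volume must contain dataset 'u'")
        ds = f["u"]
        missing = [k for k in ("axis_order", "spacing_cm") if k not in ds.attrs]
        if missing:
            raise KeyError(
                f"velocity volume missing required attrs: {missing} "
                "(need axis_order, spacing_cm)"
            )
        u = ds[...]
        axis_order = ds.attrs["axis_order"]
        if isinstance(axis_order, bytes):
            axis_order = axis_order.decode()
        spacing = float(ds.attrs["spacing_cm"])
    ndim = u.shape[0]
    want = "xyz"[:ndim]
    if sorted(axis_order) != sorted(want):
        raise ValueError(f"axis_order '{axis_order}' is not a permutation of '{want}'")
    perm = [axis_order.index(c) for c in want]
    u = np.transpose(u, axes=[0] + [1 + p for p in perm])
    u = u[list(perm), ...]  # permute the component axis consistently
    return u, {"spacing_cm": spacing, "axis_order": axis_order}


def series_to_csv(path, series: dict):
    """Diagnostic series dict -> tidy CSV (one row per sample)."""
    pd.DataFrame(series).to_csv(path, index=False)


def series_from_csv(path) -> dict:
    df = pd.read_csv(path)
    return {c: df[c].to_numpy() for c in df.columns}
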