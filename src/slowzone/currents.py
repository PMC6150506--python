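"""Surface-current interpolation and speed-through-water conversion.

The current field mirrors the operational product the monitoring station
uses: eastward/northward components on a regular 400 m planar grid, one
snapshot per hour, with sub-hour values obtained by linear interpolation in
time and bilinear interpolation in space.  Speed through water is the
magnitude of the ground-velocity vector (from SOG and COG) minus the
current vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .geo import GridSpec, LocalProjection, MPS_PER_KNOT

KNOTS_PER_MPS = 1.0 / MPS_PER_KNOT


@dataclass
class CurrentField:
    """Gridded u (eastward) / v (northward) surface current in m/s.

    ``data`` is an xarray Dataset with dims (time, y, x); x/y are projected
    metres (cell centres); ``projection`` maps lon/lat to that plane.
    """

    data: xr.Dataset
    projection: LocalProjection

    def __post_init__(self):
        ds = self.data
        for var in ("u", "v"):
            if var not in ds:
                raise ValueError(f"current field missing variable {var!r}")
        if float(np.abs(ds["u"]).max()) > 5.0 or float(np.abs(ds["v"]).max()) > 5.0:
            raise ValueError("current magnitude exceeds 5 m/s; wrong units?")
        t = pd.to_datetime(ds["time"].values)
        if len(t) > 1:
            steps = np.diff(t.view("int64")) / 1e9
            if not np.allclose(steps, 3600.0):
                raise ValueError("current snapshots must be hourly")

    @classmethod
    def from_arrays(cls, grid: GridSpec, times, u: np.ndarray, v: np.ndarray,
                    projection: LocalProjection) -> "CurrentField":
        x = grid.x0 + (np.arange(grid.ncols) + 0.5) * grid.cell_size
        y = grid.y0 + (np.arange(grid.nrows) + 0.5) * grid.cell_size
        ds = xr.Dataset(
            {"u": (("time", "y", "x"), u), "v": (("time", "y", "x"), v)},
            coords={"time": pd.to_datetime(times), "y": y, "x": x},
            attrs={"cell_size_m": grid.cell_size,
                   "proj_lon0": projection.lon0, "proj_lat0": projection.lat0},
        )
        return cls(ds, projection)

    def to_netcdf(self, path) -> None:
        self.data.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "CurrentField":
        ds = xr.load_dataset(path, engine="scipy")
        proj = LocalProjection(ds.attrs["proj_lon0"], ds.attrs["proj_lat0"])
        return cls(ds, proj)

    def to_csv(self, path) -> None:
        """Long-format fallback for tiny text fixtures."""
        df = self.data.to_dataframe().reset_index()
        df["proj_lon0"] = self.projection.lon0
        df["proj_lat0"] = self.projection.lat0
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CurrentField":
        df = pd.read_csv(path, parse_dates=["time"])
        proj = LocalProjection(df["proj_lon0"].iloc[0], df["proj_lat0"].iloc[0])
        ds = df.set_index(["time", "y", "x"])[["u", "v"]].to_xarray()
        ds.attrs["cell_size_m"] = float(np.diff(ds["x"].values)[0]) \
            if ds.sizes["x"] > 1 else 400.0
        return cls(ds, proj)

    @property
    def time_range(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        t = self.data["time"].values
        return pd.Timestamp(t[0]), pd.Timestamp(t[-1])

    def interp_uv(self, x: float, y: float, t_s: float) -> tuple[float, float]:
        """Bilinear-in-space, linear-in-time interpolation in m/s.

        ``t_s`` is seconds since the first snapshot.  No bounds checking;
        callers clamp or validate.
        """
        if not hasattr(self, "_cache"):
            ds = self.data
            t0 = pd.Timestamp(ds["time"].values[0])
            tsec = np.asarray((pd.to_datetime(ds["time"].values) - t0).total_seconds())
            self._cache = (np.asarray(ds["x"].values, float),
                           np.asarray(ds["y"].values, float),
                           np.asarray(tsec, float),
                           np.asarray(ds["u"].values, float),
                           np.asarray(ds["v"].values, float))
        xs, ys, tsec, u, v = self._cache

        def axis_weights(grid, val):
            i = int(np.clip(np.searchsorted(grid, val) - 1, 0, max(len(grid) - 2, 0)))
            if len(grid) == 1:
                return 0, 0, 0.0
            w = (val - grid[i]) / (grid[i + 1] - grid[i])
            return i, i + 1, float(np.clip(w, 0.0, 1.0))

        i0, i1, wx = axis_weights(xs, x)
        j0, j1, wy = axis_weights(ys, y)
        k0, k1, wt = axis_weights(tsec, t_s)

        def tri(a):
            c00 = a[k0, j0, i0] * (1 - wx) + a[k0, j0, i1] * wx
            c01 = a[k0, j1, i0] * (1 - wx) + a[k0, j1, i1] * wx
            c0 = c00 * (1 - wy) + c01 * wy
            c10 = a[k1, j0, i0] * (1 - wx) + a[k1, j0, i1] * wx
            c11 = a[k1, j1, i0] * (1 - wx) + a[k1, j1, i1] * wx
            c1 = c10 * (1 - wy) + c11 * wy
            return c0 * (1 - wt) + c1 * wt

        return float(tri(u)), float(tri(v))


def current_at(field: CurrentField, p, t) -> tuple[float, float]:
    """Current (u, v) in knots at geographic point p and time t.

    Bilinear in space, linear in time.  Raises outside the field's spatial
    or temporal extent, naming the violated bound.
    """
    x, y = field.projection.forward(p[0], p[1])
    ds = field.data
    t = pd.Timestamp(t)
    tmin, tmax = pd.Timestamp(ds["time"].values[0]), pd.Timestamp(ds["time"].values[-1])
    if not (tmin <= t <= tmax):
        raise ValueError(f"time {t} outside field range [{tmin}, {tmax}]")
    for coord, val in (("x", float(x)), ("y", float(y))):
        lo, hi = float(ds[coord].min()), float(ds[coord].max())
        if not (lo <= val <= hi):
            raise ValueError(f"position {coord}={val:.1f} outside field extent "
                             f"[{lo:.1f}, {hi:.1f}]")
    u, v = field.interp_uv(float(x), float(y), (t - tmin).total_seconds())
    return (u * KNOTS_PER_MPS, v * KNOTS_PER_MPS)


def sog_to_stw(sog: float, cog_deg: float, current_kn: tuple[float, float]) -> float:
    """Speed through water from speed/course over ground and the current (knots).

    The ground-velocity vector is (sog*sin COG, sog*cos COG) in east/north
    components; STW is the magnitude of ground velocity minus current.
    """
    c = np.radians(cog_deg)
    gu = sog * np.sin(c)
    gv = sog * np.cos(c)
    return float(np.hypot(gu - current_kn[0], gv - current_kn[1]))


def add_stw_fields(fixes: pd.DataFrame, fields) -> pd.DataFrame:
    """Fill STW from whichever of several fields covers each fix's time.

    Fixes covered by no field keep SOG (zero-current fallback).  Useful when
    the scenario spans several disjoint hourly windows.
    """
    if not fields:
        return add_stw(fixes, None)
    out = fixes.copy()
    stw = out["sog"].to_numpy(dtype=float).copy()
    done = np.zeros(len(out), dtype=bool)
    for fld in fields:
        t0, t1 = fld.time_range
        sel = (~done) & (out["timestamp"] >= t0) & (out["timestamp"] <= t1)
        if sel.any():
            sub = add_stw(out.loc[sel], fld)
            stw[sel.to_numpy()] = sub["stw"].to_numpy()
            done |= sel.to_numpy()
    out["stw"] = stw
    return out


def add_stw(fixes: pd.DataFrame, field: CurrentField | None) -> pd.DataFrame:
    """Return a copy of the fix table with an ``stw`` column.

    With no field, STW falls back to SOG (zero-current assumption).
    """
    out = fixes.copy()
    if field is None:
        out["stw"] = out["sog"]
        return out
    stw = np.empty(len(out))
    for i, r in enumerate(out.itertuples()):
        cur = current_at(field, (r.lon, r.lat), r.timestamp)
        stw[i] = sog_to_stw(r.sog, r.cog, cur)
    out["stw"] = stw
    return out
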