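"""AIS fix cleaning and transit construction.

A *fix* is one decoded AIS position report (vessel id, UTC timestamp,
position, speed over ground, course over ground).  A *transit* is one
vessel's continuous passage through the study area.  Cleaning removes
implausible reports; transit building groups fixes per vessel, splits
passages on silent gaps, and drops passages that do not span the study
area (the "incomplete transit" criterion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .geo import GeoPoint, MeasureCalendar, ZoneSet, geodesic_distance

FIX_COLUMNS = ["vessel_id", "timestamp", "lat", "lon", "sog", "cog"]

#: default cleaning thresholds; generous for merchant vessels
MAX_SOG_KN = 35.0
MAX_IMPLIED_SPEED_KN = 50.0
MAX_GAP_MIN = 30.0
MIN_FIXES = 5


def read_fixes_csv(path_or_buf) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a decoded-AIS CSV (vessel_id,timestamp_iso8601,lat,lon,sog_kn,cog_deg).

    Unparseable rows are logged and dropped, never fatal.  Returns
    (fixes, rejection_log).
    """
    raw = pd.read_csv(path_or_buf, dtype=str)
    raw.columns = [c.strip() for c in raw.columns]
    rename = {"timestamp_iso8601": "timestamp", "sog_kn": "sog", "cog_deg": "cog"}
    raw = raw.rename(columns=rename)
    out, rejects = [], []
    for i, r in raw.iterrows():
        try:
            out.append({
                "vessel_id": str(r["vessel_id"]),
                "timestamp": pd.Timestamp(r["timestamp"]),
                "lat": float(r["lat"]), "lon": float(r["lon"]),
                "sog": float(r["sog"]), "cog": float(r["cog"]) % 360.0,
            })
        except (ValueError, TypeError, KeyError):
            rejects.append({"fix": f"row:{i}", "reason": "unparseable"})
    fixes = pd.DataFrame(out, columns=FIX_COLUMNS)
    return fixes, pd.DataFrame(rejects, columns=["fix", "reason"])


def _fix_id(row) -> str:
    return f"{row.vessel_id}@{pd.Timestamp(row.timestamp).isoformat()}"


def clean_fixes(fixes: pd.DataFrame, study_area: Polygon,
                max_sog: float = MAX_SOG_KN,
                max_implied: float = MAX_IMPLIED_SPEED_KN,
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove poor data points: bad position, erroneous speed, duplicates.

    Filters, in order: position outside the study-area bounding box; SOG
    outside [0, max_sog]; duplicate (vessel, timestamp) keeping the first;
    implied point-to-point speed above max_implied (the later fix of the
    offending pair is dropped).  Returns (surviving fixes, rejection log with
    one reason per rejected fix).
    """
    if fixes.empty:
        return fixes.copy(), pd.DataFrame(columns=["fix", "reason"])
    df = fixes.copy().reset_index(drop=True)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    log: list[dict] = []

    minx, miny, maxx, maxy = study_area.bounds
    bad_pos = ~df["lon"].between(minx, maxx) | ~df["lat"].between(miny, maxy)
    bad_sog = ~df["sog"].between(0.0, max_sog)
    for idx in df.index[bad_pos]:
        log.append({"fix": _fix_id(df.loc[idx]), "reason": "bad_position"})
    for idx in df.index[bad_sog & ~bad_pos]:
        log.append({"fix": _fix_id(df.loc[idx]), "reason": "erroneous_speed"})
    df = df[~(bad_pos | bad_sog)]

    dup = df.duplicated(subset=["vessel_id", "timestamp"], keep="first")
    for idx in df.index[dup]:
        log.append({"fix": _fix_id(df.loc[idx]), "reason": "duplicate"})
    df = df[~dup]

    keep_idx = []
    for _, grp in df.sort_values("timestamp").groupby("vessel_id", sort=False):
        prev = None
        for idx, row in grp.iterrows():
            if prev is None:
                keep_idx.append(idx)
                prev = row
                continue
            dt_h = (row.timestamp - prev.timestamp).total_seconds() / 3600.0
            d_nm = geodesic_distance(GeoPoint(prev.lon, prev.lat),
                                     GeoPoint(row.lon, row.lat))
            if dt_h > 0 and d_nm / dt_h > max_implied:
                log.append({"fix": _fix_id(row), "reason": "implied_speed"})
            else:
                keep_idx.append(idx)
                prev = row
    out = df.loc[sorted(keep_idx)].sort_values(["vessel_id", "timestamp"])
    return out.reset_index(drop=True), pd.DataFrame(log, columns=["fix", "reason"])


@dataclass
class Transit:
    """One vessel's continuous passage through the study area."""

    transit_id: str
    vessel_id: str
    ship_class: str
    flag: str
    fixes: pd.DataFrame          # time-ordered; columns FIX_COLUMNS (+ stw)
    direction: str               # 'upstream' (southward) | 'downstream'
    pilot_onboard: bool
    year: int
    measures_active: bool

    def __post_init__(self):
        if len(self.fixes) < 2:
            raise ValueError("a transit needs at least two fixes")
        ts = self.fixes["timestamp"].to_numpy()
        if not (ts[1:] > ts[:-1]).all():
            raise ValueError("transit timestamps must be strictly increasing")

    @property
    def mid_time(self) -> pd.Timestamp:
        ts = self.fixes["timestamp"]
        return ts.iloc[0] + (ts.iloc[-1] - ts.iloc[0]) / 2


def _along_axis(zones: ZoneSet):
    """Unit vector of the study area's principal axis in the projected plane,
    oriented so that positive displacement points upstream (toward the
    Saint-Simeon gate)."""
    proj = zones.projection
    poly = proj.project_geometry(zones.study_area)
    xy = np.asarray(poly.exterior.coords)[:-1]
    xy = xy - xy.mean(axis=0)
    _, _, vt = np.linalg.svd(xy, full_matrices=False)
    axis = vt[0]
    centroid = np.array(poly.centroid.coords[0])
    gate = proj.project_geometry(zones.gate_saintsimeon).centroid
    toward_sts = np.array([gate.x, gate.y]) - centroid
    if float(np.dot(axis, toward_sts)) < 0:
        axis = -axis
    return proj, axis


def _along_coord(fix_xy: np.ndarray, axis: np.ndarray) -> np.ndarray:
    return fix_xy @ axis


def build_transits(fixes: pd.DataFrame, vessels: pd.DataFrame | None,
                   pilot_table: pd.DataFrame | None, zones: ZoneSet,
                   cal: MeasureCalendar,
                   max_gap_min: float = MAX_GAP_MIN,
                   min_fixes: int = MIN_FIXES,
                   ) -> tuple[list[Transit], pd.DataFrame]:
    """Group cleaned fixes into complete transits.

    A silent gap longer than ``max_gap_min`` splits a vessel's fixes into
    separate passages.  A passage is kept only if it has at least
    ``min_fixes`` fixes and spans both halves of the study area along the
    channel axis (otherwise it is logged as incomplete).  Direction comes
    from the sign of the net along-channel displacement; the active flag
    from the calendar at the passage's mid-time.
    """
    log: list[dict] = []
    if fixes.empty:
        return [], pd.DataFrame(log, columns=["transit", "reason"])
    proj, axis = _along_axis(zones)
    vinfo = {}
    if vessels is not None:
        for r in vessels.itertuples():
            vinfo[str(r.vessel_id)] = (str(r.ship_class), str(r.flag))

    sa = proj.project_geometry(zones.study_area)
    poly_xy = np.asarray(sa.exterior.coords)[:-1] @ axis
    lo, hi = float(poly_xy.min()), float(poly_xy.max())
    mid = 0.5 * (lo + hi)

    transits: list[Transit] = []
    df = fixes.sort_values(["vessel_id", "timestamp"])
    for vid, grp in df.groupby("vessel_id", sort=False):
        grp = grp.reset_index(drop=True)
        gaps = grp["timestamp"].diff().dt.total_seconds().fillna(0) / 60.0
        passage_id = (gaps > max_gap_min).cumsum()
        for pid, passage in grp.groupby(passage_id):
            tid = f"{vid}-{passage['timestamp'].iloc[0].strftime('%Y%m%dT%H%M%S')}"
            if len(passage) < min_fixes:
                log.append({"transit": tid, "reason": "too_few_fixes"})
                continue
            px, py = proj.forward(passage["lon"].to_numpy(),
                                  passage["lat"].to_numpy())
            s = _along_coord(np.column_stack([px, py]), axis)
            if not (s.min() < mid and s.max() > mid):
                log.append({"transit": tid, "reason": "incomplete_span"})
                continue
            net = s[-1] - s[0]
            direction = "upstream" if net > 0 else "downstream"
            cls, flag = vinfo.get(str(vid), ("unknown", "unknown"))
            if str(vid) not in vinfo and vessels is not None:
                log.append({"transit": tid, "reason": "missing_vessel_metadata"})
            t_mid = passage["timestamp"].iloc[0] + \
                (passage["timestamp"].iloc[-1] - passage["timestamp"].iloc[0]) / 2
            pilot = _lookup_pilot(pilot_table, str(vid), t_mid)
            transits.append(Transit(
                transit_id=tid, vessel_id=str(vid), ship_class=cls, flag=flag,
                fixes=passage.reset_index(drop=True), direction=direction,
                pilot_onboard=pilot, year=int(t_mid.year),
                measures_active=cal.any_active(t_mid),
            ))
    return transits, pd.DataFrame(log, columns=["transit", "reason"])


def _lookup_pilot(pilot_table: pd.DataFrame | None, vessel_id: str,
                  t: pd.Timestamp) -> bool:
    if pilot_table is None or pilot_table.empty:
        return False
    sel = pilot_table[pilot_table["vessel_id"].astype(str) == vessel_id]
    for r in sel.itertuples():
        if pd.Timestamp(r.t_start) <= t <= pd.Timestamp(r.t_end):
            return bool(r.pilot_onboard)
    return False


def segmentize(tr: Transit) -> pd.DataFrame:
    """Consecutive-fix segments with geodesic length (nm), duration (s) and a
    representative speed (mean of endpoint STW, falling back to SOG), so the
    current correction applied at fixes propagates to distance weighting."""
    fx = tr.fixes
    n = len(fx)
    speed_col = "stw" if "stw" in fx.columns else "sog"
    lon = fx["lon"].to_numpy(); lat = fx["lat"].to_numpy()
    lengths = np.array([
        geodesic_distance(GeoPoint(lon[i], lat[i]), GeoPoint(lon[i + 1], lat[i + 1]))
        for i in range(n - 1)])
    dur = fx["timestamp"].diff().dt.total_seconds().to_numpy()[1:]
    v = fx[speed_col].to_numpy()
    seg_speed = 0.5 * (v[:-1] + v[1:])
    return pd.DataFrame({
        "lon0": lon[:-1], "lat0": lat[:-1], "lon1": lon[1:], "lat1": lat[1:],
        "t0": fx["timestamp"].to_numpy()[:-1], "t1": fx["timestamp"].to_numpy()[1:],
        "length_nm": lengths, "duration_s": dur, "speed_kn": seg_speed,
    })
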