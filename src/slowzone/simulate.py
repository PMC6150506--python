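"""Synthetic study scenarios: zones, tidal currents, whale densities and
vessel transits with configurable compliance behaviour.

The generator emulates the statistical structure of the monitoring inputs:

* a channel-shaped study area with a slow-down zone (speed limit 10 kn STW),
  a no-go area, route-reference gates at an island, and transit-time gates;
* tidal surface currents (12.42-h semidiurnal period) with a smooth spatial
  gradient, sampled onto an hourly gridded field;
* per-class cruising speeds around 14.1 +/- 2.6 kn, active-period target
  speeds around 11.3 +/- 1.7 kn, a configurable strict-compliance share,
  deceleration ramps into the zone, and north/south route choice;
* speed-dependent AIS emission intervals with dropout, which reproduces the
  over-representation of slow ships in time-sampled AIS data.

Every planted quantity is recorded in a truth log so each pipeline stage can
be checked against what was generated.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm
from shapely.geometry import LineString, Point, Polygon, box

from .currents import MPS_PER_KNOT, CurrentField
from .geo import (GeoPoint, GridSpec, LocalProjection, MeasureCalendar,
                  ZoneSet, M_PER_NM)

KN_TO_MPS = MPS_PER_KNOT


# ---------------------------------------------------------------------------
# Synthetic zone layout (rectangles approximating the real estuary layout;
# the official coordinates are not public)


def synthetic_zones() -> ZoneSet:
    """A channel study area with slow-down and no-go zones.

    The channel runs east-west; "upstream" is westward (toward the
    Saint-Simeon gate).  The slow-down zone spans ~5.4 nm along-channel.
    """
    study = box(-69.95, 48.00, -69.05, 48.50)
    sra = box(-69.600, 48.05, -69.465, 48.45)
    nga = box(-69.38, 48.26, -69.22, 48.45)
    caution = box(-69.45, 48.02, -69.06, 48.48)
    return ZoneSet(
        study_area=study, sra=sra, nga=nga, caution=caution,
        rr_gate_north=LineString([(-69.75, 48.27), (-69.75, 48.50)]),
        rr_gate_south=LineString([(-69.75, 48.00), (-69.75, 48.23)]),
        gate_escoumins=LineString([(-69.10, 48.00), (-69.10, 48.50)]),
        gate_saintsimeon=LineString([(-69.90, 48.00), (-69.90, 48.50)]),
        pilot_station=GeoPoint(-69.43, 48.25),
        nga_chord_up=LineString([(-69.38, 48.26), (-69.38, 48.45)]),
        nga_chord_down=LineString([(-69.22, 48.26), (-69.22, 48.45)]),
    )


def analysis_grid(zones: ZoneSet, cell_m: float = 1000.0) -> GridSpec:
    """A square-cell grid covering the study area in the zone projection."""
    proj = zones.projection
    poly = proj.project_geometry(zones.study_area)
    minx, miny, maxx, maxy = poly.bounds
    ncols = int(math.ceil((maxx - minx) / cell_m))
    nrows = int(math.ceil((maxy - miny) / cell_m))
    return GridSpec(x0=minx, y0=miny, cell_size=cell_m, nrows=nrows, ncols=ncols)


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class ScenarioConfig:
    """Study conditions for a synthetic scenario.

    Speed defaults follow the monitored fleet: cruising (inactive-period)
    speeds 14.1 +/- 2.6 kn, active-period target speeds 11.3 +/- 1.7 kn,
    ~10% strictly compliant transits, >= 93% using the north route when the
    recommendation is in force.  Emission intervals shorten with speed
    (60 s at 6 kn, capped at [2 s, 180 s]) with Bernoulli dropout.
    """

    seed: int = 0
    n_transits: dict = dc_field(default_factory=lambda: {
        (2012, "inactive"): 30,
        **{(y, "active"): 40 for y in (2014, 2015, 2016)},
        **{(y, "inactive"): 20 for y in (2014, 2015, 2016)},
    })
    # speed regimes (knots)
    cruise_mean_kn: float = 14.1
    cruise_sd_kn: float = 2.6
    active_mean_kn: float = 11.3
    active_sd_kn: float = 1.7
    speed_limit_kn: float = 10.0
    p_strict: float = 0.10
    ramp_km: float = 3.0
    # routing behaviour
    p_north_rr: float = 0.93          # north-route share when RR is in force
    p_north_hist: float = 0.90        # historical share otherwise
    p_nga_cross: float = 0.095        # complete crossings of the no-go area
    p_nga_clip: float = 0.03          # corner-clipping (partial-only) tracks
    # vessel mix
    class_probs: dict = dc_field(default_factory=lambda: {
        "cargo": 0.62, "tanker": 0.25, "passenger": 0.13})
    p_international: float = 0.5
    p_pilot_domestic: float = 0.8     # internationals always carry a pilot
    # currents
    tidal_amplitude_kn: float = 2.0
    tidal_period_h: float = 12.42
    tidal_phase_rad: float = 0.0
    current_cell_m: float = 2000.0
    # AIS emission
    emission_ref_s: float = 60.0
    emission_ref_kn: float = 6.0
    emission_min_s: float = 2.0
    emission_max_s: float = 180.0
    dropout_p: float = 0.10
    stw_noise_sd_kn: float = 0.36     # per velocity component
    # numerics
    dt_s: float = 10.0
    window_days: float = 3.0          # transits of a period share a short window

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _period_window(year: int, status: str) -> pd.Timestamp:
    """Representative window start for a (year, status) period: mid-summer
    for active periods, August for the pre-measure year, March otherwise."""
    if status == "active":
        return pd.Timestamp(year=year, month=7, day=10)
    if year <= 2013:
        return pd.Timestamp(year=year, month=8, day=5)
    return pd.Timestamp(year=year, month=3, day=5)


# ---------------------------------------------------------------------------
# Currents


def gen_current_field(cfg: ScenarioConfig, zones: ZoneSet,
                      start: pd.Timestamp, hours: int,
                      cell_m: float | None = None) -> CurrentField:
    """Materialise the tidal current model on an hourly grid.

    u,v are an along-channel semidiurnal sinusoid modulated by a smooth
    spatial gradient (stronger mid-channel), in m/s.
    """
    proj = zones.projection
    grid_poly = proj.project_geometry(zones.study_area)
    minx, miny, maxx, maxy = grid_poly.bounds
    cell = cell_m if cell_m is not None else cfg.current_cell_m
    pad = 2 * cell
    gs = GridSpec(x0=minx - pad, y0=miny - pad, cell_size=cell,
                  nrows=int(math.ceil((maxy - miny + 2 * pad) / cell)),
                  ncols=int(math.ceil((maxx - minx + 2 * pad) / cell)))
    times = pd.date_range(start, periods=hours, freq="1h")
    x = gs.x0 + (np.arange(gs.ncols) + 0.5) * gs.cell_size
    y = gs.y0 + (np.arange(gs.nrows) + 0.5) * gs.cell_size
    xx, yy = np.meshgrid(x, y)
    # spatial modulation: full strength mid-channel, ~40% weaker at the edges
    span_y = max(maxy - miny, 1.0)
    mod = 1.0 - 0.4 * ((yy - (miny + maxy) / 2) / (span_y / 2)) ** 2
    t_h = (times - times[0]).total_seconds().to_numpy() / 3600.0
    t_abs_h = (times - pd.Timestamp("2012-01-01")).total_seconds().to_numpy() / 3600.0
    amp_mps = cfg.tidal_amplitude_kn * KN_TO_MPS
    phase = 2 * np.pi * t_abs_h / cfg.tidal_period_h + cfg.tidal_phase_rad
    tide = np.sin(phase)[:, None, None] * mod[None, :, :] * amp_mps
    u = tide                       # channel runs east-west: u carries the tide
    v = 0.15 * amp_mps * np.cos(phase)[:, None, None] * mod[None, :, :]
    return CurrentField.from_arrays(gs, times, u, v, proj)


# ---------------------------------------------------------------------------
# Whale densities


_SPECIES_HOTSPOTS = {
    # (anchor zone, offset east m, offset north m, sigma m)
    "blue": ("nga", 0.0, 0.0, 6000.0),
    "fin": ("sra", 0.0, 0.0, 6000.0),
    "humpback": ("sra", 3000.0, 2000.0, 7000.0),
    "minke": ("sra", -3000.0, -2000.0, 8000.0),
}


def gen_whale_density(cfg: ScenarioConfig, species: str, zones: ZoneSet,
                      grid: GridSpec):
    """Gaussian-hotspot relative density surface for one species.

    The blue-whale hotspot sits in the no-go area; fin, humpback and minke
    hotspots overlap the slow-down zone, so those species benefit most from
    the speed limit.
    """
    from .risk import WhaleDensitySurface
    if species not in _SPECIES_HOTSPOTS:
        raise ValueError(f"unknown species {species!r}")
    anchor, dx, dy, sigma = _SPECIES_HOTSPOTS[species]
    proj = zones.projection
    c = proj.project_geometry(getattr(zones, anchor)).centroid
    cx, cy = c.x + dx, c.y + dy
    x = grid.x0 + (np.arange(grid.ncols) + 0.5) * grid.cell_size
    y = grid.y0 + (np.arange(grid.nrows) + 0.5) * grid.cell_size
    xx, yy = np.meshgrid(x, y)
    vals = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma ** 2))
    return WhaleDensitySurface(species=species, grid=grid, values=vals)


# ---------------------------------------------------------------------------
# Transits


def _route_waypoints(direction: str, north: bool, nga_mode: str,
                     rng: np.random.Generator, jitter_m: float = 200.0):
    """Lon/lat waypoints, east->west, reversed for downstream transits."""
    if nga_mode == "cross":
        nga_wps = [(-69.20, 48.345), (-69.40, 48.345)]
    elif nga_mode == "clip":
        nga_wps = [(-69.20, 48.285), (-69.40, 48.20)]
    else:
        nga_wps = [(-69.20, 48.16), (-69.40, 48.16)]
    ir = (-69.75, 48.34) if north else (-69.75, 48.14)
    chain = [(-69.94, 48.25), ir, (-69.43, 48.25), *reversed(nga_wps),
             (-69.06, 48.30)]                      # west -> east
    if direction == "upstream":                    # travels east -> west
        chain = list(reversed(chain))
    lat_jit = jitter_m / 111195.0
    out = []
    for i, (lon, lat) in enumerate(chain):
        if 0 < i < len(chain) - 1:
            lat = lat + rng.normal(0.0, lat_jit)
        out.append((lon, lat))
    return out


class _Polyline:
    """A projected waypoint chain with chainage arithmetic."""

    def __init__(self, waypoints_lonlat, proj: LocalProjection):
        xs, ys = proj.forward([w[0] for w in waypoints_lonlat],
                              [w[1] for w in waypoints_lonlat])
        self.xy = np.column_stack([xs, ys])
        d = np.linalg.norm(np.diff(self.xy, axis=0), axis=1)
        self.cum = np.concatenate([[0.0], np.cumsum(d)])
        self.total = float(self.cum[-1])
        self.line = LineString(self.xy)

    def point_at(self, s: float) -> tuple[float, float]:
        p = self.line.interpolate(min(max(s, 0.0), self.total))
        return p.x, p.y

    def direction_at(self, s: float) -> np.ndarray:
        i = int(np.clip(np.searchsorted(self.cum, s) - 1, 0, len(self.cum) - 2))
        d = self.xy[i + 1] - self.xy[i]
        return d / np.linalg.norm(d)

    def zone_interval(self, zone_planar: Polygon) -> tuple[float, float] | None:
        inter = self.line.intersection(zone_planar)
        if inter.is_empty:
            return None
        ss = []
        for g in getattr(inter, "geoms", [inter]):
            if g.geom_type != "LineString":
                continue
            for c in (g.coords[0], g.coords[-1]):
                ss.append(self.line.project(Point(c)))
        if not ss:
            return None
        return float(min(ss)), float(max(ss))


def _speed_profile(s, s_entry, s_exit, v_cruise, v_target, ramp_m):
    """Water speed (kn) at chainage s: cruise outside the zone, target inside,
    linear ramps of length ramp_m before entry and after exit."""
    if s_entry is None:
        return v_cruise
    if s < s_entry - ramp_m or s > s_exit + ramp_m:
        return v_cruise
    if s < s_entry:
        f = (s - (s_entry - ramp_m)) / ramp_m
        return v_cruise + f * (v_target - v_cruise)
    if s <= s_exit:
        return v_target
    f = (s - s_exit) / ramp_m
    return v_target + f * (v_cruise - v_target)


def gen_transits(cfg: ScenarioConfig, zones: ZoneSet | None = None
                 ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame,
                            pd.DataFrame, list[CurrentField]]:
    """Simulate the scenario's vessel transits and their AIS emissions.

    Ships follow waypoint routes at a planted water speed with first-order
    deceleration ramps into the slow-down zone, crabbing across the tidal
    current so the ground track stays on the route.  Fixes are emitted at a
    speed-dependent interval with dropout; reported SOG/COG carry the
    current-model noise budget.

    Returns (fixes, vessels, pilot table, truth log, hourly current fields —
    one per period window).
    """
    zones = zones or synthetic_zones()
    proj = zones.projection
    cal = MeasureCalendar.study_default()
    rng = cfg.rng()
    sra_planar = proj.project_geometry(zones.sra)
    ramp_m = cfg.ramp_km * 1000.0

    fixes_rows, vessel_rows, pilot_rows, truth_rows = [], [], [], []
    fields: list[CurrentField] = []

    # vessel pool
    total_n = sum(cfg.n_transits.values())
    n_vessels = max(3, total_n // 3)
    classes = rng.choice(list(cfg.class_probs), size=n_vessels,
                         p=list(cfg.class_probs.values()))
    flags = np.where(rng.random(n_vessels) < cfg.p_international,
                     "international", "Canadian")
    vessel_ids = [f"V{100000 + i}" for i in range(n_vessels)]
    for vid, cls, fl in zip(vessel_ids, classes, flags):
        vessel_rows.append({"vessel_id": vid, "ship_class": cls, "flag": fl})

    window_s = cfg.window_days * 86400.0
    tcount = 0
    for (year, status), n in sorted(cfg.n_transits.items()):
        if n <= 0:
            continue
        w0 = _period_window(year, status)
        hours = int(cfg.window_days * 24) + 36
        field = gen_current_field(cfg, zones, w0, hours)
        fields.append(field)
        # assign transits to vessels; a vessel's successive passages are kept
        # >= 6.5 h apart so gap-splitting cannot merge them
        v_idx = rng.permutation(n_vessels)[: max(1, min(n_vessels, n))]
        assignment = [int(v_idx[i % len(v_idx)]) for i in range(n)]
        base = rng.uniform(0, max(window_s - 8 * 3600, 3600), size=n)
        starts = np.array(base)
        per_vessel_last: dict[int, float] = {}
        for j in np.argsort(base):
            vi = assignment[j]
            t0 = float(base[j])
            last = per_vessel_last.get(vi)
            if last is not None and t0 < last + 6.5 * 3600:
                t0 = last + 6.5 * 3600
            per_vessel_last[vi] = t0
            starts[j] = t0

        active = status == "active"
        rr_on = active and cal.is_active(w0 + pd.Timedelta(hours=1), "RR") \
            and year >= 2014
        for j in range(n):
            vi = assignment[j]
            vid = vessel_ids[vi]
            t_start = w0 + pd.Timedelta(seconds=float(starts[j]))
            direction = "upstream" if rng.random() < 0.5 else "downstream"
            p_north = cfg.p_north_rr if rr_on else cfg.p_north_hist
            north = rng.random() < p_north
            u = rng.random()
            nga_mode = ("cross" if u < cfg.p_nga_cross
                        else "clip" if u < cfg.p_nga_cross + cfg.p_nga_clip
                        else "avoid")
            v_cruise = float(np.clip(rng.normal(cfg.cruise_mean_kn,
                                                cfg.cruise_sd_kn), 7.0, 24.0))
            strict = False
            if active and rng.random() < cfg.p_strict:
                strict = True
                v_target = float(rng.uniform(8.5, 9.5))
            elif active:
                # truncated normal above the limit: non-strict transits never
                # plant an accidentally compliant zone speed
                lo = (cfg.speed_limit_kn + 0.2 - cfg.active_mean_kn) / cfg.active_sd_kn
                hi = (24.0 - cfg.active_mean_kn) / cfg.active_sd_kn
                v_target = float(truncnorm.rvs(lo, hi, loc=cfg.active_mean_kn,
                                               scale=cfg.active_sd_kn,
                                               random_state=rng))
                v_target = min(v_target, v_cruise)
            else:
                v_target = v_cruise
            pilot = (flags[vi] == "international") or \
                (rng.random() < cfg.p_pilot_domestic)
            tid = f"T{tcount:05d}"
            tcount += 1
            emitted, truth = _simulate_one(
                cfg, zones, proj, sra_planar, field, rng, vid, t_start,
                direction, north, nga_mode, v_cruise, v_target, ramp_m)
            for row in emitted:
                fixes_rows.append(row)
            truth.update({
                "transit_id": tid, "vessel_id": vid, "year": year,
                "active": active, "direction": direction,
                "route_north": north, "nga_mode": nga_mode,
                "pilot_onboard": bool(pilot),
                "ship_class": classes[vi], "flag": flags[vi],
                "planted_cruise_kn": v_cruise, "planted_target_kn": v_target,
                "planted_strict": strict, "t_start": t_start,
            })
            truth_rows.append(truth)
            pilot_rows.append({
                "vessel_id": vid,
                "t_start": t_start - pd.Timedelta(hours=1),
                "t_end": t_start + pd.Timedelta(hours=12),
                "pilot_onboard": bool(pilot),
            })

    fixes = pd.DataFrame(fixes_rows,
                         columns=["vessel_id", "timestamp", "lat", "lon",
                                  "sog", "cog"])
    fixes = fixes.sort_values(["vessel_id", "timestamp"]).reset_index(drop=True)
    return (fixes, pd.DataFrame(vessel_rows), pd.DataFrame(pilot_rows),
            pd.DataFrame(truth_rows), fields)


def _simulate_one(cfg, zones, proj, sra_planar, field, rng, vid, t_start,
                  direction, north, nga_mode, v_cruise, v_target, ramp_m):
    """Integrate one transit; returns (emitted fix rows, truth dict)."""
    wps = _route_waypoints(direction, north, nga_mode, rng)
    line = _Polyline(wps, proj)
    interval = line.zone_interval(sra_planar)
    s_entry, s_exit = interval if interval else (None, None)

    dt = cfg.dt_s
    s = 0.0
    t = 0.0
    next_emit = 0.0
    emitted = []
    d_sra = 0.0
    dv_sra = 0.0
    vmax_sra = 0.0
    noise = cfg.stw_noise_sd_kn
    while s < line.total:
        x, y = line.point_at(s)
        tvec = line.direction_at(s)
        cu, cv = field.interp_uv(x, y, (t_start - field.time_range[0])
                                 .total_seconds() + t)
        cu /= KN_TO_MPS
        cv /= KN_TO_MPS
        v_w = _speed_profile(s, s_entry, s_exit, v_cruise, v_target, ramp_m)
        c_along = cu * tvec[0] + cv * tvec[1]
        c_perp2 = max(cu * cu + cv * cv - c_along * c_along, 0.0)
        v_g = c_along + math.sqrt(max(v_w * v_w - c_perp2, 0.25))
        v_g = max(v_g, 1.0)
        ds = v_g * KN_TO_MPS * dt
        if s_entry is not None and s_exit is not None:
            lo, hi = max(s, s_entry), min(s + ds, s_exit)
            if hi > lo:
                d_sra += hi - lo
                dv_sra += (hi - lo) * v_w
                vmax_sra = max(vmax_sra, v_w)
        if t >= next_emit:
            first = not emitted
            if first or rng.random() >= cfg.dropout_p:
                gvx, gvy = v_g * tvec[0], v_g * tvec[1]
                if noise > 0:
                    gvx += rng.normal(0.0, noise)
                    gvy += rng.normal(0.0, noise)
                sog = math.hypot(gvx, gvy)
                cog = math.degrees(math.atan2(gvx, gvy)) % 360.0
                lon, lat = proj.inverse(x, y)
                emitted.append({
                    "vessel_id": vid,
                    "timestamp": t_start + pd.Timedelta(seconds=round(t, 3)),
                    "lat": float(lat), "lon": float(lon),
                    "sog": sog, "cog": cog,
                })
            gap = min(cfg.emission_max_s,
                      max(cfg.emission_min_s,
                          cfg.emission_ref_s * cfg.emission_ref_kn / max(v_g, 0.1)))
            next_emit = t + gap
        s += ds
        t += dt
    # final fix at the end point (anchors the span of the transit)
    x, y = line.point_at(line.total)
    tvec = line.direction_at(line.total - 1.0)
    cu, cv = field.interp_uv(x, y, (t_start - field.time_range[0])
                             .total_seconds() + t)
    cu /= KN_TO_MPS
    cv /= KN_TO_MPS
    c_along = cu * tvec[0] + cv * tvec[1]
    c_perp2 = max(cu * cu + cv * cv - c_along * c_along, 0.0)
    v_g = max(c_along + math.sqrt(max(v_cruise ** 2 - c_perp2, 0.25)), 1.0)
    gvx, gvy = v_g * tvec[0], v_g * tvec[1]
    if noise > 0:
        gvx += rng.normal(0.0, noise)
        gvy += rng.normal(0.0, noise)
    lon, lat = proj.inverse(x, y)
    emitted.append({
        "vessel_id": vid, "timestamp": t_start + pd.Timedelta(seconds=round(t, 3)),
        "lat": float(lat), "lon": float(lon),
        "sog": math.hypot(gvx, gvy),
        "cog": math.degrees(math.atan2(gvx, gvy)) % 360.0,
    })
    buffer_m = 3000.0
    if s_entry is not None and s_entry > 0:
        ramp_in_buf = min(ramp_m, buffer_m)
        cruise_in_buf = buffer_m - ramp_in_buf
        v_ramp_mean = 0.5 * (v_cruise + v_target)
        buf_dwas = (cruise_in_buf * v_cruise + ramp_in_buf * v_ramp_mean) / buffer_m
        planted_i4 = buf_dwas - v_target
    else:
        planted_i4 = np.nan
    truth = {
        "planted_dwas_kn": dv_sra / d_sra if d_sra > 0 else np.nan,
        "planted_compliant": bool(vmax_sra <= cfg.speed_limit_kn)
        if d_sra > 0 else np.nan,
        "planted_i4_kn": planted_i4,
        "sra_distance_m": d_sra,
        "duration_s": t,
        "n_fixes": len(emitted),
    }
    return emitted, truth


def attach_truth(indicators: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Join recovered per-transit indicators to the generator's truth log.

    Built transits are keyed by (vessel, first-fix time), which equals the
    planted start time when the first emission survives (it always does: the
    first fix is never dropped).
    """
    t = truth.copy()
    t["transit_key"] = (t["vessel_id"].astype(str) + "-" +
                        pd.to_datetime(t["t_start"]).dt.strftime("%Y%m%dT%H%M%S"))
    return indicators.merge(t.drop(columns=["vessel_id"]),
                            left_on="transit_id", right_on="transit_key",
                            suffixes=("", "_truth"))


# ---------------------------------------------------------------------------
# Transit-level statistical scenarios (planted linear-model truths)


def table1_scenario(seed: int = 0, n_years: int = 5, per_year: int = 400,
                    intercept: float = 14.1,
                    active_effect: float | dict = -2.8,
                    resid_sd: float = 2.0, year_sd: float = 0.2) -> pd.DataFrame:
    """Per-transit DWAS with a planted active-measures effect.

    Gaussian linear model: dwas = intercept + effect*active + year intercept
    + residual, balanced active/inactive within each year.  ``active_effect``
    may be a per-year dict (years missing from it get no active transits),
    which plants the inter-annual design.
    """
    rng = np.random.default_rng(seed)
    years = np.arange(2012, 2012 + n_years)
    year_eff = dict(zip(years.tolist(), rng.normal(0.0, year_sd, n_years)))
    rows = []
    for y in years:
        if isinstance(active_effect, dict):
            eff = active_effect.get(int(y))
            active = (rng.random(per_year) < 0.5) if eff is not None \
                else np.zeros(per_year, dtype=bool)
            eff = eff if eff is not None else 0.0
        else:
            eff = active_effect
            active = rng.random(per_year) < 0.5
        d = intercept + eff * active + year_eff[int(y)] \
            + rng.normal(0.0, resid_sd, per_year)
        for a, dw in zip(active, d):
            rows.append({"year": int(y), "active": bool(a), "dwas": float(dw)})
    return pd.DataFrame(rows)


def table5_scenario(seed: int = 0, n: int = 2000, intercept: float = 12.5,
                    pilot_effect: float = -0.8, flag_effect: float = -0.1,
                    cargo_effect: float = 0.1, passenger_effect: float = 0.2,
                    direction_effect: float = -0.8, resid_sd: float = 1.5,
                    year_sd: float = 0.2, p_pilot: float = 0.6) -> pd.DataFrame:
    """Active-period transits with planted covariate effects on DWAS.

    Reference levels (in the intercept): tanker, no pilot, Canadian flag,
    upstream direction.
    """
    rng = np.random.default_rng(seed)
    years = np.array([2014, 2015, 2016])
    year_eff = dict(zip(years.tolist(), rng.normal(0.0, year_sd, len(years))))
    yr = rng.choice(years, size=n)
    pilot = rng.random(n) < p_pilot
    intl = rng.random(n) < 0.5
    cls = rng.choice(["cargo", "passenger", "tanker"], size=n,
                     p=[0.6, 0.15, 0.25])
    down = rng.random(n) < 0.5
    d = (intercept + pilot_effect * pilot + flag_effect * intl
         + cargo_effect * (cls == "cargo") + passenger_effect * (cls == "passenger")
         + direction_effect * down
         + np.array([year_eff[int(y)] for y in yr])
         + rng.normal(0.0, resid_sd, n))
    return pd.DataFrame({
        "year": yr, "active": True, "dwas": d,
        "pilot_onboard": pilot,
        "flag": np.where(intl, "international", "Canadian"),
        "ship_class": cls,
        "direction": np.where(down, "downstream", "upstream"),
    })
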