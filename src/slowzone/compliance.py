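"""The compliance-indicator portfolio for voluntary slow-down measures.

Seven indicators summarise how shipping responds to the measures:

* I1 — strict compliance: share of transits whose every in-zone fix is at or
  below the speed limit (speed through water).
* I2 — no-go area usage: share of transits crossing the no-go area,
  split into partial and complete users.
* I3 — route compliance: share of transits passing north of Ile Rouge.
* I4 — slow-down effort: speed drop between a 3-km pre-entry buffer and the
  slow-down zone.
* I5 — distance-weighted average speed (DWAS) per transit in the zone.
* I6 — share of total in-zone distance travelled above the limit.
* I7 — distance-weighted mean speed of that non-compliant distance.

Distance weighting compensates the sampling bias of AIS: report intervals
shorten at low speed, so a per-fix average over-represents slow segments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Polygon
from shapely.prepared import prep

from .ais import Transit, segmentize
from .geo import (LocalProjection, MeasureCalendar, ZoneSet,
                  clip_segment_to_polygon)

SPEED_LIMIT_KN = 10.0
BUFFER_M = 3000.0


class _PlanarZone:
    """A zone polygon projected once, with prepared predicates."""

    def __init__(self, poly: Polygon, projection: LocalProjection):
        self.projection = projection
        self.planar = projection.project_geometry(poly)
        self._prepared = prep(self.planar.buffer(1e-6))

    def segment_parts(self, a_xy, b_xy):
        seg = LineString([a_xy, b_xy])
        if self._prepared.contains_properly(seg):
            return [(0.0, 1.0, 1.0, True)]
        if not self._prepared.intersects(seg):
            return [(0.0, 1.0, 1.0, False)]
        return clip_segment_to_polygon(a_xy, b_xy, self.planar)

    def inside_fractions(self, xy: np.ndarray) -> np.ndarray:
        """In-zone length fraction of each consecutive segment of xy."""
        out = np.empty(len(xy) - 1)
        for i in range(len(xy) - 1):
            out[i] = sum(p[2] for p in self.segment_parts(xy[i], xy[i + 1]) if p[3])
        return out


def _transit_xy(tr: Transit, projection: LocalProjection) -> np.ndarray:
    x, y = projection.forward(tr.fixes["lon"].to_numpy(),
                              tr.fixes["lat"].to_numpy())
    return np.column_stack([x, y])


def _inzone_weights(tr: Transit, zone: Polygon, projection: LocalProjection):
    """Per-segment (in-zone length nm, speed kn) for a transit."""
    segs = segmentize(tr)
    pz = _PlanarZone(zone, projection)
    xy = _transit_xy(tr, projection)
    frac = pz.inside_fractions(xy)
    d = segs["length_nm"].to_numpy() * frac
    return d, segs["speed_kn"].to_numpy()


def dwas(tr: Transit, zone: Polygon, projection: LocalProjection) -> float:
    """Distance-weighted average speed (knots) of a transit inside a zone (I5).

    Each segment's speed is weighted by its in-zone geodesic length.  Raises
    if the transit has no in-zone distance.
    """
    d, v = _inzone_weights(tr, zone, projection)
    total = d.sum()
    if total <= 0:
        raise ValueError(f"transit {tr.transit_id} has no in-zone distance")
    return float((d * v).sum() / total)


def strict_compliance(transits, zone: Polygon, projection: LocalProjection,
                      limit: float = SPEED_LIMIT_KN) -> float | None:
    """I1: percent of transits with *every* in-zone fix at or below the limit.

    One fix above the limit makes the whole transit non-compliant.  Transits
    with no in-zone fix are excluded from the denominator.  Returns None
    (absent, not 0%) when no transit qualifies.
    """
    n, ok = 0, 0
    for tr in transits:
        flags = _inzone_fix_mask(tr, zone, projection)
        if not flags.any():
            continue
        speed = _fix_speeds(tr)[flags]
        n += 1
        if (speed <= limit).all():
            ok += 1
    return None if n == 0 else 100.0 * ok / n


def _fix_speeds(tr: Transit) -> np.ndarray:
    col = "stw" if "stw" in tr.fixes.columns else "sog"
    return tr.fixes[col].to_numpy()


def _inzone_fix_mask(tr: Transit, zone: Polygon,
                     projection: LocalProjection) -> np.ndarray:
    pz = _PlanarZone(zone, projection)
    xy = _transit_xy(tr, projection)
    import shapely
    return shapely.contains_xy(pz.planar.buffer(1e-6), xy[:, 0], xy[:, 1])


def _entry_chainage(tr: Transit, zone: Polygon, projection: LocalProjection):
    """(cumulative lengths, per-seg parts, entry chainage in nm) along track."""
    segs = segmentize(tr)
    pz = _PlanarZone(zone, projection)
    xy = _transit_xy(tr, projection)
    lengths = segs["length_nm"].to_numpy()
    cum = np.concatenate([[0.0], np.cumsum(lengths)])
    parts = [pz.segment_parts(xy[i], xy[i + 1]) for i in range(len(xy) - 1)]
    entry = None
    for i, pp in enumerate(parts):
        for t0, t1, fr, inside in pp:
            if inside:
                entry = cum[i] + t0 * lengths[i]
                break
        if entry is not None:
            break
    return segs, lengths, cum, parts, entry


def slowdown_effort(tr: Transit, zone: Polygon, projection: LocalProjection,
                    buffer_m: float = BUFFER_M) -> float | None:
    """I4: DWAS in the pre-entry buffer minus DWAS inside the zone (knots).

    The buffer is measured along-track backwards from the first zone entry
    (entering a zone is a track property, not a Euclidean one).  Positive
    values mean the ship slowed down.  None when the track has no coverage
    in the buffer window.
    """
    segs, lengths, cum, parts, entry = _entry_chainage(tr, zone, projection)
    if entry is None:
        return None
    buf_nm = buffer_m / 1852.0
    w0, w1 = entry - buf_nm, entry
    v = segs["speed_kn"].to_numpy()
    # overlap of each segment [cum[i], cum[i+1]] with the buffer window
    d_buf = np.clip(np.minimum(cum[1:], w1) - np.maximum(cum[:-1], w0), 0.0, None)
    if d_buf.sum() <= 0:
        return None
    dwas_buf = float((d_buf * v).sum() / d_buf.sum())
    d_in = np.array([sum(p[2] for p in pp if p[3]) for pp in parts]) * lengths
    if d_in.sum() <= 0:
        return None
    dwas_in = float((d_in * v).sum() / d_in.sum())
    return dwas_buf - dwas_in


def noncompliance_profile(tr: Transit, zone: Polygon,
                          projection: LocalProjection,
                          limit: float = SPEED_LIMIT_KN
                          ) -> tuple[float, float | None]:
    """(I6, I7) for one transit: percent of in-zone distance above the limit,
    and the distance-weighted mean speed of that distance (None when I6=0)."""
    d, v = _inzone_weights(tr, zone, projection)
    total = d.sum()
    if total <= 0:
        raise ValueError(f"transit {tr.transit_id} has no in-zone distance")
    over = v > limit
    i6 = 100.0 * d[over].sum() / total
    i7 = float((d[over] * v[over]).sum() / d[over].sum()) if over.any() and d[over].sum() > 0 else None
    return float(i6), i7


def nga_usage(transits, zones: ZoneSet, projection: LocalProjection | None = None,
              limit: float = SPEED_LIMIT_KN) -> dict:
    """I2 and the no-go-area speed check.

    A transit is a *partial* user iff its path intersects the no-go area; a
    *complete* user iff, between the area's upstream and downstream crossing
    chords, its entire path stays inside the area.  Returns percentages over
    all transits plus the DWAS of complete users.
    """
    projection = projection or zones.projection
    pz = _PlanarZone(zones.nga, projection)
    partial = complete = 0
    dwas_complete = []
    for tr in transits:
        xy = _transit_xy(tr, projection)
        path = LineString(xy)
        if not path.intersects(pz.planar):
            continue
        partial += 1
        if _is_complete_user(path, pz, zones, projection):
            complete += 1
            try:
                dwas_complete.append(dwas(tr, zones.nga, projection))
            except ValueError:
                pass
    n = len(transits)
    return {
        "n": n,
        "pct_partial": 100.0 * partial / n if n else None,
        "pct_complete": 100.0 * complete / n if n else None,
        "dwas_complete": dwas_complete,
    }


def _is_complete_user(path: LineString, pz: _PlanarZone, zones: ZoneSet,
                      projection: LocalProjection) -> bool:
    if zones.nga_chord_up is None or zones.nga_chord_down is None:
        # fall back: complete iff every in-area crossing is a single traversal
        # entirely within the area between first entry and last exit
        inter = path.intersection(pz.planar)
        return inter.length >= 0.99 * path.intersection(pz.planar.convex_hull).length
    c_up = projection.project_geometry(zones.nga_chord_up)
    c_dn = projection.project_geometry(zones.nga_chord_down)
    if not (path.intersects(c_up) and path.intersects(c_dn)):
        return False
    s_up = path.project(path.intersection(c_up).centroid)
    s_dn = path.project(path.intersection(c_dn).centroid)
    s0, s1 = sorted([s_up, s_dn])
    # sample the sub-path between the chords and require it to stay inside
    ss = np.linspace(s0, s1, 50)
    probe = pz.planar.buffer(1.0)  # 1 m tolerance
    return all(probe.covers(path.interpolate(s)) for s in ss)


def rr_compliance(transits, zones: ZoneSet,
                  projection: LocalProjection | None = None
                  ) -> tuple[float | None, pd.DataFrame]:
    """I3: percent of classifiable transits crossing the north reference gate.

    Transits crossing both gates or neither are logged unclassifiable and
    excluded from the denominator.
    """
    projection = projection or zones.projection
    g_n = projection.project_geometry(zones.rr_gate_north)
    g_s = projection.project_geometry(zones.rr_gate_south)
    north = classifiable = 0
    log = []
    for tr in transits:
        path = LineString(_transit_xy(tr, projection))
        hits_n, hits_s = path.intersects(g_n), path.intersects(g_s)
        if hits_n == hits_s:
            log.append({"transit": tr.transit_id,
                        "reason": "crosses_both_gates" if hits_n else "crosses_no_gate"})
            continue
        classifiable += 1
        north += int(hits_n)
    pct = 100.0 * north / classifiable if classifiable else None
    return pct, pd.DataFrame(log, columns=["transit", "reason"])


# ---------------------------------------------------------------------------
# Per-transit table and portfolio


def transit_indicators(transits, zones: ZoneSet,
                       limit: float = SPEED_LIMIT_KN,
                       buffer_m: float = BUFFER_M) -> pd.DataFrame:
    """Long-format per-transit indicator table (the analysis workhorse).

    One row per transit with DWAS, strict-compliance flag, I4, I6, I7 in the
    slow-down zone, no-go-area usage flags and the north-route flag, plus the
    covariates the speed models use.
    """
    projection = zones.projection
    pz_sra = _PlanarZone(zones.sra, projection)
    pz_nga = _PlanarZone(zones.nga, projection)
    g_n = projection.project_geometry(zones.rr_gate_north)
    g_s = projection.project_geometry(zones.rr_gate_south)
    rows = []
    for tr in transits:
        xy = _transit_xy(tr, projection)
        path = LineString(xy)
        row = {
            "transit_id": tr.transit_id, "vessel_id": tr.vessel_id,
            "year": tr.year, "active": tr.measures_active,
            "ship_class": tr.ship_class, "flag": tr.flag,
            "pilot_onboard": tr.pilot_onboard, "direction": tr.direction,
            "dwas_sra": np.nan, "compliant": np.nan, "i4_slowdown": np.nan,
            "i6_pct": np.nan, "i7_kn": np.nan, "sra_dist_nm": 0.0,
            "sra_noncomp_dist_nm": 0.0,
            "nga_partial": False, "nga_complete": False,
            "north_of_ir": np.nan,
        }
        try:
            d, v = _inzone_weights(tr, zones.sra, projection)
            total = d.sum()
        except ValueError:
            total = 0.0
        if total > 0:
            row["dwas_sra"] = float((d * v).sum() / total)
            row["sra_dist_nm"] = float(total)
            over = v > limit
            row["sra_noncomp_dist_nm"] = float(d[over].sum())
            flags = _inzone_fix_mask(tr, zones.sra, projection)
            if flags.any():
                row["compliant"] = bool((_fix_speeds(tr)[flags] <= limit).all())
            i6, i7 = noncompliance_profile(tr, zones.sra, projection, limit)
            row["i6_pct"], row["i7_kn"] = i6, i7 if i7 is not None else np.nan
            sd = slowdown_effort(tr, zones.sra, projection, buffer_m)
            row["i4_slowdown"] = sd if sd is not None else np.nan
        if path.intersects(pz_nga.planar):
            row["nga_partial"] = True
            row["nga_complete"] = _is_complete_user(path, pz_nga, zones, projection)
        hits_n, hits_s = path.intersects(g_n), path.intersects(g_s)
        if hits_n != hits_s:
            row["north_of_ir"] = bool(hits_n)
        rows.append(row)
    return pd.DataFrame(rows)


def build_portfolio(transits, zones: ZoneSet, cal: MeasureCalendar,
                    limit: float = SPEED_LIMIT_KN,
                    indicators: pd.DataFrame | None = None) -> pd.DataFrame:
    """Aggregate the indicator portfolio per (year, active/inactive) period.

    Mirrors the monitoring report layout: transit and vessel counts, I1, the
    pooled I6 (share of all in-zone distance above the limit), the pooled I7,
    median I5 and the share of transits that slowed by >= 1 kn (I4).  Empty
    periods get counts of 0 and absent indicators.
    """
    ind = indicators if indicators is not None else transit_indicators(
        transits, zones, limit)
    rows = []
    years = sorted(set(ind["year"])) if len(ind) else cal.years()
    for year in years:
        for active in (True, False):
            sel = ind[(ind["year"] == year) & (ind["active"] == active)]
            sra = sel[sel["sra_dist_nm"] > 0]
            row = {"year": year, "status": "active" if active else "inactive",
                   "n_transits": int(len(sel)),
                   "n_vessels": int(sel["vessel_id"].nunique())}
            if len(sra):
                comp = sra["compliant"].dropna()
                row["I1_pct"] = 100.0 * comp.mean() if len(comp) else np.nan
                total_d = sra["sra_dist_nm"].sum()
                nc_d = sra["sra_noncomp_dist_nm"].sum()
                row["I6_pct"] = 100.0 * nc_d / total_d
                w = sra["sra_noncomp_dist_nm"]
                row["I7_kn"] = (float((w * sra["i7_kn"].fillna(0)).sum() / nc_d)
                                if nc_d > 0 else np.nan)
                row["I5_median_kn"] = float(sra["dwas_sra"].median())
                i4 = sra["i4_slowdown"].dropna()
                row["I4_pct_ge_1kn"] = 100.0 * (i4 >= 1.0).mean() if len(i4) else np.nan
            else:
                row.update({"I1_pct": np.nan, "I6_pct": np.nan, "I7_kn": np.nan,
                            "I5_median_kn": np.nan, "I4_pct_ge_1kn": np.nan})
            rows.append(row)
    return pd.DataFrame(rows)
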