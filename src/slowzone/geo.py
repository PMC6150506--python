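"""Geometry, geodesy, grid and measure-calendar primitives.

All positions are WGS-style geographic coordinates (degrees east / degrees
north) treated on a spherical Earth; planar operations (polygon clipping,
gridding) go through a local azimuthal equal-area projection centred on the
study area, so that distances and areas are faithful at estuary scale.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon, mapping, shape
from shapely.ops import transform as _shapely_transform

EARTH_RADIUS_KM = 6371.0088
KM_PER_NM = 1.852
M_PER_NM = 1852.0
MPS_PER_KNOT = 0.514444


class GeoPoint(NamedTuple):
    """A geographic position: longitude (deg E), latitude (deg N)."""

    lon: float
    lat: float

    def validate(self) -> "GeoPoint":
        if not (-180.0 <= self.lon <= 180.0) or not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"invalid geographic coordinates: {self}")
        return self


def geodesic_distance(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance in nautical miles on a sphere of radius 6371.0088 km.

    Uses the atan2 form of the great-circle formula, which is accurate at
    both short and antipodal ranges.
    """
    lon1, lat1, lon2, lat2 = map(math.radians, (a[0], a[1], b[0], b[1]))
    dlon = lon2 - lon1
    s1, c1 = math.sin(lat1), math.cos(lat1)
    s2, c2 = math.sin(lat2), math.cos(lat2)
    y = math.hypot(c2 * math.sin(dlon), c1 * s2 - s1 * c2 * math.cos(dlon))
    x = s1 * s2 + c1 * c2 * math.cos(dlon)
    return EARTH_RADIUS_KM * math.atan2(y, x) / KM_PER_NM


class LocalProjection:
    """Spherical Lambert azimuthal equal-area projection centred on (lon0, lat0).

    forward() maps degrees to metres in a plane tangent at the centre;
    inverse() maps back.  Distortion is negligible over a ~100 km study area.
    """

    def __init__(self, lon0: float, lat0: float):
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        self._l0 = math.radians(lon0)
        self._p0 = math.radians(lat0)
        self._R = EARTH_RADIUS_KM * 1000.0

    def forward(self, lon, lat):
        lam = np.radians(np.asarray(lon, dtype=float)) - self._l0
        phi = np.radians(np.asarray(lat, dtype=float))
        s0, c0 = math.sin(self._p0), math.cos(self._p0)
        sp, cp = np.sin(phi), np.cos(phi)
        denom = 1.0 + s0 * sp + c0 * cp * np.cos(lam)
        k = np.sqrt(2.0 / denom)
        x = self._R * k * cp * np.sin(lam)
        y = self._R * k * (c0 * sp - s0 * cp * np.cos(lam))
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float) / self._R
        y = np.asarray(y, dtype=float) / self._R
        rho = np.hypot(x, y)
        c = 2.0 * np.arcsin(np.clip(rho / 2.0, -1.0, 1.0))
        s0, c0 = math.sin(self._p0), math.cos(self._p0)
        with np.errstate(invalid="ignore"):
            sc, cc = np.sin(c), np.cos(c)
            phi = np.where(
                rho > 0,
                np.arcsin(np.clip(cc * s0 + np.where(rho > 0, y * sc * c0 / np.where(rho > 0, rho, 1.0), 0.0), -1, 1)),
                self._p0,
            )
            lam = np.where(
                rho > 0,
                np.arctan2(x * sc, rho * c0 * cc - y * s0 * sc),
                0.0,
            )
        return np.degrees(lam + self._l0), np.degrees(phi)

    def project_geometry(self, geom):
        return _shapely_transform(lambda lon, lat: self.forward(lon, lat), geom)

    def unproject_geometry(self, geom):
        return _shapely_transform(lambda x, y: self.inverse(x, y), geom)


# ---------------------------------------------------------------------------
# Zones

ZONE_IDS = ("SRA", "NGA", "CAUTION", "STUDY_AREA", "RR_GATE_N", "RR_GATE_S",
            "GATE_ESC", "GATE_STS")


@dataclass
class ZoneSet:
    """The management-zone geometries of the voluntary measures.

    Polygons (lon/lat): speed reduction area, no-go area, caution area and the
    overall study area.  Line transects: the two reference gates whose crossing
    classifies a track as north vs south of Ile Rouge, and the two transit-time
    gates (Les Escoumins / Saint-Simeon).  Optional chords across the no-go
    area's upstream/downstream ends support the "complete user" test.
    """

    study_area: Polygon
    sra: Polygon
    nga: Polygon
    caution: Polygon
    rr_gate_north: LineString
    rr_gate_south: LineString
    gate_escoumins: LineString
    gate_saintsimeon: LineString
    pilot_station: GeoPoint
    nga_chord_up: LineString | None = None
    nga_chord_down: LineString | None = None

    def __post_init__(self):
        for name in ("study_area", "sra", "nga", "caution"):
            poly = getattr(self, name)
            if poly.is_empty or not poly.is_valid or poly.area <= 0:
                raise ValueError(f"zone polygon {name!r} is degenerate")
        if not self.study_area.buffer(1e-9).contains(self.sra):
            raise ValueError("SRA must lie within the study area")
        if not self.study_area.buffer(1e-9).contains(self.nga):
            raise ValueError("NGA must lie within the study area")
        if self.rr_gate_north.intersects(self.rr_gate_south):
            raise ValueError("route gates must not intersect each other")

    @property
    def projection(self) -> LocalProjection:
        c = self.study_area.centroid
        return LocalProjection(c.x, c.y)

    def to_geojson(self, path) -> None:
        feats = []
        geoms = {
            "STUDY_AREA": self.study_area, "SRA": self.sra, "NGA": self.nga,
            "CAUTION": self.caution, "RR_GATE_N": self.rr_gate_north,
            "RR_GATE_S": self.rr_gate_south, "GATE_ESC": self.gate_escoumins,
            "GATE_STS": self.gate_saintsimeon,
        }
        if self.nga_chord_up is not None:
            geoms["NGA_CHORD_UP"] = self.nga_chord_up
        if self.nga_chord_down is not None:
            geoms["NGA_CHORD_DOWN"] = self.nga_chord_down
        for zid, g in geoms.items():
            feats.append({"type": "Feature", "properties": {"zone_id": zid},
                          "geometry": mapping(g)})
        feats.append({"type": "Feature", "properties": {"zone_id": "PILOT_STATION"},
                      "geometry": mapping(Point(self.pilot_station))})
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)

    @classmethod
    def from_geojson(cls, path) -> "ZoneSet":
        with open(path) as fh:
            fc = json.load(fh)
        geoms = {f["properties"]["zone_id"]: shape(f["geometry"])
                 for f in fc["features"]}
        ps = geoms["PILOT_STATION"]
        return cls(
            study_area=geoms["STUDY_AREA"], sra=geoms["SRA"], nga=geoms["NGA"],
            caution=geoms["CAUTION"], rr_gate_north=geoms["RR_GATE_N"],
            rr_gate_south=geoms["RR_GATE_S"], gate_escoumins=geoms["GATE_ESC"],
            gate_saintsimeon=geoms["GATE_STS"],
            pilot_station=GeoPoint(ps.x, ps.y),
            nga_chord_up=geoms.get("NGA_CHORD_UP"),
            nga_chord_down=geoms.get("NGA_CHORD_DOWN"),
        )


# ---------------------------------------------------------------------------
# Segment clipping


class ClippedPart(NamedTuple):
    t0: float          # parametric start along the segment, in [0, 1]
    t1: float
    fraction: float    # share of the segment's length, t1 - t0
    inside: bool


def clip_segment_to_polygon(a, b, poly: Polygon,
                            projection: LocalProjection | None = None
                            ) -> list[ClippedPart]:
    """Split the segment a->b at polygon boundary crossings.

    Returns ordered parts whose fractions sum to 1; each part is flagged
    inside/outside by its midpoint.  Coordinates may be geographic (pass the
    projection used to planarise the polygon) or already planar.
    """
    if poly.is_empty or not poly.is_valid or poly.area <= 0:
        raise ValueError("degenerate polygon")
    if projection is not None:
        ax, ay = projection.forward(a[0], a[1])
        bx, by = projection.forward(b[0], b[1])
        poly = projection.project_geometry(poly)
        a, b = (float(ax), float(ay)), (float(bx), float(by))
    seg = LineString([a, b])
    if seg.length == 0:
        raise ValueError("zero-length segment")
    ts = {0.0, 1.0}
    inter = poly.boundary.intersection(seg)
    stack = [inter]
    while stack:
        g = stack.pop()
        if g.is_empty:
            continue
        if g.geom_type == "Point":
            ts.add(seg.project(g) / seg.length)
        elif g.geom_type == "LineString":
            for c in g.coords:
                ts.add(seg.project(Point(c)) / seg.length)
        else:  # Multi* / GeometryCollection
            stack.extend(g.geoms)
    cuts = sorted(min(max(t, 0.0), 1.0) for t in ts)
    parts = []
    probe = poly.buffer(1e-9)
    for t0, t1 in zip(cuts[:-1], cuts[1:]):
        if t1 - t0 <= 1e-12:
            continue
        mid = seg.interpolate((t0 + t1) / 2.0, normalized=True)
        parts.append(ClippedPart(t0, t1, t1 - t0, probe.covers(mid)))
    # re-normalise away the dropped slivers so fractions sum to exactly 1
    total = sum(p.fraction for p in parts)
    return [ClippedPart(p.t0, p.t1, p.fraction / total, p.inside) for p in parts]


def inside_fraction(a, b, poly, projection=None) -> float:
    """Fraction of segment a->b lying inside the polygon."""
    return sum(p.fraction for p in clip_segment_to_polygon(a, b, poly, projection)
               if p.inside)


# ---------------------------------------------------------------------------
# Measure calendar


@dataclass(frozen=True)
class CalendarEntry:
    year: int
    start: _dt.date
    end: _dt.date
    measures: frozenset

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("calendar entry start after end")
        if self.start.year != self.year or self.end.year != self.year:
            raise ValueError("calendar entry dates must fall in its year")


@dataclass
class MeasureCalendar:
    """Day-resolution calendar of which voluntary measures are in force."""

    entries: list[CalendarEntry] = field(default_factory=list)

    def __post_init__(self):
        by_year: dict[int, list[CalendarEntry]] = {}
        for e in self.entries:
            if "RR" in e.measures and e.year < 2014:
                raise ValueError("the recommended route was not in force before 2014")
            by_year.setdefault(e.year, []).append(e)
        for year, es in by_year.items():
            es = sorted(es, key=lambda e: e.start)
            for e1, e2 in zip(es[:-1], es[1:]):
                if e2.start <= e1.end:
                    raise ValueError(f"overlapping calendar entries in {year}")

    def is_active(self, t, measure: str) -> bool:
        d = pd.Timestamp(t).date()
        for e in self.entries:
            if e.year == d.year and e.start <= d <= e.end and measure in e.measures:
                return True
        return False

    def any_active(self, t) -> bool:
        d = pd.Timestamp(t).date()
        return any(e.year == d.year and e.start <= d <= e.end for e in self.entries)

    def years(self) -> list[int]:
        return sorted({e.year for e in self.entries})

    def to_csv(self, path) -> None:
        rows = [{"year": e.year, "start_date": e.start.isoformat(),
                 "end_date": e.end.isoformat(),
                 "measures": ";".join(sorted(e.measures))} for e in self.entries]
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MeasureCalendar":
        df = pd.read_csv(path)
        entries = [CalendarEntry(int(r.year),
                                 _dt.date.fromisoformat(str(r.start_date)),
                                 _dt.date.fromisoformat(str(r.end_date)),
                                 frozenset(str(r.measures).split(";")))
                   for r in df.itertuples()]
        return cls(entries)

    @classmethod
    def study_default(cls) -> "MeasureCalendar":
        """The historical calendar: SRA+NGA from June 2013, May-October with
        the recommended route added from 2014 through 2016."""
        entries = [CalendarEntry(2013, _dt.date(2013, 6, 1), _dt.date(2013, 10, 31),
                                 frozenset({"SRA", "NGA"}))]
        for year in (2014, 2015, 2016):
            entries.append(CalendarEntry(year, _dt.date(year, 5, 1),
                                         _dt.date(year, 10, 31),
                                         frozenset({"SRA", "NGA", "RR"})))
        return cls(entries)


def is_measure_active(t, measure: str, cal: MeasureCalendar) -> bool:
    """True iff the measure is in force at timestamp t."""
    return cal.is_active(t, measure)


# ---------------------------------------------------------------------------
# Analysis grid


@dataclass(frozen=True)
class GridSpec:
    """A regular planar grid: origin (m), square cell size (m), shape."""

    x0: float
    y0: float
    cell_size: float
    nrows: int
    ncols: int

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def x_edges(self) -> np.ndarray:
        return self.x0 + self.cell_size * np.arange(self.ncols + 1)

    @property
    def y_edges(self) -> np.ndarray:
        return self.y0 + self.cell_size * np.arange(self.nrows + 1)

    def cell_index(self, x: float, y: float) -> tuple[int, int]:
        col = int(math.floor((x - self.x0) / self.cell_size))
        row = int(math.floor((y - self.y0) / self.cell_size))
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (self.x0 + (col + 0.5) * self.cell_size,
                self.y0 + (row + 0.5) * self.cell_size)

    def contains(self, x: float, y: float) -> bool:
        r, c = self.cell_index(x, y)
        return 0 <= r < self.nrows and 0 <= c < self.ncols
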