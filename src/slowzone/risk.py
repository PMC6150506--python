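"""Lethality model, gridded co-occurrence risk and effectiveness.

The probability that a ship strike is lethal to a whale rises with ship
speed following a two-parameter logistic P(v) = 1/(1+exp(-(b0+b1*v))),
calibrated here from two published anchor points on the speed-lethality
curve.  Relative lethal-strike risk per grid cell is whale density times
lethality-weighted traffic distance; *effectiveness* of a measure is the
percent reduction of summed risk between a baseline and an active period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Polygon

from .ais import Transit, segmentize
from .geo import GridSpec, LocalProjection

#: published anchor points: ~31% lethality at the 10-kn limit, 50% at 11.8 kn
DEFAULT_ANCHORS = ((10.0, 0.31), (11.8, 0.50))
SPECIES = ("minke", "fin", "humpback", "blue")


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


@dataclass(frozen=True)
class LethalityModel:
    """Logistic speed-to-lethality curve on the logit scale."""

    beta0: float
    beta1: float

    def __post_init__(self):
        if self.beta1 <= 0:
            raise ValueError("lethality must increase with speed (beta1 > 0)")

    def probability(self, v) -> np.ndarray | float:
        v = np.asarray(v, dtype=float)
        p = 1.0 / (1.0 + np.exp(-(self.beta0 + self.beta1 * v)))
        return float(p) if p.ndim == 0 else p


def calibrate_lethality(anchors=DEFAULT_ANCHORS) -> LethalityModel:
    """Unique logistic through two (speed, probability) anchor points."""
    (v1, p1), (v2, p2) = anchors
    if v1 == v2:
        raise ValueError("anchor speeds must differ")
    if not (0 < p1 < 1 and 0 < p2 < 1) or p1 == p2:
        raise ValueError("anchor probabilities must be distinct and in (0, 1)")
    beta1 = (_logit(p2) - _logit(p1)) / (v2 - v1)
    beta0 = _logit(p1) - beta1 * v1
    return LethalityModel(beta0=beta0, beta1=beta1)


def lethality_probability(m: LethalityModel, v) -> float | np.ndarray:
    """P(strike is lethal) at ship speed v knots."""
    return m.probability(v)


# ---------------------------------------------------------------------------
# Gridded surfaces


@dataclass
class WhaleDensitySurface:
    """Relative whale density per grid cell, normalised to sum to one."""

    species: str
    grid: GridSpec
    values: np.ndarray           # (nrows, ncols), >= 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.nrows, self.grid.ncols):
            raise ValueError("density shape does not match the grid")
        if (self.values < 0).any():
            raise ValueError("densities must be non-negative")
        total = self.values.sum()
        if total <= 0:
            raise ValueError("density surface is identically zero")
        self.values = self.values / total

    def to_csv(self, path) -> None:
        rows, cols = np.nonzero(self.values >= 0)
        pd.DataFrame({"y_index": rows, "x_index": cols,
                      "value": self.values[rows, cols]}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, species: str, grid: GridSpec) -> "WhaleDensitySurface":
        df = pd.read_csv(path)
        vals = np.zeros((grid.nrows, grid.ncols))
        vals[df["y_index"].to_numpy(), df["x_index"].to_numpy()] = df["value"].to_numpy()
        return cls(species, grid, vals)


@dataclass
class TrafficSurface:
    """Per-cell traffic: total track distance (nm) and lethality-weighted
    distance sum_i d_i * P(v_i), plus the number of contributing transits."""

    grid: GridSpec
    distance_nm: np.ndarray
    weighted_nm: np.ndarray
    n_transits: int
    skipped_segments: int = 0


def _split_on_grid(x0, y0, x1, y1, grid: GridSpec):
    """Yield (row, col, fraction) of the planar segment across grid cells."""
    dx, dy = x1 - x0, y1 - y0
    ts = {0.0, 1.0}
    if dx != 0.0:
        t = (grid.x_edges - x0) / dx
        ts.update(t[(t > 0) & (t < 1)].tolist())
    if dy != 0.0:
        t = (grid.y_edges - y0) / dy
        ts.update(t[(t > 0) & (t < 1)].tolist())
    cuts = sorted(ts)
    for a, b in zip(cuts[:-1], cuts[1:]):
        if b - a <= 1e-12:
            continue
        tm = 0.5 * (a + b)
        r, c = grid.cell_index(x0 + tm * dx, y0 + tm * dy)
        yield r, c, b - a


def traffic_surface(transits, grid: GridSpec, model: LethalityModel,
                    projection: LocalProjection,
                    speed_basis: str = "STW") -> TrafficSurface:
    """Accumulate per-cell distance and lethality-weighted distance.

    Each track segment is split exactly across the cells it crosses; a cell
    receives the segment's in-cell geodesic length d and d*P(speed).  Speed
    basis is STW (hydrodynamic encounter speed) by default, SOG optionally.
    Segments falling outside the grid are counted and skipped.
    """
    if speed_basis not in ("STW", "SOG"):
        raise ValueError("speed_basis must be 'STW' or 'SOG'")
    dist = np.zeros((grid.nrows, grid.ncols))
    weighted = np.zeros_like(dist)
    skipped = 0
    for tr in transits:
        segs = segmentize(tr)
        if speed_basis == "SOG":
            fx = tr.fixes["sog"].to_numpy()
            segs["speed_kn"] = 0.5 * (fx[:-1] + fx[1:])
        x0, y0 = projection.forward(segs["lon0"].to_numpy(), segs["lat0"].to_numpy())
        x1, y1 = projection.forward(segs["lon1"].to_numpy(), segs["lat1"].to_numpy())
        p_seg = model.probability(segs["speed_kn"].to_numpy())
        lengths = segs["length_nm"].to_numpy()
        for i in range(len(segs)):
            for r, c, frac in _split_on_grid(x0[i], y0[i], x1[i], y1[i], grid):
                if 0 <= r < grid.nrows and 0 <= c < grid.ncols:
                    d = lengths[i] * frac
                    dist[r, c] += d
                    weighted[r, c] += d * p_seg[i]
                else:
                    skipped += 1
    return TrafficSurface(grid=grid, distance_nm=dist, weighted_nm=weighted,
                          n_transits=len(transits), skipped_segments=skipped)


def risk_map(traffic: TrafficSurface, density: WhaleDensitySurface,
             normalize_per_transit: bool = True) -> np.ndarray:
    """Per-cell relative lethal-strike risk: density x weighted distance.

    With ``normalize_per_transit`` the weighted distance is divided by the
    number of transits, making periods with different traffic volumes
    comparable.
    """
    if density.grid != traffic.grid:
        raise ValueError("traffic and density grids do not match")
    w = traffic.weighted_nm
    if normalize_per_transit:
        if traffic.n_transits == 0:
            raise ValueError("cannot normalise an empty traffic surface")
        w = w / traffic.n_transits
    return density.values * w


def _region_mask(grid: GridSpec, region: Polygon | None,
                 projection: LocalProjection | None) -> np.ndarray:
    if region is None:
        return np.ones((grid.nrows, grid.ncols), dtype=bool)
    import shapely
    poly = projection.project_geometry(region) if projection else region
    rr, cc = np.meshgrid(np.arange(grid.nrows), np.arange(grid.ncols), indexing="ij")
    cx = grid.x0 + (cc + 0.5) * grid.cell_size
    cy = grid.y0 + (rr + 0.5) * grid.cell_size
    return shapely.contains_xy(poly, cx.ravel(), cy.ravel()).reshape(rr.shape)


def effectiveness(before: np.ndarray, after: np.ndarray, grid: GridSpec,
                  region: Polygon | None = None,
                  projection: LocalProjection | None = None) -> float:
    """Percent reduction in summed risk over a region: 100*(1 - after/before).

    ``region`` (lon/lat polygon, with the projection used for the grid)
    restricts the sum to cells whose centres fall inside; None sums the
    whole grid.  Raises when the baseline risk in the region is zero.
    """
    mask = _region_mask(grid, region, projection)
    b = float(before[mask].sum())
    a = float(after[mask].sum())
    if b <= 0:
        raise ValueError("baseline risk in the region is zero; reduction undefined")
    return 100.0 * (1.0 - a / b)


@dataclass
class EffectivenessReport:
    """Species x region percent risk reductions."""

    table: pd.DataFrame          # columns: species, region, before, after, reduction_pct

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def effectiveness_report(traffic_before: TrafficSurface,
                         traffic_after: TrafficSurface,
                         densities: dict[str, WhaleDensitySurface],
                         regions: dict[str, Polygon | None],
                         projection: LocalProjection,
                         normalize_per_transit: bool = True) -> EffectivenessReport:
    rows = []
    for sp, dens in densities.items():
        rb = risk_map(traffic_before, dens, normalize_per_transit)
        ra = risk_map(traffic_after, dens, normalize_per_transit)
        for rname, region in regions.items():
            mask = _region_mask(dens.grid, region, projection)
            b, a = float(rb[mask].sum()), float(ra[mask].sum())
            rows.append({
                "species": sp, "region": rname, "risk_before": b, "risk_after": a,
                "reduction_pct": 100.0 * (1.0 - a / b) if b > 0 else np.nan,
            })
    return EffectivenessReport(pd.DataFrame(rows))


def speed_distribution_surrogate(model: LethalityModel,
                                 before: tuple[float, float] = (14.1, 2.6),
                                 after: tuple[float, float] = (11.3, 1.7),
                                 n: int = 10_000,
                                 seed: int | None = 0) -> float:
    """Monte-Carlo percent risk reduction from two speed distributions.

    Draws ``n`` before- and after-speeds from Normals truncated at zero
    (summary statistics of the monitored fleet's zone speeds), weights each
    draw equally in distance and assumes a common route over uniform whale
    density, so the reduction collapses to
    100*(1 - mean P(after) / mean P(before)).
    """
    from scipy.stats import truncnorm
    rng = np.random.default_rng(seed)
    def draw(mu, sd):
        a = (0.0 - mu) / sd
        return truncnorm.rvs(a, np.inf, loc=mu, scale=sd, size=n,
                             random_state=rng)
    p_before = model.probability(draw(*before)).mean()
    p_after = model.probability(draw(*after)).mean()
    return 100.0 * (1.0 - p_after / p_before)


# ---------------------------------------------------------------------------
# Transit-time cost


def _gate_crossing_time(tr: Transit, gate: LineString,
                        projection: LocalProjection) -> pd.Timestamp | None:
    """First crossing instant of a gate, linearly interpolated between the
    straddling fixes."""
    fx = tr.fixes
    x, y = projection.forward(fx["lon"].to_numpy(), fx["lat"].to_numpy())
    g = projection.project_geometry(gate)
    for i in range(len(fx) - 1):
        seg = LineString([(x[i], y[i]), (x[i + 1], y[i + 1])])
        if seg.length == 0 or not seg.intersects(g):
            continue
        pt = seg.intersection(g)
        if pt.is_empty:
            continue
        frac = seg.project(pt.centroid) / seg.length
        t0, t1 = fx["timestamp"].iloc[i], fx["timestamp"].iloc[i + 1]
        return t0 + frac * (t1 - t0)
    return None


def transit_time_stats(transits, gate_a: LineString, gate_b: LineString,
                       projection: LocalProjection) -> pd.DataFrame:
    """Mean gate-to-gate elapsed minutes by direction and period.

    Transits missing either gate crossing are excluded.  Returns one row per
    (direction, active) group with the mean, sd and count.
    """
    rows = []
    for tr in transits:
        ta = _gate_crossing_time(tr, gate_a, projection)
        tb = _gate_crossing_time(tr, gate_b, projection)
        if ta is None or tb is None:
            continue
        rows.append({"transit_id": tr.transit_id, "direction": tr.direction,
                     "active": tr.measures_active, "year": tr.year,
                     "minutes": abs((tb - ta).total_seconds()) / 60.0})
    per = pd.DataFrame(rows)
    if per.empty:
        return pd.DataFrame(columns=["direction", "active", "mean_minutes",
                                     "sd_minutes", "n"])
    g = per.groupby(["direction", "active"])["minutes"]
    out = g.agg(mean_minutes="mean", sd_minutes="std", n="count").reset_index()
    return out
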