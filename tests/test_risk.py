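import math

import numpy as np
import pandas as pd
import pytest
import slowzone as sz
from slowzone.geo import GridSpec, LocalProjection
from tests.conftest import make_transit


@pytest.fixture(scope="module")
def model():
    return sz.calibrate_lethality()


class TestLethalityCalibration:
    def test_coefficients_from_logit_algebra(self, model):
        logit = lambda p: math.log(p / (1 - p))
        beta1 = (logit(0.5) - logit(0.31)) / (11.8 - 10.0)
        assert model.beta1 == pytest.approx(beta1, rel=1e-12)
        assert model.beta1 == pytest.approx(0.4446, abs=1e-4)
        assert model.beta0 == pytest.approx(logit(0.31) - beta1 * 10.0, rel=1e-12)
        assert model.beta0 == pytest.approx(-5.246, abs=2e-3)

    def test_anchors_reproduced(self, model):
        assert model.probability(10.0) == pytest.approx(0.31, abs=1e-12)
        assert model.probability(11.8) == pytest.approx(0.50, abs=1e-12)

    def test_monotone_increasing(self, model):
        v = np.linspace(0, 30, 100)
        p = model.probability(v)
        assert (np.diff(p) > 0).all()
        assert ((p > 0) & (p < 1)).all()

    def test_symmetric_anchor_limit(self):
        m = sz.calibrate_lethality(((0.0, 0.5), (1.0, 0.5 + 1e-9)))
        assert m.beta0 == pytest.approx(0.0, abs=1e-6)

    def test_degenerate_anchors_rejected(self):
        with pytest.raises(ValueError):
            sz.calibrate_lethality(((10.0, 0.3), (10.0, 0.5)))
        with pytest.raises(ValueError):
            sz.calibrate_lethality(((10.0, 0.3), (12.0, 0.3)))

    def test_evaluated_at_typical_cruise_speed(self, model):
        assert sz.lethality_probability(model, 14.1) == pytest.approx(0.735,
                                                                      abs=1e-3)


GRID = GridSpec(x0=-10000, y0=-10000, cell_size=1000, nrows=20, ncols=20)
PROJ = LocalProjection(0.0, 0.0)
NM = 1.0 / 60.0405


class TestTrafficSurface:
    def _straight(self, speed, n=21, length_nm=10.0):
        lons = np.linspace(-length_nm / 2 * NM, length_nm / 2 * NM, n)
        return make_transit([(lo, 0.0) for lo in lons], [speed] * n)

    def test_distance_and_weight_at_cruise(self, model):
        ts = sz.traffic_surface([self._straight(14.1)], GRID, model, PROJ)
        assert ts.distance_nm.sum() == pytest.approx(10.0, rel=1e-3)
        assert ts.weighted_nm.sum() == pytest.approx(
            10.0 * model.probability(14.1), rel=1e-3)

    def test_weight_at_limit_speed(self, model):
        ts = sz.traffic_surface([self._straight(10.0)], GRID, model, PROJ)
        assert ts.weighted_nm.sum() == pytest.approx(3.10, abs=0.01)

    def test_empty(self, model):
        ts = sz.traffic_surface([], GRID, model, PROJ)
        assert ts.distance_nm.sum() == 0 and ts.n_transits == 0

    def test_distance_conserved_on_random_tracks(self, model):
        rng = np.random.default_rng(3)
        transits = []
        for _ in range(10):
            n = rng.integers(5, 15)
            lons = np.sort(rng.uniform(-0.08, 0.08, n))
            lats = rng.uniform(-0.05, 0.05, n)
            transits.append(make_transit(list(zip(lons, lats)),
                                         rng.uniform(8, 18, n).tolist()))
        ts = sz.traffic_surface(transits, GRID, model, PROJ)
        total = sum(sz.segmentize(t)["length_nm"].sum() for t in transits)
        assert ts.distance_nm.sum() == pytest.approx(total, rel=1e-6)
        assert (ts.weighted_nm <= ts.distance_nm + 1e-12).all()


class TestRiskAndEffectiveness:
    def _uniform_density(self):
        return sz.WhaleDensitySurface("fin", GRID,
                                      np.ones((GRID.nrows, GRID.ncols)))

    def test_identical_maps_zero_reduction(self, model):
        ts = sz.traffic_surface([TestTrafficSurface()._straight(12.0)],
                                GRID, model, PROJ)
        r = sz.risk_map(ts, self._uniform_density())
        assert sz.effectiveness(r, r, GRID) == pytest.approx(0.0)

    def test_halved_risk(self, model):
        ts = sz.traffic_surface([TestTrafficSurface()._straight(12.0)],
                                GRID, model, PROJ)
        r = sz.risk_map(ts, self._uniform_density())
        assert sz.effectiveness(r, 0.5 * r, GRID) == pytest.approx(50.0)

    def test_point_speed_closed_form(self, model):
        """Single-speed fleets: reduction == 100*(1 - P(v2)/P(v1)) exactly."""
        t_before = TestTrafficSurface()._straight(14.1)
        t_after = TestTrafficSurface()._straight(10.0)
        dens = self._uniform_density()
        rb = sz.risk_map(sz.traffic_surface([t_before], GRID, model, PROJ), dens)
        ra = sz.risk_map(sz.traffic_surface([t_after], GRID, model, PROJ), dens)
        got = sz.effectiveness(rb, ra, GRID)
        closed = 100.0 * (1 - model.probability(10.0) / model.probability(14.1))
        assert got == pytest.approx(closed, abs=1e-6)
        assert closed == pytest.approx(57.85, abs=0.01)

    def test_density_rescale_invariance(self, model):
        ts_b = sz.traffic_surface([TestTrafficSurface()._straight(14.0)],
                                  GRID, model, PROJ)
        ts_a = sz.traffic_surface([TestTrafficSurface()._straight(11.0)],
                                  GRID, model, PROJ)
        rng = np.random.default_rng(4)
        vals = rng.uniform(0.1, 1.0, (GRID.nrows, GRID.ncols))
        d1 = sz.WhaleDensitySurface("fin", GRID, vals)
        d2 = sz.WhaleDensitySurface("fin", GRID, 37.5 * vals)
        e1 = sz.effectiveness(sz.risk_map(ts_b, d1), sz.risk_map(ts_a, d1), GRID)
        e2 = sz.effectiveness(sz.risk_map(ts_b, d2), sz.risk_map(ts_a, d2), GRID)
        assert e1 == pytest.approx(e2, rel=1e-12)

    def test_slower_is_never_worse(self, model):
        dens = self._uniform_density()
        speeds = [14.0, 12.5, 11.0, 10.0, 9.0]
        base = sz.risk_map(sz.traffic_surface(
            [TestTrafficSurface()._straight(15.0)], GRID, model, PROJ), dens)
        prev = None
        for v in speeds:
            r = sz.risk_map(sz.traffic_surface(
                [TestTrafficSurface()._straight(v)], GRID, model, PROJ), dens)
            eff = sz.effectiveness(base, r, GRID)
            if prev is not None:
                assert eff >= prev - 1e-9
            prev = eff

    def test_hotspot_scales_pointwise(self, model):
        ts = sz.traffic_surface([TestTrafficSurface()._straight(12.0)],
                                GRID, model, PROJ)
        vals = np.ones((GRID.nrows, GRID.ncols))
        vals[10, 10] = 3.0
        dens = sz.WhaleDensitySurface("fin", GRID, vals)
        uni = self._uniform_density()
        r_h = sz.risk_map(ts, dens)
        r_u = sz.risk_map(ts, uni)
        # the hotspot cell carries 3x the (normalised) density of a uniform cell
        expected = dens.values[10, 10] / uni.values[10, 10]
        assert r_h[10, 10] / r_u[10, 10] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(3.0 * 400 / 402, rel=1e-12)

    def test_zero_baseline_rejected(self, model):
        z = np.zeros((GRID.nrows, GRID.ncols))
        with pytest.raises(ValueError):
            sz.effectiveness(z, z, GRID)

    def test_grid_mismatch_rejected(self, model):
        ts = sz.traffic_surface([TestTrafficSurface()._straight(12.0)],
                                GRID, model, PROJ)
        other = GridSpec(x0=0, y0=0, cell_size=500, nrows=4, ncols=4)
        dens = sz.WhaleDensitySurface("fin", other, np.ones((4, 4)))
        with pytest.raises(ValueError):
            sz.risk_map(ts, dens)


class TestSurrogate:
    def test_reduction_in_printed_band(self, model):
        red = sz.speed_distribution_surrogate(model, seed=0)
        assert 36.1 - 3.4 <= red <= 36.1 + 3.4

    def test_stable_across_seeds(self, model):
        vals = [sz.speed_distribution_surrogate(model, seed=s)
                for s in range(5)]
        assert np.std(vals) < 1.0


class TestTransitTimes:
    def test_constant_speed_elapsed(self):
        from shapely.geometry import LineString
        gate_a = LineString([(-0.05, -0.1), (-0.05, 0.1)])
        gate_b = LineString([(0.05, -0.1), (0.05, 0.1)])
        n = 41
        lons = np.linspace(-0.08, 0.08, n)
        # physically consistent timing: time step = segment distance / speed
        seg_nm = sz.geodesic_distance(sz.GeoPoint(lons[0], 0),
                                      sz.GeoPoint(lons[1], 0))
        dt = seg_nm / 12.0 * 3600
        tr = make_transit([(lo, 0.0) for lo in lons], [12.0] * n, dt_s=dt)
        out = sz.transit_time_stats([tr], gate_a, gate_b, PROJ)
        d = sz.geodesic_distance(sz.GeoPoint(-0.05, 0), sz.GeoPoint(0.05, 0))
        assert out["mean_minutes"].iloc[0] == pytest.approx(d / 12.0 * 60,
                                                            rel=1e-5)

    def test_crossing_interpolated_between_fixes(self):
        from shapely.geometry import LineString
        gate = LineString([(0.0, -0.1), (0.0, 0.1)])
        # two fixes 6 min apart straddling the gate at their midpoint
        tr = make_transit([(-0.01, 0.0), (0.01, 0.0)], [10.0, 10.0], dt_s=360)
        t = sz.risk._gate_crossing_time(tr, gate, PROJ)
        t0 = tr.fixes["timestamp"].iloc[0]
        assert (t - t0).total_seconds() == pytest.approx(180.0, abs=0.5)

    def test_missing_gate_crossing_excluded(self):
        from shapely.geometry import LineString
        gate_a = LineString([(-0.05, -0.1), (-0.05, 0.1)])
        gate_b = LineString([(0.5, -0.1), (0.5, 0.1)])   # never crossed
        tr = make_transit([(-0.08, 0.0), (0.08, 0.0)], [12.0, 12.0])
        out = sz.transit_time_stats([tr], gate_a, gate_b, PROJ)
        assert out.empty

    def test_slowdown_cost_matches_kinematics(self):
        """Slowing a 5.4-nm stretch from 12 to 10 kn adds 5.4*60*(1/10-1/12)
        minutes to the gate-to-gate time."""
        from shapely.geometry import LineString
        gate_a = LineString([(-0.1, -0.2), (-0.1, 0.2)])
        gate_b = LineString([(0.1, -0.2), (0.1, 0.2)])

        def transit_with_zone_speed(v_zone):
            # 0.2 deg ~ 12 nm between gates; middle 5.4 nm at v_zone
            xs, ts_s = [], []
            x, t = -0.105, 0.0
            while x < 0.105:
                in_zone = abs(x) < 2.7 * NM
                v = v_zone if in_zone else 12.0
                xs.append(x)
                ts_s.append(t)
                step_nm = 0.05
                x += step_nm * NM
                t += step_nm / v * 3600
            pts = [(xi, 0.0) for xi in xs]
            n = len(pts)
            fixes = pd.DataFrame({
                "vessel_id": "V1",
                "timestamp": pd.to_datetime("2014-07-15") +
                pd.to_timedelta(ts_s, unit="s"),
                "lat": 0.0, "lon": [p[0] for p in pts],
                "sog": 12.0, "cog": 90.0, "stw": 12.0})
            return sz.Transit(transit_id="t", vessel_id="V1",
                              ship_class="cargo", flag="Canadian",
                              fixes=fixes, direction="upstream",
                              pilot_onboard=False, year=2014,
                              measures_active=True)

        fast = sz.transit_time_stats([transit_with_zone_speed(12.0)],
                                     gate_a, gate_b, PROJ)
        slow = sz.transit_time_stats([transit_with_zone_speed(10.0)],
                                     gate_a, gate_b, PROJ)
        delta = slow["mean_minutes"].iloc[0] - fast["mean_minutes"].iloc[0]
        assert delta == pytest.approx(5.4 * 60 * (1 / 10 - 1 / 12), abs=0.25)
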