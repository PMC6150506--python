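import numpy as np
import pytest
from shapely.geometry import box

import slowzone as sz
from slowzone.geo import LocalProjection
from tests.conftest import make_transit

# a simple planar-ish test zone: 0.2 deg of longitude near the equator so
# distances are essentially euclidean in degrees
ZONE = box(-0.1, -0.5, 0.1, 0.5)
PROJ = LocalProjection(0.0, 0.0)
NM = 1.0 / 60.0405   # one nautical mile in degrees of longitude at lat 0


def path(lons, lat=0.0):
    return [(lon, lat) for lon in lons]


class TestDwas:
    def test_distance_weighted_mean(self):
        # 1 nm @ 10 kn then (via a negligible splice) 3 nm @ 14 kn -> 13.0
        lons = [-0.05, -0.05 + NM, -0.05 + NM + 1e-9, -0.05 + 4 * NM]
        tr = make_transit(path(lons), [10.0, 10.0, 14.0, 14.0])
        assert sz.dwas(tr, ZONE, PROJ) == pytest.approx(13.0, abs=1e-3)

    def test_constant_speed_identity(self):
        tr = make_transit(path([-0.05, 0.0, 0.05]), [11.0, 11.0, 11.0])
        assert sz.dwas(tr, ZONE, PROJ) == pytest.approx(11.0)

    def test_only_inzone_distance_counts(self):
        # half of the track is outside the zone at a different speed
        tr = make_transit(path([-0.3, -0.1, 0.1]), [20.0, 20.0, 10.0])
        # in-zone segment speed = mean(20, 10) = 15 over the single segment
        assert sz.dwas(tr, ZONE, PROJ) == pytest.approx(15.0)

    def test_no_inzone_distance_raises(self):
        tr = make_transit(path([0.5, 0.6, 0.7]), [10.0, 10.0, 10.0])
        with pytest.raises(ValueError):
            sz.dwas(tr, ZONE, PROJ)

    def test_bounded_by_segment_speeds(self, small_transits, zones):
        for tr in small_transits[:8]:
            try:
                d = sz.dwas(tr, zones.sra, zones.projection)
            except ValueError:
                continue
            speeds = tr.fixes["stw"]
            assert speeds.min() - 1e-9 <= d <= speeds.max() + 1e-9


class TestDwasSamplingBias:
    """A ship decelerating through the zone, AIS-sampled at fixed time steps:
    distance weighting must stay at the true space-mean speed while the naive
    per-fix mean drifts toward the slow end."""

    @staticmethod
    def _sampled_transit(dt_s):
        # speed drops linearly in *distance* from 14 kn to 10 kn over 8 nm:
        # v(s) = 14 - 0.5*s ; time to reach s: t(s) = -2 ln(1 - s/28) h
        total_nm = 8.0
        t, s = 0.0, 0.0
        lons, speeds = [], []
        while s < total_nm:
            v = 14.0 - 0.5 * s
            lons.append(-0.099 + s * NM)
            speeds.append(v)
            s += v * dt_s / 3600.0
            t += dt_s
        return make_transit(path(lons), speeds, dt_s=dt_s)

    def test_resampling_invariance(self):
        zone = box(-0.1, -0.5, 0.2, 0.5)
        d_fast = sz.dwas(self._sampled_transit(10.0), zone, PROJ)
        d_slow = sz.dwas(self._sampled_transit(120.0), zone, PROJ)
        assert abs(d_fast - d_slow) < 0.05

    def test_dwas_equals_distance_over_time(self):
        zone = box(-0.1, -0.5, 0.2, 0.5)
        tr = self._sampled_transit(10.0)
        segs = sz.segmentize(tr)
        ratio = segs["length_nm"].sum() / (segs["duration_s"].sum() / 3600.0)
        assert sz.dwas(tr, zone, PROJ) == pytest.approx(ratio, rel=0.02)

    def test_naive_mean_is_biased_low(self):
        zone = box(-0.1, -0.5, 0.2, 0.5)
        tr = self._sampled_transit(10.0)
        naive = tr.fixes["stw"].mean()
        d = sz.dwas(tr, zone, PROJ)
        # time sampling over-represents the slow tail
        assert naive < d
        # space-mean of v(s)=14-0.5s over 8 nm is 12; time-mean is lower
        assert d == pytest.approx(12.0, abs=0.05)
        assert naive == pytest.approx(11.86, abs=0.1)


class TestStrictCompliance:
    def test_boundary_inclusive(self):
        tr = make_transit(path([-0.05, 0.0, 0.05]), [9.8, 9.9, 10.0])
        assert sz.strict_compliance([tr], ZONE, PROJ) == pytest.approx(100.0)

    def test_single_fix_over_limit_fails_whole_transit(self):
        tr = make_transit(path([-0.05, 0.0, 0.05]), [9.8, 10.1, 9.9])
        assert sz.strict_compliance([tr], ZONE, PROJ) == pytest.approx(0.0)

    def test_empty_reported_absent(self):
        assert sz.strict_compliance([], ZONE, PROJ) is None

    def test_out_of_zone_speeds_ignored(self):
        tr = make_transit(path([-0.3, -0.05, 0.05]), [18.0, 9.5, 9.9])
        assert sz.strict_compliance([tr], ZONE, PROJ) == pytest.approx(100.0)


class TestSlowdownEffort:
    def test_step_change_at_entry(self):
        # approach at 13 kn, duplicate fix at the boundary, zone at 10 kn
        eps = 1e-7
        lons = [-0.1 - 3000 / 1852 * NM * 1.5, -0.1 - eps, -0.1 + eps, 0.0, 0.09]
        tr = make_transit(path(lons), [13.0, 13.0, 10.0, 10.0, 10.0])
        dv = sz.slowdown_effort(tr, ZONE, PROJ)
        assert dv == pytest.approx(3.0, abs=0.01)

    def test_constant_speed_zero(self):
        tr = make_transit(path([-0.2, -0.05, 0.05]), [12.0, 12.0, 12.0])
        assert sz.slowdown_effort(tr, ZONE, PROJ) == pytest.approx(0.0, abs=1e-6)

    def test_absent_without_buffer_coverage(self):
        # track starts inside the zone: no pre-entry buffer
        tr = make_transit(path([-0.05, 0.0, 0.05]), [10.0, 10.0, 10.0])
        assert sz.slowdown_effort(tr, ZONE, PROJ) is None

    def test_planted_slowdown_recovered(self, small_scenario, small_transits,
                                        zones):
        ind = sz.transit_indicators(small_transits, zones)
        j = sz.attach_truth(ind, small_scenario["truth"])
        j = j.dropna(subset=["i4_slowdown", "planted_i4_kn"])
        assert len(j) > 5
        err = (j["i4_slowdown"] - j["planted_i4_kn"]).abs()
        assert err.median() < 0.25


class TestNoncomplianceProfile:
    def test_mixed_segments(self):
        # 2 nm @ 9, 3 nm @ 12, 1 nm @ 13 (via negligible splices)
        e = 1e-9
        lons = [-0.08, -0.08 + 2 * NM, -0.08 + 2 * NM + e,
                -0.08 + 5 * NM, -0.08 + 5 * NM + e, -0.08 + 6 * NM]
        tr = make_transit(path(lons), [9, 9, 12, 12, 13, 13])
        i6, i7 = sz.noncompliance_profile(tr, ZONE, PROJ)
        assert i6 == pytest.approx(100 * 4 / 6, abs=0.01)
        assert i7 == pytest.approx(12.25, abs=0.01)

    def test_all_compliant(self):
        tr = make_transit(path([-0.05, 0.0, 0.05]), [9.0, 9.0, 9.0])
        i6, i7 = sz.noncompliance_profile(tr, ZONE, PROJ)
        assert i6 == 0.0 and i7 is None

    def test_all_over_equals_dwas(self):
        tr = make_transit(path([-0.05, 0.0, 0.05]), [12.0, 13.0, 14.0])
        i6, i7 = sz.noncompliance_profile(tr, ZONE, PROJ)
        assert i6 == pytest.approx(100.0)
        assert i7 == pytest.approx(sz.dwas(tr, ZONE, PROJ))

    def test_constant_speed_gives_zero_or_hundred(self):
        for v, expect in [(9.0, 0.0), (11.0, 100.0)]:
            tr = make_transit(path([-0.05, 0.0, 0.05]), [v, v, v])
            i6, _ = sz.noncompliance_profile(tr, ZONE, PROJ)
            assert i6 == expect


class TestNgaAndRoute:
    def test_nga_usage_classes(self, zones):
        avoid = make_transit([(-69.10, 48.16), (-69.45, 48.16)], [12, 12])
        cross = make_transit([(-69.18, 48.345), (-69.42, 48.345)], [12, 12])
        clip = make_transit([(-69.20, 48.285), (-69.40, 48.20)], [12, 12])
        res = sz.nga_usage([avoid, cross, clip], zones)
        assert res["pct_partial"] == pytest.approx(100 * 2 / 3)
        assert res["pct_complete"] == pytest.approx(100 * 1 / 3)
        assert len(res["dwas_complete"]) == 1
        assert res["dwas_complete"][0] == pytest.approx(12.0, abs=1e-6)

    def test_rr_classification_counts(self, zones):
        def gate_crossing(lat):
            return make_transit([(-69.80, lat), (-69.70, lat)], [12, 12])
        transits = [gate_crossing(48.40) for _ in range(93)]
        transits += [gate_crossing(48.10) for _ in range(7)]
        pct, log = sz.rr_compliance(transits, zones)
        assert pct == pytest.approx(93.0)
        assert log.empty

    def test_rr_unclassifiable_excluded(self, zones):
        north = [make_transit([(-69.80, 48.40), (-69.70, 48.40)], [12, 12])]
        neither = [make_transit([(-69.60, 48.25), (-69.50, 48.25)], [12, 12])]
        pct, log = sz.rr_compliance(north + neither, zones)
        assert pct == pytest.approx(100.0)
        assert list(log["reason"]) == ["crosses_no_gate"]


class TestPortfolio:
    def test_two_year_scenario_rows(self, small_transits, zones, calendar):
        pf = sz.build_portfolio(small_transits, zones, calendar)
        assert set(zip(pf["year"], pf["status"])) == {
            (2012, "active"), (2012, "inactive"),
            (2014, "active"), (2014, "inactive")}
        empty = pf[(pf["year"] == 2012) & (pf["status"] == "active")]
        assert int(empty["n_transits"].iloc[0]) == 0
        assert np.isnan(empty["I1_pct"].iloc[0])

    def test_vessels_not_more_than_transits(self, small_transits, zones,
                                            calendar):
        pf = sz.build_portfolio(small_transits, zones, calendar)
        assert (pf["n_vessels"] <= pf["n_transits"]).all()

    def test_strict_rate_matches_generator_truth(self, small_scenario,
                                                 small_transits, zones,
                                                 calendar):
        """With no emission noise the recovered strict-compliance flags equal
        the planted ones transit by transit."""
        ind = sz.transit_indicators(small_transits, zones)
        j = sz.attach_truth(ind, small_scenario["truth"])
        j = j[j["active"]].dropna(subset=["compliant"])
        assert len(j) > 0
        assert (j["compliant"].astype(bool) ==
                j["planted_compliant"].astype(bool)).all()

    def test_i7_above_limit_when_i6_positive(self, small_transits, zones,
                                             calendar):
        pf = sz.build_portfolio(small_transits, zones, calendar)
        sel = pf.dropna(subset=["I6_pct", "I7_kn"])
        sel = sel[sel["I6_pct"] > 0]
        assert (sel["I7_kn"] > 10.0).all()
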