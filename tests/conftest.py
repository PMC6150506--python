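import numpy as np
import pandas as pd
import pytest

import slowzone as sz


@pytest.fixture(scope="session")
def zones():
    return sz.synthetic_zones()


@pytest.fixture(scope="session")
def projection(zones):
    return zones.projection


@pytest.fixture(scope="session")
def calendar():
    return sz.MeasureCalendar.study_default()


@pytest.fixture(scope="session")
def small_scenario(zones):
    """A small noise-free, dropout-free kinematic scenario shared by tests."""
    cfg = sz.ScenarioConfig(
        seed=11,
        n_transits={(2012, "inactive"): 8, (2014, "active"): 12,
                    (2014, "inactive"): 6},
        stw_noise_sd_kn=0.0, dropout_p=0.0,
    )
    fixes, vessels, pilots, truth, fields = sz.gen_transits(cfg, zones)
    return {"cfg": cfg, "fixes": fixes, "vessels": vessels, "pilots": pilots,
            "truth": truth, "fields": fields}


@pytest.fixture(scope="session")
def small_transits(small_scenario, zones, calendar):
    from slowzone.currents import add_stw_fields
    clean, _ = sz.clean_fixes(small_scenario["fixes"], zones.study_area)
    clean = add_stw_fields(clean, small_scenario["fields"])
    transits, log = sz.build_transits(clean, small_scenario["vessels"],
                                      small_scenario["pilots"], zones, calendar)
    return transits


def make_transit(points, speeds, t0="2014-07-15T10:00:00", dt_s=120.0,
                 vessel="V1", **kw):
    """Hand-built transit: points as (lon, lat), per-fix STW in knots."""
    n = len(points)
    ts = pd.to_datetime(t0) + pd.to_timedelta(np.arange(n) * dt_s, unit="s")
    fixes = pd.DataFrame({
        "vessel_id": vessel, "timestamp": ts,
        "lat": [p[1] for p in points], "lon": [p[0] for p in points],
        "sog": speeds, "cog": 90.0, "stw": speeds,
    })
    defaults = dict(transit_id=f"{vessel}-test", vessel_id=vessel,
                    ship_class="cargo", flag="Canadian", fixes=fixes,
                    direction="upstream", pilot_onboard=True, year=ts[0].year,
                    measures_active=True)
    defaults.update(kw)
    return sz.Transit(**defaults)


@pytest.fixture
def make_transit_factory():
    return make_transit
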