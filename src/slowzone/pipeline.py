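"""End-to-end orchestration: scenario or files in, monitoring reports out.

Stages: (1) simulate or load AIS fixes, vessel metadata, zones, currents and
whale densities; (2) clean fixes and build transits; (3) convert SOG to STW
with the current field; (4) compute the compliance-indicator portfolio;
(5) fit the speed models and year-to-year KS comparisons; (6) grid the
traffic, map lethal-strike risk per species and report before/after
effectiveness and transit-time cost.  Every output carries a metadata
header (config hash, seed, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .ais import build_transits, clean_fixes, read_fixes_csv
from .compliance import build_portfolio, transit_indicators
from .currents import CurrentField, add_stw_fields
from .geo import MeasureCalendar, ZoneSet
from .inference import (fit_active_effect, fit_covariate_model,
                        fit_year_effects, fit_to_csv, ks_year_table)
from .risk import (SPECIES, calibrate_lethality, effectiveness_report,
                   traffic_surface, transit_time_stats)
from .simulate import (ScenarioConfig, analysis_grid, gen_transits,
                       gen_whale_density, synthetic_zones)

log = logging.getLogger("slowzone")


@dataclass
class PipelineConfig:
    """Either a synthetic scenario or a set of input paths, plus options."""

    out_dir: str | Path = "slowzone_out"
    scenario: ScenarioConfig | None = None
    # file inputs (used when scenario is None)
    fixes_csv: str | None = None
    vessels_csv: str | None = None
    pilot_csv: str | None = None
    zones_geojson: str | None = None
    calendar_csv: str | None = None
    currents_nc: list[str] = field(default_factory=list)
    # analysis options
    speed_limit_kn: float = 10.0
    buffer_m: float = 3000.0
    grid_cell_m: float = 1000.0
    normalize_per_transit: bool = True
    speed_basis: str = "STW"
    baseline_year: int = 2012

    def __post_init__(self):
        has_files = self.fixes_csv is not None
        if (self.scenario is None) == (not has_files):
            raise ValueError("provide exactly one of scenario or input paths")

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("out_dir")    # the hash covers the analysis, not where it lands
        if d.get("scenario") and "n_transits" in d["scenario"]:
            d["scenario"]["n_transits"] = sorted(
                (str(k), v) for k, v in d["scenario"]["n_transits"].items())
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, meta: dict) -> None:
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(meta, default=str) + "\n")
        df.to_csv(fh, index=False)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write the report bundle to cfg.out_dir.

    Returns a dict with the in-memory results (transits, portfolio, model
    fits, KS table, effectiveness report, transit times, output paths).
    """
    t_begin = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    meta = {"config_hash": cfg.config_hash(), "version": __version__,
            "seed": cfg.scenario.seed if cfg.scenario else None,
            "speed_basis": cfg.speed_basis,
            "normalize_per_transit": cfg.normalize_per_transit,
            "grid_cell_m": cfg.grid_cell_m}

    # ---- inputs -----------------------------------------------------------
    if cfg.scenario is not None:
        zones = synthetic_zones()
        cal = MeasureCalendar.study_default()
        fixes, vessels, pilots, truth, fields = gen_transits(cfg.scenario, zones)
        log.info("simulated %d fixes", len(fixes))
    else:
        zones = ZoneSet.from_geojson(cfg.zones_geojson)
        cal = (MeasureCalendar.from_csv(cfg.calendar_csv)
               if cfg.calendar_csv else MeasureCalendar.study_default())
        fixes, parse_log = read_fixes_csv(cfg.fixes_csv)
        vessels = pd.read_csv(cfg.vessels_csv) if cfg.vessels_csv else None
        pilots = pd.read_csv(cfg.pilot_csv, parse_dates=["t_start", "t_end"]) \
            if cfg.pilot_csv else None
        fields = [CurrentField.from_netcdf(p) for p in cfg.currents_nc]
        truth = None

    # ---- ingest + STW -----------------------------------------------------
    clean, reject_log = clean_fixes(fixes, zones.study_area)
    clean = add_stw_fields(clean, fields)
    transits, transit_log = build_transits(clean, vessels, pilots, zones, cal)
    log.info("built %d transits (%d fixes kept)", len(transits), len(clean))
    reject_log.to_csv(out / "rejected_fixes.csv", index=False)
    transit_log.to_csv(out / "rejected_transits.csv", index=False)

    # ---- compliance -------------------------------------------------------
    ind = transit_indicators(transits, zones, cfg.speed_limit_kn, cfg.buffer_m)
    portfolio = build_portfolio(transits, zones, cal, cfg.speed_limit_kn,
                                indicators=ind)
    _write_csv(ind, out / "transit_indicators.csv", meta)
    _write_csv(portfolio, out / "portfolio.csv", meta)

    # ---- speed models + KS ------------------------------------------------
    model_tbl = ind.dropna(subset=["dwas_sra"]).rename(columns={"dwas_sra": "dwas"})
    fits = {}
    if model_tbl["active"].nunique() == 2 and model_tbl["year"].nunique() >= 2:
        fits["active_effect"] = fit_active_effect(model_tbl)
        fits["year_effects"] = fit_year_effects(model_tbl)
        fit_to_csv(fits["active_effect"], out / "model_active_effect.csv")
        fit_to_csv(fits["year_effects"], out / "model_year_effects.csv")
    act = model_tbl[model_tbl["active"]]
    if len(act) and act["year"].nunique() >= 1 and act["pilot_onboard"].nunique() >= 1:
        try:
            fits["covariates"] = fit_covariate_model(act)
            fit_to_csv(fits["covariates"], out / "model_covariates.csv")
        except ValueError as e:
            log.warning("covariate model skipped: %s", e)
    ks = ks_year_table(model_tbl)
    _write_csv(ks, out / "ks_by_year.csv", meta)

    # ---- risk + effectiveness --------------------------------------------
    grid = analysis_grid(zones, cfg.grid_cell_m)
    model = calibrate_lethality()
    proj = zones.projection
    before = [t for t in transits if t.year == cfg.baseline_year
              and not t.measures_active]
    after = [t for t in transits if t.measures_active]
    eff_rows = None
    if before and after:
        tb = traffic_surface(before, grid, model, proj, cfg.speed_basis)
        ta = traffic_surface(after, grid, model, proj, cfg.speed_basis)
        scen = cfg.scenario or ScenarioConfig()
        dens = {sp: gen_whale_density(scen, sp, zones, grid) for sp in SPECIES}
        regions = {"whole_area": zones.study_area, "sra": zones.sra}
        eff = effectiveness_report(tb, ta, dens, regions, proj,
                                   cfg.normalize_per_transit)
        _write_csv(eff.table, out / "effectiveness.csv", meta)
        eff_rows = eff
    else:
        _write_csv(pd.DataFrame({"note": ["no active period or no baseline; "
                                          "effectiveness not computed"]}),
                   out / "effectiveness.csv", meta)

    tt = transit_time_stats(transits, zones.gate_escoumins,
                            zones.gate_saintsimeon, proj)
    _write_csv(tt, out / "transit_times.csv", meta)

    elapsed = time.time() - t_begin
    with open(out / "run.log", "w") as fh:
        fh.write(json.dumps({**meta, "elapsed_s": round(elapsed, 2),
                             "n_transits": len(transits)}, default=str) + "\n")
    log.info("pipeline done in %.1f s", elapsed)
    return {"transits": transits, "indicators": ind, "portfolio": portfolio,
            "fits": fits, "ks": ks, "effectiveness": eff_rows,
            "transit_times": tt, "truth": truth, "out_dir": out, "meta": meta}
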