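"""End-to-end study pipeline: metrics → Markov-CA → valuation → sensitivity.

One structured config drives the full workflow on two or more dated
land-cover rasters: transition matrices and dynamic degrees per observed
pair, Markov calibration on the latest pair, CA simulation of the next
map, ESV for every date (observed and simulated), per-zone sensitivity
indices per period, and SI-change summaries between consecutive
periods. All artifacts are written to an output directory and indexed
in a JSON run report; given a fixed seed the run is deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

import lucc
from lucc.change_metrics import crosstab, dynamic_degrees
from lucc.grid_io import load_landcover, load_zones, write_landcover
from lucc.grids import ClassLegend, LandCoverGrid, ZoneMap, DEFAULT_LEGEND
from lucc.markov_ca import CASpec, ca_simulate, estimate_transition_probs
from lucc.sensitivity import classify_si_change, si_by_zone
from lucc.tables import load_class_mapping, load_crops, load_factors
from lucc.valuation import esv_by_zone, food_production_unit_value, unit_price_table

logger = logging.getLogger("lucc.pipeline")


@dataclass
class PipelineConfig:
    """Validated configuration of a full run.

    ``rasters`` maps date labels (sortable as numbers) to raster paths;
    ``crops`` maps date labels to crop-economics CSVs (a single path is
    reused for all dates). The simulated horizon extends the last
    observed period length beyond the final date.
    """

    rasters: dict[str, str]
    zones_path: str
    crops: dict[str, str] | str
    factors_path: str
    mapping_path: str | None = None
    legend: ClassLegend = field(default_factory=lambda: DEFAULT_LEGEND)
    seed: int = 0
    epsilon: float = 0.1
    area_tolerance: float = 0.005
    annualize: str = "linear"
    out_dir: str = "lucc_out"

    def __post_init__(self):
        if len(self.rasters) < 2:
            raise ValueError("pipeline needs at least two dated rasters")
        try:
            [float(d) for d in self.rasters]
        except ValueError as exc:
            raise ValueError("raster date labels must be numeric years") from exc

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) if path.suffix in (".yaml", ".yml") else json.load(fh)
        return cls(**raw)

    def crops_for(self, date: str) -> str:
        if isinstance(self.crops, str):
            return self.crops
        return self.crops[date]


@dataclass
class RunReport:
    """Machine-readable record of one pipeline run."""

    version: str
    config: dict
    outputs: dict[str, str]
    headline: dict
    warnings: list[str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "config": self.config,
                "outputs": self.outputs,
                "headline": self.headline,
                "warnings": self.warnings,
            },
            indent=2,
        )


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full workflow; see module docstring for the stages."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []
    outputs: dict[str, str] = {}
    headline: dict = {}

    dates = sorted(config.rasters, key=float)
    logger.info("loading %d rasters and zone map", len(dates))
    grids: dict[str, LandCoverGrid] = {
        d: load_landcover(config.rasters[d], config.legend, date_label=d) for d in dates
    }
    zones: ZoneMap = load_zones(config.zones_path)
    factors = load_factors(config.factors_path)
    class_map = (
        load_class_mapping(config.mapping_path) if config.mapping_path else None
    )

    # --- change metrics on every observed pair -------------------------
    observed_pairs = list(zip(dates[:-1], dates[1:]))
    tms = {}
    for d1, d2 in observed_pairs:
        T = float(d2) - float(d1)
        tm = crosstab(grids[d1], grids[d2], T)
        tms[(d1, d2)] = tm
        dd = dynamic_degrees(tm)
        prefix = out / f"metrics_{d1}_{d2}"
        tm.to_frame().to_csv(f"{prefix}_transition.csv")
        _dd_to_csv(dd, f"{prefix}_dynamic_degrees.csv")
        outputs[f"transition_{d1}_{d2}"] = f"{prefix}_transition.csv"
        outputs[f"dynamic_degrees_{d1}_{d2}"] = f"{prefix}_dynamic_degrees.csv"
        headline[f"cludd_{d1}_{d2}"] = dd.cludd
        if dd.undefined_classes:
            warnings_log.append(
                f"{d1}-{d2}: SLUDD undefined for {list(dd.undefined_classes)}"
            )
        logger.info("period %s-%s: CLUDD %.2f %%/a", d1, d2, dd.cludd)

    # --- Markov calibration on the latest pair, CA simulation ----------
    d1, d2 = observed_pairs[-1]
    T_last = float(d2) - float(d1)
    model = estimate_transition_probs(tms[(d1, d2)])
    sim_date = f"{float(d2) + T_last:g}"
    spec = CASpec(
        iterations=max(1, int(round(T_last))),
        seed=config.seed,
        epsilon=config.epsilon,
        area_tolerance=config.area_tolerance,
        annualize=config.annualize,
    )
    logger.info("simulating %s from %s (%d iterations)", sim_date, d2, spec.iterations)
    simulated = ca_simulate(grids[d2], model, spec)
    simulated.date_label = sim_date
    sim_path = out / f"simulated_{sim_date}.asc"
    write_landcover(simulated, sim_path)
    outputs[f"simulated_{sim_date}"] = str(sim_path)
    grids[sim_date] = simulated
    all_dates = dates + [sim_date]

    # metrics for the simulated period too
    tm_sim = crosstab(grids[d2], simulated, T_last)
    tms[(d2, sim_date)] = tm_sim
    dd_sim = dynamic_degrees(tm_sim)
    headline[f"cludd_{d2}_{sim_date}"] = dd_sim.cludd

    # --- valuation for every date --------------------------------------
    esvs = {}
    for d in all_dates:
        crops = load_crops(config.crops_for(d if d in dates else dates[-1]))
        e_a = food_production_unit_value(crops)
        prices = unit_price_table(e_a, factors, class_map)
        res = esv_by_zone(grids[d], zones, prices, year_label=d)
        esvs[d] = res
        path = out / f"esv_{d}.csv"
        res.by_class.to_frame("esv_yuan").to_csv(path)
        zpath = out / f"esv_zones_{d}.csv"
        frame = res.by_zone.to_frame("esv_yuan")
        frame["esv_yuan_per_km2"] = res.by_zone_per_km2
        frame.to_csv(zpath, index_label="zone")
        outputs[f"esv_{d}"] = str(path)
        outputs[f"esv_zones_{d}"] = str(zpath)
        headline[f"esv_total_{d}"] = res.total
        headline[f"E_a_{d}"] = e_a
        logger.info("ESV %s: %.4g Yuan (E_a %.2f Yuan/hm2/a)", d, res.total, e_a)

    # --- sensitivity per period and change summaries --------------------
    # prices of the last observed date drive SI (one consistent price set)
    crops = load_crops(config.crops_for(dates[-1]))
    prices = unit_price_table(food_production_unit_value(crops), factors, class_map)
    periods = list(zip(all_dates[:-1], all_dates[1:]))
    si_results = {}
    for p1, p2 in periods:
        res = si_by_zone(
            grids[p1], grids[p2], zones, prices, t1=float(p1), t2=float(p2)
        )
        si_results[(p1, p2)] = res
        path = out / f"si_{p1}_{p2}.csv"
        frame = res.si.to_frame("si")
        frame["esv_t1_1e9_yuan"] = res.esv_t1
        frame["esv_t2_1e9_yuan"] = res.esv_t2
        frame["cludd_pct_per_year"] = res.r
        frame.to_csv(path, index_label="zone")
        outputs[f"si_{p1}_{p2}"] = str(path)
        headline[f"si_zones_defined_{p1}_{p2}"] = int(res.si.notna().sum())
        if res.undefined_zones:
            warnings_log.append(
                f"SI undefined (no change) in {len(res.undefined_zones)} zones "
                f"for {p1}-{p2}"
            )

    summary_rows = []
    for (pa, pb) in zip(periods[:-1], periods[1:]):
        ra, rb = si_results[pa], si_results[pb]
        summ = classify_si_change(ra.si, rb.si, ra.zone_areas_km2)
        for key in ("increase", "decrease", "tie"):
            summary_rows.append(
                {
                    "compare": f"{pa[0]}-{pa[1]} vs {pb[0]}-{pb[1]}",
                    "change": key,
                    "n_zones": summ.counts[key],
                    "zone_share_pct": round(summ.count_shares_pct[key], 2),
                    "area_km2": summ.areas_km2[key],
                    "area_share_pct": round(summ.area_shares_pct[key], 2),
                }
            )
        headline[f"si_increase_share_{pa[0]}-{pa[1]}_vs_{pb[0]}-{pb[1]}"] = (
            summ.area_shares_pct["increase"]
        )
    if summary_rows:
        import pandas as pd

        spath = out / "si_change_summary.csv"
        pd.DataFrame(summary_rows).to_csv(spath, index=False)
        outputs["si_change_summary"] = str(spath)

    report = RunReport(
        version=lucc.__version__,
        config={
            "rasters": dict(config.rasters),
            "zones": config.zones_path,
            "factors": config.factors_path,
            "seed": config.seed,
            "epsilon": config.epsilon,
            "area_tolerance": config.area_tolerance,
            "annualize": config.annualize,
        },
        outputs=outputs,
        headline=headline,
        warnings=warnings_log,
    )
    rpath = out / "report.json"
    rpath.write_text(report.to_json())
    outputs["report"] = str(rpath)
    logger.info("run complete: %s", rpath)
    return report


def _dd_to_csv(dd, path: str) -> None:
    import pandas as pd

    rows = [{"class": k, "sludd_pct_per_year": v} for k, v in dd.sludd.items()]
    rows.append({"class": "__cludd__", "sludd_pct_per_year": dd.cludd})
    pd.DataFrame(rows).to_csv(path, index=False)
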