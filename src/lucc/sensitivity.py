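"""Sensitivity of ecosystem-service value to land-cover change.

An elasticity-style index relates the ESV change over a period to the
comprehensive land-use dynamic degree (CLUDD, ``R``) over the same
period::

    SI = |(ESV_t2 - ESV_t1) / R| * 1/(t2 - t1) * 100

``R`` enters as a percentage number (1.61, not 0.0161); the ESV unit is
the caller's choice and defaults to 10⁹ Yuan throughout this package. A
high SI flags an area where a small amount of land conversion moved a
large amount of service value. Where nothing changed (``R = 0``) the
index is undefined and flagged, never infinite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from lucc.change_metrics import cludd, crosstab
from lucc.grids import LandCoverGrid, ZoneMap, check_aligned
from lucc.valuation import HM2_PER_KM2, UnitPriceTable

#: Default ESV scale for SI: values expressed in 10⁹ Yuan.
DEFAULT_ESV_SCALE = 1e9


@dataclass
class SensitivityResult:
    """Per-zone sensitivity indices for one period, with their inputs.

    ``si`` is indexed by zone id (NaN where undefined); ``esv_t1`` /
    ``esv_t2`` are in the scale used for SI; ``r`` holds zonal CLUDDs
    (% per year); ``undefined_zones`` lists zones where R = 0.
    """

    si: pd.Series
    esv_t1: pd.Series
    esv_t2: pd.Series
    r: pd.Series
    t1: float
    t2: float
    undefined_zones: tuple[int, ...] = ()
    zone_areas_km2: pd.Series | None = None


@dataclass
class SIChangeSummary:
    """Zones classified by SI movement between two periods (Table-style).

    Counts, total areas (km²), and percentage shares for zones whose SI
    increased, decreased, or tied; shares are over the classified zones'
    area and sum to 100% up to rounding.
    """

    counts: dict[str, int]
    areas_km2: dict[str, float]
    area_shares_pct: dict[str, float]
    count_shares_pct: dict[str, float]
    excluded_zones: tuple[int, ...] = ()


def sensitivity_index(
    esv_t1: float, esv_t2: float, R: float, t1: float, t2: float
) -> float:
    """SI for one region and period; NaN (undefined) when R = 0.

    ESVs must share one unit; SI scales inversely with that unit, so
    report the convention alongside the number.
    """
    if t2 <= t1:
        raise ValueError("t2 must be after t1")
    if R == 0:
        return float("nan")
    return abs((esv_t2 - esv_t1) / R) / (t2 - t1) * 100.0


def si_by_zone(
    grid_t1: LandCoverGrid,
    grid_t2: LandCoverGrid,
    zones: ZoneMap,
    prices: UnitPriceTable,
    t1: float,
    t2: float,
    services: tuple[str, ...] | None = None,
    esv_scale: float = DEFAULT_ESV_SCALE,
) -> SensitivityResult:
    """Per-zone SI: zonal CLUDD from the zone-restricted transition
    matrix, zonal ESV at both dates, then the index.

    ``services`` restricts the valuation to a subset of the nine
    services (for service-specific sensitivity maps); default is all.
    Zones with no land change get an undefined (NaN) SI and are listed;
    zones with no valid cells are skipped with a warning.
    """
    check_aligned(grid_t1, grid_t2)
    check_aligned(grid_t1, zones, "grid and zones")
    if t2 <= t1:
        raise ValueError("t2 must be after t1")
    T = t2 - t1
    legend = grid_t1.legend
    cell_km2 = grid_t1.cell_area_km2
    price_rows = prices.prices if services is None else prices.prices.loc[list(services)]
    per_class_price = price_rows.sum(axis=0)

    si_vals: dict[int, float] = {}
    e1_vals: dict[int, float] = {}
    e2_vals: dict[int, float] = {}
    r_vals: dict[int, float] = {}
    areas: dict[int, float] = {}
    undefined: list[int] = []
    nodata = legend.nodata_code

    for zid in zones.zone_ids:
        zmask = zones.values == zid
        v1 = np.where(zmask, grid_t1.values, nodata)
        v2 = np.where(zmask, grid_t2.values, nodata)
        sub1 = grid_t1.copy_with(values=v1)
        sub2 = grid_t2.copy_with(values=v2)
        valid = ~(sub1.nodata_mask | sub2.nodata_mask)
        if not valid.any():
            warnings.warn(f"zone {zid} has no valid cells; skipped", stacklevel=2)
            continue
        tm = crosstab(sub1, sub2, T)
        r = cludd(tm)
        e1 = _zonal_esv(sub1, per_class_price, cell_km2) / esv_scale
        e2 = _zonal_esv(sub2, per_class_price, cell_km2) / esv_scale
        zid = int(zid)
        e1_vals[zid], e2_vals[zid], r_vals[zid] = e1, e2, r
        areas[zid] = float(valid.sum()) * cell_km2
        if r == 0:
            si_vals[zid] = float("nan")
            undefined.append(zid)
        else:
            si_vals[zid] = sensitivity_index(e1, e2, r, t1, t2)

    return SensitivityResult(
        si=pd.Series(si_vals, dtype=float),
        esv_t1=pd.Series(e1_vals, dtype=float),
        esv_t2=pd.Series(e2_vals, dtype=float),
        r=pd.Series(r_vals, dtype=float),
        t1=t1,
        t2=t2,
        undefined_zones=tuple(undefined),
        zone_areas_km2=pd.Series(areas, dtype=float),
    )


def _zonal_esv(grid: LandCoverGrid, per_class_price: pd.Series, cell_km2: float) -> float:
    counts = grid.class_counts()
    total = 0.0
    for name, n in zip(grid.legend.names, counts):
        if n and name in per_class_price.index:
            total += per_class_price[name] * n * cell_km2 * HM2_PER_KM2
    return total


def classify_si_change(
    si_period_a: pd.Series,
    si_period_b: pd.Series,
    zone_areas_km2: pd.Series,
) -> SIChangeSummary:
    """Classify zones by SI movement between two periods.

    Zones are split into ``increase`` (SI_b > SI_a), ``decrease``
    (SI_b < SI_a), and ``tie``; zones with an undefined SI in either
    period are excluded with a warning and listed. Shares are over the
    classified zones.
    """
    common = si_period_a.index.intersection(si_period_b.index)
    dropped = sorted(
        set(si_period_a.index.symmetric_difference(si_period_b.index))
    )
    excluded: list[int] = [int(z) for z in dropped]
    if dropped:
        warnings.warn(f"zones missing in one period excluded: {dropped}", stacklevel=2)

    counts = {"increase": 0, "decrease": 0, "tie": 0}
    areas = {"increase": 0.0, "decrease": 0.0, "tie": 0.0}
    for zid in common:
        a, b = si_period_a[zid], si_period_b[zid]
        if np.isnan(a) or np.isnan(b):
            excluded.append(int(zid))
            continue
        key = "increase" if b > a else ("decrease" if b < a else "tie")
        counts[key] += 1
        areas[key] += float(zone_areas_km2.get(zid, 0.0))
    if excluded and len(excluded) > len(dropped):
        warnings.warn(
            f"{len(excluded) - len(dropped)} zones with undefined SI excluded",
            stacklevel=2,
        )
    total_area = sum(areas.values())
    total_count = sum(counts.values())
    area_shares = {
        k: (100.0 * v / total_area if total_area > 0 else 0.0) for k, v in areas.items()
    }
    count_shares = {
        k: (100.0 * v / total_count if total_count > 0 else 0.0)
        for k, v in counts.items()
    }
    return SIChangeSummary(
        counts=counts,
        areas_km2=areas,
        area_shares_pct=area_shares,
        count_shares_pct=count_shares,
        excluded_zones=tuple(excluded),
    )
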