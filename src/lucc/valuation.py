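"""Equivalent-factor ecosystem-service valuation.

The method attaches a monetary value to each land-cover class by way of
one reference price: ``E_a``, the economic value of the food-production
service of one hectare of average cropland, defined as one seventh of
the area-weighted grain market value per hectare::

    E_a = (1/7) * sum_i(m_i * p_i * q_i) / M        [Yuan/hm²/a]

Unit prices of every service in every ecosystem follow by scaling the
unitless equivalent factors, ``E_ij = e_ij * E_a``, and the ecosystem
service value of a landscape is the area-weighted sum::

    ESV = sum_j A_j * sum_i E_ij                    [Yuan/a]

with areas in hm² (1 km² = 100 hm²). The 1/7 factor is the method's
fixed convention (one unit is one seventh of the grain value, reflecting
that natural ecosystems yield no marketed harvest).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from lucc.grids import LandCoverGrid, ZoneMap, check_aligned
from lucc.tables import SERVICE_NAMES, CropEconomics, EquivalentFactorTable

HM2_PER_KM2 = 100.0


@dataclass(frozen=True)
class UnitPriceTable:
    """Per-service, per-class unit prices E_ij in Yuan/hm²/a.

    Columns are land-cover class names (already resolved through the
    class→ecosystem mapping); a zero column marks a class whose service
    value is not counted (e.g. construction land by default).
    """

    prices: pd.DataFrame
    E_a: float

    def __post_init__(self):
        if (self.prices.to_numpy() < 0).any():
            raise ValueError("unit prices must be >= 0")
        missing = [s for s in SERVICE_NAMES if s not in self.prices.index]
        if missing:
            raise ValueError(f"unit-price table missing services: {missing}")

    @property
    def class_names(self) -> tuple[str, ...]:
        return tuple(self.prices.columns)

    def per_class_total(self) -> pd.Series:
        """Sum of all nine service prices per class, Yuan/hm²/a."""
        return self.prices.sum(axis=0)


@dataclass
class ESVResult:
    """Ecosystem-service value decomposed by class, service, and zone.

    ``by_class`` and ``by_service`` always sum to ``total``; ``by_zone``
    does too whenever the zones partition the analyzed cells.
    ``by_zone_per_km2`` is value density in Yuan/km² of zone area.
    """

    total: float
    by_class: pd.Series
    by_service: pd.Series
    year_label: str = ""
    by_zone: pd.Series | None = None
    by_zone_per_km2: pd.Series | None = None
    by_zone_service: pd.DataFrame | None = None


def food_production_unit_value(crops: CropEconomics) -> float:
    """E_a (Yuan/hm²/a) from sowing areas, prices, and yields (Eq. above)."""
    num = sum(m * p * q for _, m, p, q in crops.records)
    return num / crops.M / 7.0


def unit_price_table(
    E_a: float,
    factors: EquivalentFactorTable,
    class_map: dict[str, str | None] | None = None,
) -> UnitPriceTable:
    """Scale equivalent factors into unit prices, resolved per class.

    ``class_map`` sends each land-cover class name to an ecosystem
    column of the factor table, or to ``None`` for classes whose service
    value is excluded (zero column). Without a map the factor columns
    are used as class names directly.
    """
    if E_a < 0:
        raise ValueError("E_a must be >= 0")
    scaled = factors.factors * E_a
    if class_map is None:
        return UnitPriceTable(prices=scaled, E_a=E_a)
    cols = {}
    for cls, eco in class_map.items():
        if eco is None:
            cols[cls] = pd.Series(0.0, index=scaled.index)
        else:
            if eco not in scaled.columns:
                raise ValueError(
                    f"class {cls!r} maps to unknown ecosystem {eco!r}"
                )
            cols[cls] = scaled[eco]
    return UnitPriceTable(prices=pd.DataFrame(cols), E_a=E_a)


def _areas_km2(source, prices: UnitPriceTable) -> pd.Series:
    """Per-class areas in km² from a grid or an explicit mapping."""
    if isinstance(source, LandCoverGrid):
        areas = pd.Series(source.class_areas_km2(), index=list(source.legend.names))
    else:
        areas = pd.Series(source, dtype=float)
    unpriced = [c for c in areas.index if areas[c] > 0 and c not in prices.class_names]
    if unpriced:
        raise ValueError(
            f"classes with positive area but no price column: {unpriced}"
        )
    return areas


def esv_totals(
    source: LandCoverGrid | dict[str, float] | pd.Series,
    prices: UnitPriceTable,
    year_label: str = "",
) -> ESVResult:
    """Total ESV (Yuan/a) with by-class and by-service decompositions.

    ``source`` is either a land-cover grid or per-class areas in km².
    """
    areas = _areas_km2(source, prices)
    common = [c for c in areas.index if c in prices.class_names]
    a_hm2 = areas[common] * HM2_PER_KM2
    by_class = prices.per_class_total()[common] * a_hm2
    by_service = prices.prices[common] @ a_hm2
    total = float(by_class.sum())
    return ESVResult(
        total=total,
        by_class=by_class,
        by_service=by_service,
        year_label=year_label,
    )


def esv_by_zone(
    grid: LandCoverGrid,
    zones: ZoneMap,
    prices: UnitPriceTable,
    year_label: str = "",
) -> ESVResult:
    """ESV aggregated over an administrative-zone raster.

    Per zone: class areas × prices, plus value density per km² of zone
    area. Zone values sum to the regional total when zones cover every
    analyzed cell.
    """
    check_aligned(grid, zones, "grid and zones")
    regional = esv_totals(grid, prices, year_label)
    legend = grid.legend
    cell_km2 = grid.cell_area_km2
    valid = ~grid.nodata_mask
    per_class_price = prices.per_class_total()

    zone_vals: dict[int, float] = {}
    zone_dens: dict[int, float] = {}
    zone_service: dict[int, pd.Series] = {}
    for zid in zones.zone_ids:
        zmask = (zones.values == zid) & valid
        n_zone = int(zmask.sum())
        if n_zone == 0:
            continue
        counts = np.array(
            [int(np.count_nonzero(grid.values[zmask] == c)) for c in legend.codes]
        )
        a_hm2 = pd.Series(counts * cell_km2 * HM2_PER_KM2, index=list(legend.names))
        common = [c for c in a_hm2.index if c in prices.class_names]
        val = float((per_class_price[common] * a_hm2[common]).sum())
        zone_vals[int(zid)] = val
        zone_dens[int(zid)] = val / (n_zone * cell_km2)
        zone_service[int(zid)] = prices.prices[common] @ a_hm2[common]

    by_zone = pd.Series(zone_vals, dtype=float)
    return ESVResult(
        total=regional.total,
        by_class=regional.by_class,
        by_service=regional.by_service,
        year_label=year_label,
        by_zone=by_zone,
        by_zone_per_km2=pd.Series(zone_dens, dtype=float),
        by_zone_service=pd.DataFrame(zone_service).T,
    )
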