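"""Categorical raster containers: class legend, land-cover grid, zone map.

All arrays are row-major, 0-based ``(row, col)``. Geospatial referencing is
reduced to the cell size: every computation downstream is per-cell, so a
full geotransform would be dead weight. Areas are reported in km²
(a 30 m cell is 0.0009 km²).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ClassLegend:
    """Mapping of integer raster codes to land-cover class names.

    Parameters
    ----------
    entries
        Sequence of ``(code, name)`` pairs. Codes must be unique,
        non-negative integers; names must be unique.
    nodata_code
        Integer marking cells outside the analysis area. Must not collide
        with a class code.
    """

    entries: tuple[tuple[int, str], ...]
    nodata_code: int = 0

    def __post_init__(self):
        object.__setattr__(self, "entries", tuple((int(c), str(n)) for c, n in self.entries))
        codes = [c for c, _ in self.entries]
        names = [n for _, n in self.entries]
        if len(set(codes)) != len(codes):
            raise ValueError("legend codes must be unique")
        if len(set(names)) != len(names):
            raise ValueError("legend names must be unique")
        if any(c < 0 for c in codes):
            raise ValueError("legend codes must be non-negative")
        if self.nodata_code in codes:
            raise ValueError(f"nodata_code {self.nodata_code} collides with a class code")

    @property
    def codes(self) -> tuple[int, ...]:
        return tuple(c for c, _ in self.entries)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for _, n in self.entries)

    @property
    def n_classes(self) -> int:
        return len(self.entries)

    def name_of(self, code: int) -> str:
        for c, n in self.entries:
            if c == code:
                return n
        raise KeyError(f"code {code} not in legend")

    def code_of(self, name: str) -> int:
        for c, n in self.entries:
            if n == name:
                return c
        raise KeyError(f"class {name!r} not in legend")

    def index_of(self, code: int) -> int:
        """Position of ``code`` in the legend's fixed class order."""
        try:
            return self.codes.index(code)
        except ValueError:
            raise KeyError(f"code {code} not in legend") from None


#: Seven-class legend standard in Chinese land-use survey work:
#: cropland, forestland, grassland, wetland, waterbody, construction
#: land, unused land. Code 0 is nodata.
DEFAULT_LEGEND = ClassLegend(
    entries=(
        (1, "cropland"),
        (2, "forestland"),
        (3, "grassland"),
        (4, "wetland"),
        (5, "waterbody"),
        (6, "construction land"),
        (7, "unused land"),
    ),
    nodata_code=0,
)


@dataclass
class LandCoverGrid:
    """A single-date categorical land-cover raster.

    ``values`` holds legend codes; every non-nodata value must be a legend
    code. ``cell_size_m`` is the side length of the square cell in meters.
    """

    values: np.ndarray
    cell_size_m: float
    legend: ClassLegend = DEFAULT_LEGEND
    date_label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("land-cover values must be a 2-D array")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("land-cover values must be integers")
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")
        allowed = set(self.legend.codes) | {self.legend.nodata_code}
        present = set(np.unique(self.values).tolist())
        unknown = sorted(present - allowed)
        if unknown:
            raise ValueError(f"values contain codes not in legend: {unknown}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size_m / 1000.0) ** 2

    @property
    def nodata_mask(self) -> np.ndarray:
        return self.values == self.legend.nodata_code

    def class_counts(self) -> np.ndarray:
        """Cell counts per class in legend order."""
        return np.array(
            [int(np.count_nonzero(self.values == c)) for c in self.legend.codes]
        )

    def class_areas_km2(self) -> np.ndarray:
        """Class areas in km², legend order."""
        return self.class_counts() * self.cell_area_km2

    def copy_with(self, values: np.ndarray, date_label: str | None = None) -> "LandCoverGrid":
        return LandCoverGrid(
            values=values,
            cell_size_m=self.cell_size_m,
            legend=self.legend,
            date_label=self.date_label if date_label is None else date_label,
        )


@dataclass
class ZoneMap:
    """Raster of administrative-unit (township-style) identifiers.

    Zone ids are non-negative integers; cells with ``nodata_id`` belong to
    no zone. Must share the shape of any land-cover grid it aggregates.
    """

    values: np.ndarray
    zone_names: dict[int, str] = field(default_factory=dict)
    nodata_id: int = -1

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("zone values must be a 2-D array")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("zone ids must be integers")
        ids = np.unique(self.values)
        ids = ids[ids != self.nodata_id]
        if ids.size and ids.min() < 0:
            raise ValueError("zone ids must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def zone_ids(self) -> np.ndarray:
        ids = np.unique(self.values)
        return ids[ids != self.nodata_id]

    def name_of(self, zone_id: int) -> str:
        return self.zone_names.get(int(zone_id), f"zone_{int(zone_id)}")


def check_aligned(a, b, what: str = "grids") -> None:
    """Raise if two rasters cannot be overlaid cell-by-cell."""
    if a.shape != b.shape:
        raise ValueError(f"{what} have different shapes: {a.shape} vs {b.shape}")
    if isinstance(a, LandCoverGrid) and isinstance(b, LandCoverGrid):
        if a.legend.codes != b.legend.codes:
            raise ValueError(f"{what} have different legends")
        if not np.isclose(a.cell_size_m, b.cell_size_m):
            raise ValueError(
                f"{what} have different cell sizes: {a.cell_size_m} vs {b.cell_size_m}"
            )
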