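"""Tabular inputs: crop economics and the equivalent-factor table.

The equivalent-factor method expresses every ecosystem service as a
unitless multiple ``e_ij`` of one reference unit: the annual market value
of grain produced on one hectare of average cropland (``E_a``). The
factor table has nine fixed service rows; its columns are ecosystem
types, and a separate class→ecosystem mapping connects land-cover
classes to those columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: The nine ecosystem-service functions, fixed order.
SERVICE_NAMES = (
    "food production",
    "raw material production",
    "gas regulation",
    "climate regulation",
    "hydrology regulation",
    "waste treatment",
    "soil conservation",
    "biodiversity maintenance",
    "aesthetic landscape provision",
)

CROPS_COLUMNS = ("crop", "sowing_area_hm2", "price_yuan_per_t", "yield_t_per_hm2")


@dataclass(frozen=True)
class CropEconomics:
    """Sowing areas, prices, and yields of the region's grain crops.

    ``records`` rows are ``(crop_name, m_i [hm²], p_i [Yuan/t],
    q_i [t/hm²/a])``; ``M`` is the total sowing area in hm².
    """

    records: tuple[tuple[str, float, float, float], ...]
    M: float

    def __post_init__(self):
        for name, m, p, q in self.records:
            if m < 0 or p < 0 or q < 0:
                raise ValueError(f"crop {name!r}: area, price, and yield must be >= 0")
        if self.M <= 0:
            raise ValueError("total sowing area M must be positive")

    @classmethod
    def from_records(cls, records, M: float | None = None) -> "CropEconomics":
        recs = tuple((str(n), float(m), float(p), float(q)) for n, m, p, q in records)
        if M is None:
            M = sum(m for _, m, _, _ in recs)
        return cls(records=recs, M=float(M))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.records), columns=list(CROPS_COLUMNS))


@dataclass(frozen=True)
class EquivalentFactorTable:
    """Unitless factors e_ij: 9 services (rows) × ecosystem types (columns)."""

    factors: pd.DataFrame

    def __post_init__(self):
        df = self.factors
        missing = [s for s in SERVICE_NAMES if s not in df.index]
        if missing:
            raise ValueError(f"factor table missing service rows: {missing}")
        extra = [s for s in df.index if s not in SERVICE_NAMES]
        if extra:
            raise ValueError(f"factor table has unknown service rows: {extra}")
        if (df.to_numpy() < 0).any():
            raise ValueError("equivalent factors must be >= 0")
        # canonical row order
        object.__setattr__(self, "factors", df.loc[list(SERVICE_NAMES)].astype(float))

    @property
    def ecosystems(self) -> tuple[str, ...]:
        return tuple(self.factors.columns)


def load_crops(path: str | Path) -> CropEconomics:
    """Read the crop-economics CSV (columns: crop, sowing_area_hm2,
    price_yuan_per_t, yield_t_per_hm2). Total sowing area is the column sum."""
    df = pd.read_csv(path)
    missing = [c for c in CROPS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"crops CSV missing columns: {missing}")
    return CropEconomics.from_records(
        df[list(CROPS_COLUMNS)].itertuples(index=False, name=None)
    )


def load_factors(path: str | Path) -> EquivalentFactorTable:
    """Read the equivalent-factor CSV: first column ``service`` (the nine
    fixed names), remaining columns one per ecosystem type."""
    df = pd.read_csv(path)
    first = df.columns[0]
    df = df.set_index(first)
    df.index.name = "service"
    return EquivalentFactorTable(factors=df)


def load_tables(
    crops_path: str | Path, factors_path: str | Path
) -> tuple[CropEconomics, EquivalentFactorTable]:
    return load_crops(crops_path), load_factors(factors_path)


def write_crops(crops: CropEconomics, path: str | Path) -> None:
    crops.to_frame().to_csv(path, index=False)


def write_factors(table: EquivalentFactorTable, path: str | Path) -> None:
    table.factors.to_csv(path, index_label="service")


def load_class_mapping(path: str | Path) -> dict[str, str | None]:
    """Read the class→ecosystem mapping CSV (columns: class, ecosystem).

    An empty/'none' ecosystem marks the class as zero-value (e.g.
    construction land when its service value is not counted).
    """
    df = pd.read_csv(path)
    if "class" not in df.columns or "ecosystem" not in df.columns:
        raise ValueError("mapping CSV needs columns: class, ecosystem")
    out: dict[str, str | None] = {}
    for _, row in df.iterrows():
        eco = row["ecosystem"]
        if pd.isna(eco) or str(eco).strip().lower() in ("", "none", "zero"):
            out[str(row["class"])] = None
        else:
            out[str(row["class"])] = str(eco)
    return out
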