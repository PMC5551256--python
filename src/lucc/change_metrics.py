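"""Transition matrices, land-use dynamic degrees, and map agreement.

The single land-use dynamic degree (SLUDD) annualizes one class's
relative area change::

    K = (U_b - U_a) / U_a * (1/T) * 100        [% per year]

The comprehensive land-use dynamic degree (CLUDD) annualizes the share
of the landscape that changed class — the sum of all off-diagonal
transition areas over the total area at period start::

    R = (sum_{i != j} dLU_{i->j}) / (sum_i LU_i) * (1/T) * 100

Both carry their period T in years, so decade tables give per-year
percentages directly. Cohen's kappa measures chance-corrected
cell-by-cell agreement between two categorical maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lucc.grids import LandCoverGrid, check_aligned


@dataclass
class TransitionMatrix:
    """Class-by-class converted areas between two dates.

    ``areas[i, j]`` is the area (km²) that was class ``i`` at the start
    date and class ``j`` at the end date; class order follows
    ``class_names``. Row totals are start-date class areas, column totals
    end-date class areas.
    """

    areas: np.ndarray
    class_names: tuple[str, ...]
    period_years: float
    t1_label: str = ""
    t2_label: str = ""

    def __post_init__(self):
        self.areas = np.asarray(self.areas, dtype=float)
        n = len(self.class_names)
        if self.areas.shape != (n, n):
            raise ValueError(
                f"areas must be {n}x{n} to match class_names, got {self.areas.shape}"
            )
        if (self.areas < 0).any():
            raise ValueError("transition areas must be >= 0")
        if self.period_years <= 0:
            raise ValueError("period_years must be positive")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def row_totals(self) -> np.ndarray:
        """Class areas at the start date (LU_i), km²."""
        return self.areas.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        """Class areas at the end date, km²."""
        return self.areas.sum(axis=0)

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    @property
    def changed_area(self) -> float:
        """Sum of off-diagonal entries: total converted area, km²."""
        return float(self.areas.sum() - np.trace(self.areas))

    def net_change(self) -> np.ndarray:
        """Per-class net area change (end minus start), km²."""
        return self.col_totals - self.row_totals

    def to_frame(self) -> pd.DataFrame:
        """Row/column-labelled table with marginal totals appended."""
        df = pd.DataFrame(self.areas, index=self.class_names, columns=self.class_names)
        df["Total"] = df.sum(axis=1)
        df.loc["Total"] = df.sum(axis=0)
        return df


@dataclass
class DynamicDegrees:
    """SLUDD per class (NaN where undefined) and scalar CLUDD, % per year."""

    sludd: dict[str, float]
    cludd: float
    undefined_classes: tuple[str, ...] = field(default_factory=tuple)


@dataclass
class AgreementStats:
    """Observed and chance-expected cell agreement, and Cohen's kappa."""

    observed_agreement: float
    expected_agreement: float
    kappa: float
    n_cells: int


def crosstab(
    grid_t1: LandCoverGrid, grid_t2: LandCoverGrid, T: float
) -> TransitionMatrix:
    """Cross-tabulate two co-registered land-cover maps into a transition
    matrix of areas (km²) over a period of ``T`` years.

    Cells that are nodata in either map are excluded from both, so the
    matrix marginals are the class areas over the jointly valid region.
    """
    check_aligned(grid_t1, grid_t2)
    if T <= 0:
        raise ValueError("period T must be positive")
    legend = grid_t1.legend
    valid = ~(grid_t1.nodata_mask | grid_t2.nodata_mask)
    code_to_idx = {c: i for i, c in enumerate(legend.codes)}
    lut = np.full(max(legend.codes) + 1, -1, dtype=np.int64)
    for c, i in code_to_idx.items():
        lut[c] = i
    a = lut[grid_t1.values[valid]]
    b = lut[grid_t2.values[valid]]
    n = legend.n_classes
    counts = np.bincount(a * n + b, minlength=n * n).reshape(n, n)
    return TransitionMatrix(
        areas=counts * grid_t1.cell_area_km2,
        class_names=legend.names,
        period_years=float(T),
        t1_label=grid_t1.date_label,
        t2_label=grid_t2.date_label,
    )


def sludd(area_start: float, area_end: float, T: float) -> float:
    """Single land-use dynamic degree, % per year.

    ``K = (U_b - U_a)/U_a × (1/T) × 100``. Undefined when the class is
    absent at the start date (``area_start == 0``).
    """
    if T <= 0:
        raise ValueError("period T must be positive")
    if area_start <= 0:
        raise ValueError(
            "SLUDD is undefined for a class with zero area at the start date"
        )
    return (area_end - area_start) / area_start / T * 100.0


def cludd(tm: TransitionMatrix) -> float:
    """Comprehensive land-use dynamic degree, % per year.

    Off-diagonal (converted) area over total start area, annualized.
    """
    total = tm.total_area
    if total <= 0:
        raise ValueError("transition matrix covers zero area")
    return tm.changed_area / total / tm.period_years * 100.0


def dynamic_degrees(tm: TransitionMatrix) -> DynamicDegrees:
    """SLUDD for every class plus the CLUDD, from one transition matrix.

    Classes absent at the start date get SLUDD NaN and are listed in
    ``undefined_classes`` instead of producing infinities.
    """
    start = tm.row_totals
    end = tm.col_totals
    per_class: dict[str, float] = {}
    undefined: list[str] = []
    for i, name in enumerate(tm.class_names):
        if start[i] > 0:
            per_class[name] = sludd(start[i], end[i], tm.period_years)
        else:
            per_class[name] = float("nan")
            undefined.append(name)
    return DynamicDegrees(
        sludd=per_class, cludd=cludd(tm), undefined_classes=tuple(undefined)
    )


def cohen_kappa(grid_a: LandCoverGrid, grid_b: LandCoverGrid) -> AgreementStats:
    """Cohen's kappa between two aligned categorical maps.

    Computed from the cell-by-cell confusion matrix: ``kappa =
    (p_o - p_e) / (1 - p_e)`` with ``p_o`` the observed agreement and
    ``p_e`` the agreement expected from the marginal class shares.
    """
    check_aligned(grid_a, grid_b)
    valid = ~(grid_a.nodata_mask | grid_b.nodata_mask)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("no overlapping non-nodata cells")
    a = grid_a.values[valid]
    b = grid_b.values[valid]
    p_o = float(np.mean(a == b))
    codes = grid_a.legend.codes
    pa = np.array([np.count_nonzero(a == c) for c in codes]) / n_valid
    pb = np.array([np.count_nonzero(b == c) for c in codes]) / n_valid
    p_e = float(pa @ pb)
    kappa = 1.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    return AgreementStats(
        observed_agreement=p_o, expected_agreement=p_e, kappa=kappa, n_cells=n_valid
    )


def kappa_from_confusion(confusion: np.ndarray) -> AgreementStats:
    """Cohen's kappa from a precomputed confusion-count matrix."""
    confusion = np.asarray(confusion, dtype=float)
    n = confusion.sum()
    if n <= 0:
        raise ValueError("empty confusion matrix")
    p_o = float(np.trace(confusion) / n)
    p_e = float(confusion.sum(axis=1) @ confusion.sum(axis=0) / n**2)
    kappa = 1.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    return AgreementStats(
        observed_agreement=p_o, expected_agreement=p_e, kappa=kappa, n_cells=int(n)
    )
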