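"""Synthetic landscapes with known transition structure.

Everything downstream (change metrics, Markov estimation, CA
simulation, valuation, sensitivity) is exercised against landscapes
whose generating process is known exactly: patchy categorical maps from
multi-seed region growing, temporal evolution under a chosen
row-stochastic kernel with optional clustering bias, Voronoi zone
partitions, and plausible crop-economics / equivalent-factor tables.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from lucc.grids import ClassLegend, LandCoverGrid, ZoneMap, DEFAULT_LEGEND
from lucc.markov_ca import neighbor_fractions
from lucc.tables import SERVICE_NAMES, CropEconomics, EquivalentFactorTable

_SUM_TOL = 1e-9


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic landscape series.

    ``class_weights`` are target area shares per legend class;
    ``patchiness`` is the mean patch size in cells (1 = i.i.d. noise);
    ``kernel`` is the row-stochastic matrix used to evolve the landscape
    between dates; ``clustering_strength`` in [0, 1] biases evolution
    toward classes already present in a cell's neighborhood.
    """

    shape: tuple[int, int] = (256, 256)
    class_weights: np.ndarray | None = None
    patchiness: float = 40.0
    seed: int = 0
    kernel: np.ndarray | None = None
    clustering_strength: float = 0.3
    legend: ClassLegend = field(default_factory=lambda: DEFAULT_LEGEND)

    def __post_init__(self):
        n = self.legend.n_classes
        if self.class_weights is None:
            self.class_weights = np.full(n, 1.0 / n)
        self.class_weights = np.asarray(self.class_weights, dtype=float)
        if self.class_weights.shape != (n,):
            raise ValueError(f"class_weights must have length {n}")
        if abs(self.class_weights.sum() - 1.0) > _SUM_TOL:
            raise ValueError("class_weights must sum to 1")
        if (self.class_weights < 0).any():
            raise ValueError("class_weights must be >= 0")
        if self.patchiness < 1:
            raise ValueError("patchiness must be >= 1 cell")
        if not 0.0 <= self.clustering_strength <= 1.0:
            raise ValueError("clustering_strength must be in [0, 1]")
        if self.kernel is not None:
            self.kernel = _check_kernel(np.asarray(self.kernel, dtype=float), n)


def _check_kernel(kernel: np.ndarray, n: int) -> np.ndarray:
    if kernel.shape != (n, n):
        raise ValueError(f"kernel must be {n}x{n}, got {kernel.shape}")
    if (kernel < 0).any():
        raise ValueError("kernel entries must be >= 0")
    if not np.allclose(kernel.sum(axis=1), 1.0, atol=_SUM_TOL):
        raise ValueError("kernel rows must sum to 1")
    return kernel


def _voronoi_labels(shape: tuple[int, int], n_seeds: int, rng) -> np.ndarray:
    """Partition a grid into ``n_seeds`` contiguous cells by nearest seed.

    Equivalent to growing all regions simultaneously at uniform speed
    from random seed cells; Euclidean Voronoi cells are convex, so every
    rasterized region is connected and non-empty (it contains its seed).
    """
    rows, cols = shape
    n_cells = rows * cols
    if n_seeds > n_cells:
        raise ValueError(f"cannot place {n_seeds} seeds on {n_cells} cells")
    flat = rng.choice(n_cells, size=n_seeds, replace=False)
    seeds = np.zeros(shape, dtype=bool)
    seeds.ravel()[flat] = True
    # distance to nearest seed; indices of that seed
    _, (ir, ic) = ndimage.distance_transform_edt(~seeds, return_indices=True)
    seed_label = np.full(shape, -1, dtype=np.int64)
    seed_label.ravel()[flat] = np.arange(n_seeds)
    return seed_label[ir, ic]


def default_evolution_kernel(n_classes: int, persistence: float = 0.92) -> np.ndarray:
    """A diagonal-dominant row-stochastic kernel: each class persists
    with probability ``persistence`` and spreads the rest uniformly —
    the magnitude of decadal land-cover persistence in regional
    transition tables."""
    if not 0.0 < persistence <= 1.0:
        raise ValueError("persistence must be in (0, 1]")
    off = (1.0 - persistence) / (n_classes - 1) if n_classes > 1 else 0.0
    kernel = np.full((n_classes, n_classes), off)
    np.fill_diagonal(kernel, persistence)
    return kernel


def generate_landscape(spec: SyntheticSpec, date_label: str = "t0") -> LandCoverGrid:
    """Generate a patchy categorical landscape.

    The grid is split into roughly ``n_cells / patchiness`` contiguous
    patches by seeded region growing, and each patch is assigned a class
    drawn from ``class_weights``. With many patches the realized class
    shares concentrate tightly around the weights, while like-class
    adjacency stays far above the i.i.d. (shuffled) expectation.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    n_cells = rows * cols
    n_patches = max(1, int(round(n_cells / spec.patchiness)))
    labels = _voronoi_labels(spec.shape, n_patches, rng)
    codes = np.array(spec.legend.codes)
    # quota assignment: each class gets its share of patches (largest
    # remainder), shuffled over patch ids — tighter realized proportions
    # than i.i.d. class draws, at identical patch structure
    from lucc.markov_ca import largest_remainder

    quota = largest_remainder(spec.class_weights * n_patches, n_patches)
    patch_classes = np.repeat(codes, quota)
    rng.shuffle(patch_classes)
    return LandCoverGrid(
        values=patch_classes[labels],
        cell_size_m=30.0,
        legend=spec.legend,
        date_label=date_label,
    )


def evolve_landscape(
    grid: LandCoverGrid,
    kernel: np.ndarray,
    clustering_strength: float = 0.0,
    seed: int = 0,
    date_label: str = "",
) -> LandCoverGrid:
    """Advance a landscape one step under a known Markov kernel.

    Each cell's next class is drawn from its current class's kernel row,
    with the probability of class ``j`` re-weighted by
    ``(1 + clustering_strength * f_j)`` and renormalized, where ``f_j``
    is the fraction of the cell's 12 von Neumann radius-2 neighbors in
    class ``j``. With ``clustering_strength = 0`` the draw is exactly
    the kernel row, so empirical transition frequencies estimate the
    kernel consistently.
    """
    n = grid.legend.n_classes
    kernel = _check_kernel(np.asarray(kernel, dtype=float), n)
    if not 0.0 <= clustering_strength <= 1.0:
        raise ValueError("clustering_strength must be in [0, 1]")
    rng = np.random.default_rng(seed)
    codes = grid.legend.codes
    valid = ~grid.nodata_mask
    lut = np.full(max(codes) + 1, -1, dtype=np.int64)
    for i, c in enumerate(codes):
        lut[c] = i
    idx = lut[grid.values[valid]]

    weights = kernel[idx]  # (n_valid, n_class)
    if clustering_strength > 0:
        f = neighbor_fractions(grid.values, codes, valid)
        weights = weights * (1.0 + clustering_strength * f[:, valid].T)
    weights = weights / weights.sum(axis=1, keepdims=True)

    u = rng.random(weights.shape[0])
    cum = np.cumsum(weights, axis=1)
    draw = (cum < u[:, None]).sum(axis=1)
    draw = np.minimum(draw, n - 1)  # guard against round-off at 1.0

    out = grid.values.copy()
    out[valid] = np.array(codes)[draw]
    return grid.copy_with(values=out, date_label=date_label or grid.date_label)


def generate_zones(shape: tuple[int, int], n_zones: int, seed: int = 0) -> ZoneMap:
    """Partition a grid into ``n_zones`` contiguous zones (ids 0..n-1)
    by seeded Voronoi growth; every cell belongs to exactly one zone."""
    if n_zones < 1:
        raise ValueError("n_zones must be >= 1")
    rng = np.random.default_rng(seed)
    labels = _voronoi_labels(shape, n_zones, rng)
    return ZoneMap(values=labels)


def synthetic_crop_economics(seed: int | None = None) -> CropEconomics:
    """A plausible highland crop-economics table (synthetic stand-in).

    Three grain crops with magnitudes typical of high-plateau statistics
    yearbooks: sowing areas in the 10³–10⁴ hm² range, grain prices around
    1500–2500 Yuan/t, yields of 2–4 t/hm²/a. With a seed, areas, prices,
    and yields are jittered ±10% for property testing.
    """
    base = [
        ("wheat", 21000.0, 2100.0, 3.2),
        ("coarse cereal", 14000.0, 1700.0, 2.6),
        ("tuber crop", 6000.0, 1500.0, 3.8),
    ]
    if seed is not None:
        rng = np.random.default_rng(seed)
        base = [
            (name, m * rng.uniform(0.9, 1.1), p * rng.uniform(0.9, 1.1), q * rng.uniform(0.9, 1.1))
            for name, m, p, q in base
        ]
    return CropEconomics.from_records(base)


#: Ecosystem columns of the synthetic factor table, and the default
#: mapping from the seven land-cover classes onto them. Construction
#: land maps to no ecosystem (zero service value) by default.
SYNTHETIC_ECOSYSTEMS = (
    "cropland", "forestland", "grassland", "wetland", "waterbody", "unused land",
)

DEFAULT_CLASS_ECOSYSTEM_MAP: dict[str, str | None] = {
    "cropland": "cropland",
    "forestland": "forestland",
    "grassland": "grassland",
    "wetland": "wetland",
    "waterbody": "waterbody",
    "construction land": None,
    "unused land": "unused land",
}

_SYNTHETIC_FACTORS = np.array(
    [
        # cropland, forest, grass, wetland, water, unused
        [1.00, 0.33, 0.43, 0.36, 0.53, 0.02],  # food production
        [0.39, 2.98, 0.36, 0.24, 0.35, 0.04],  # raw material production
        [0.72, 4.32, 1.50, 2.41, 0.51, 0.06],  # gas regulation
        [0.97, 4.07, 1.56, 13.55, 2.06, 0.13],  # climate regulation
        [0.77, 4.09, 1.52, 13.44, 18.77, 0.07],  # hydrology regulation
        [1.39, 1.72, 1.32, 14.40, 14.85, 0.26],  # waste treatment
        [1.47, 4.02, 2.24, 1.99, 0.41, 0.17],  # soil conservation
        [1.02, 4.51, 1.87, 3.69, 3.43, 0.40],  # biodiversity maintenance
        [0.17, 2.08, 0.87, 4.69, 4.44, 0.24],  # aesthetic landscape provision
    ]
)


def synthetic_factor_table() -> EquivalentFactorTable:
    """A synthetic 9-service × 6-ecosystem equivalent-factor table.

    The values follow the conventional structure of Chinese
    equivalent-factor systems (cropland food production = 1; wetlands
    and waterbodies dominate hydrology regulation and waste treatment;
    forests dominate gas regulation and raw materials) but are synthetic
    stand-ins, not any published calibration.
    """
    df = pd.DataFrame(
        _SYNTHETIC_FACTORS,
        index=list(SERVICE_NAMES),
        columns=list(SYNTHETIC_ECOSYSTEMS),
    )
    df.index.name = "service"
    return EquivalentFactorTable(factors=df)
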