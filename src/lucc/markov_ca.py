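"""Markov-chain area projection and cellular-automaton spatial allocation.

The Markov side answers *how much*: transition probabilities estimated
from an observed transition matrix project per-class areas forward. The
CA side answers *where*: projected areas become integer cell targets,
and cells are reallocated iteratively (one iteration per year) by a
score combining each cell's suitability for a class with the class's
presence in the cell's von Neumann radius-2 neighborhood (the 12 cells
within Manhattan distance 2, i.e. a 5×5 von Neumann rule).

Suitability surfaces are the Markov conditional probabilities broadcast
per cell: the suitability of cell ``x`` for class ``j`` is
``P[current_class(x), j]`` — history-only, with no covariates.

Allocation rule per iteration: interim targets are linearly
interpolated between initial and final counts; classes above target
release their lowest-scoring cells, classes below target claim released
cells greedily by descending score ``S_j(x) * (epsilon + f_j(x))``,
where ``f_j`` is the neighbor fraction of class ``j`` and ``epsilon``
lets new patches nucleate away from existing ones. Ties are broken by a
seeded random priority fixed per run, so output is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from lucc.change_metrics import TransitionMatrix
from lucc.grids import LandCoverGrid, check_aligned

_ROW_SUM_TOL = 1e-9


@dataclass
class MarkovModel:
    """Row-stochastic transition probabilities over one period of T years."""

    P: np.ndarray
    class_names: tuple[str, ...]
    period_years: float

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float)
        n = len(self.class_names)
        if self.P.shape != (n, n):
            raise ValueError(f"P must be {n}x{n}, got {self.P.shape}")
        if (self.P < 0).any():
            raise ValueError("transition probabilities must be >= 0")
        rows = self.P.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-6):
            raise ValueError(f"rows of P must sum to 1, got sums {rows}")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


@dataclass
class SuitabilitySurfaces:
    """One suitability grid per class, values in [0, 1], legend order."""

    surfaces: np.ndarray  # (n_class, rows, cols)
    class_names: tuple[str, ...]

    def for_class(self, name: str) -> np.ndarray:
        return self.surfaces[self.class_names.index(name)]


@dataclass
class CASpec:
    """Cellular-automaton run parameters.

    ``iterations`` is the number of annual allocation steps (1 iteration
    = 1 year). ``epsilon`` is the neighborhood floor in the allocation
    score; without it a class could never colonize a cell none of whose
    neighbors hold it. ``area_tolerance`` is the accepted deviation of
    final class counts from targets, as a fraction of the landscape.
    ``annualize`` chooses how interim targets are formed: ``"linear"``
    interpolation of counts, or ``"matrix-root"`` (annual kernel from
    the fractional matrix power, when one exists).
    """

    iterations: int = 10
    seed: int = 0
    epsilon: float = 0.1
    area_tolerance: float = 0.005
    neighborhood_radius: int = 2
    annualize: str = "linear"

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.annualize not in ("linear", "matrix-root"):
            raise ValueError("annualize must be 'linear' or 'matrix-root'")


def estimate_transition_probs(tm: TransitionMatrix) -> MarkovModel:
    """Row-normalize a transition matrix into transition probabilities.

    ``P_ij = areas[i, j] / row_total[i]``; a class absent at the start
    date gets an identity row (it persists vacuously).
    """
    n = tm.n_classes
    P = np.eye(n)
    rows = tm.row_totals
    for i in range(n):
        if rows[i] > 0:
            P[i] = tm.areas[i] / rows[i]
    return MarkovModel(P=P, class_names=tm.class_names, period_years=tm.period_years)


def project_areas(model: MarkovModel, areas_t: np.ndarray) -> np.ndarray:
    """Project per-class areas one model period forward: ``areas_t · P``.

    Total area is conserved exactly (P is row-stochastic).
    """
    areas_t = np.asarray(areas_t, dtype=float)
    if areas_t.shape != (model.n_classes,):
        raise ValueError(
            f"areas must have length {model.n_classes}, got {areas_t.shape}"
        )
    return areas_t @ model.P


def von_neumann_footprint(radius: int = 2) -> np.ndarray:
    """Boolean 5×5 (for radius 2) footprint of cells within Manhattan
    distance ``radius``, center excluded — 12 neighbors at radius 2."""
    size = 2 * radius + 1
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    fp = (np.abs(yy) + np.abs(xx)) <= radius
    fp[radius, radius] = False
    return fp


def neighbor_fractions(
    values: np.ndarray,
    codes: tuple[int, ...],
    valid: np.ndarray,
    radius: int = 2,
) -> np.ndarray:
    """Per-class fraction of valid neighbors, shape (n_class, rows, cols).

    Neighborhoods are truncated at borders and at nodata: fractions use
    only the neighbors that exist and are valid. Cells with no valid
    neighbor get fraction 0 for every class.
    """
    fp = von_neumann_footprint(radius).astype(float)
    valid_f = valid.astype(float)
    denom = ndimage.correlate(valid_f, fp, mode="constant", cval=0.0)
    out = np.zeros((len(codes),) + values.shape)
    for k, code in enumerate(codes):
        onehot = ((values == code) & valid).astype(float)
        num = ndimage.correlate(onehot, fp, mode="constant", cval=0.0)
        np.divide(num, denom, out=out[k], where=denom > 0)
    return out


def suitability_surfaces(
    grid_t: LandCoverGrid, model: MarkovModel
) -> SuitabilitySurfaces:
    """Markov conditional probabilities broadcast per cell.

    For class ``j``, ``S_j(cell) = P[current_class(cell), j]``; nodata
    cells get 0 everywhere.
    """
    if grid_t.legend.names != tuple(model.class_names):
        raise ValueError("grid legend classes do not match the Markov model")
    idx = _class_index_grid(grid_t)
    valid = ~grid_t.nodata_mask
    n = model.n_classes
    surfaces = np.zeros((n,) + grid_t.shape)
    for j in range(n):
        surfaces[j][valid] = model.P[idx[valid], j]
    return SuitabilitySurfaces(surfaces=surfaces, class_names=tuple(model.class_names))


def _class_index_grid(grid: LandCoverGrid) -> np.ndarray:
    """Map legend codes to 0..n-1 positions; nodata cells get -1."""
    lut = np.full(max(grid.legend.codes) + 1, -1, dtype=np.int64)
    for i, c in enumerate(grid.legend.codes):
        lut[c] = i
    out = np.full(grid.shape, -1, dtype=np.int64)
    valid = ~grid.nodata_mask
    out[valid] = lut[grid.values[valid]]
    return out


def largest_remainder(fractions: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative fractional counts to integers summing to ``total``.

    Floors everything, then hands the remaining units to the largest
    fractional remainders (stable order breaks exact ties).
    """
    fractions = np.asarray(fractions, dtype=float)
    if (fractions < -1e-9).any():
        raise ValueError("negative target counts are infeasible")
    fractions = np.clip(fractions, 0.0, None)
    floors = np.floor(fractions + 1e-9).astype(np.int64)
    short = total - int(floors.sum())
    if short < 0 or short > len(fractions):
        raise ValueError(
            f"fractional counts (sum {fractions.sum():.6f}) inconsistent with total {total}"
        )
    if short:
        rem = fractions - floors
        order = np.argsort(-rem, kind="stable")
        floors[order[:short]] += 1
    return floors


def _annual_kernel(P: np.ndarray, iterations: int) -> np.ndarray | None:
    """Attempt a stochastic ``iterations``-th root of P; None if it fails."""
    from scipy.linalg import fractional_matrix_power

    try:
        root = fractional_matrix_power(P, 1.0 / iterations)
    except Exception:
        return None
    if np.iscomplexobj(root):
        if np.abs(root.imag).max() > 1e-8:
            return None
        root = root.real
    if root.min() < -1e-6:
        return None
    root = np.clip(root, 0.0, None)
    sums = root.sum(axis=1, keepdims=True)
    if (sums <= 0).any():
        return None
    return root / sums


def _interim_targets(
    counts0: np.ndarray, counts_final: np.ndarray, spec: CASpec, P: np.ndarray
) -> list[np.ndarray]:
    """Integer per-class cell targets for each iteration (last = final)."""
    total = int(counts0.sum())
    its = spec.iterations
    targets: list[np.ndarray] = []
    annual = None
    if spec.annualize == "matrix-root" and its > 1:
        annual = _annual_kernel(P, its)
    if annual is not None:
        frac = counts0.astype(float)
        for _ in range(its - 1):
            frac = frac @ annual
            targets.append(largest_remainder(frac, total))
    else:
        for k in range(1, its):
            frac = counts0 + (counts_final - counts0) * (k / its)
            targets.append(largest_remainder(frac, total))
    targets.append(largest_remainder(counts_final.astype(float), total))
    return targets


def ca_simulate(
    grid_t: LandCoverGrid, model: MarkovModel, spec: CASpec
) -> LandCoverGrid:
    """Allocate Markov-projected class areas in space with a CA.

    Guarantees: nodata cells never change; total non-nodata cell count is
    conserved every iteration; a class below its interim target never
    loses cells in that iteration; identical inputs and seed give
    bit-identical output; with an identity kernel the output equals the
    input.
    """
    if grid_t.legend.names != tuple(model.class_names):
        raise ValueError("grid legend classes do not match the Markov model")
    n = model.n_classes
    valid = ~grid_t.nodata_mask
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("grid has no valid cells")

    counts0 = grid_t.class_counts().astype(float)
    counts_final = counts0 @ model.P
    targets = _interim_targets(counts0, counts_final, spec, model.P)

    rng = np.random.default_rng(spec.seed)
    tiebreak = rng.random(grid_t.shape).ravel()

    values = grid_t.values.copy()
    codes = grid_t.legend.codes
    flat_valid = valid.ravel()

    for t_j in targets:
        cur = np.array([int(np.count_nonzero((values == c) & valid)) for c in codes])
        delta = cur - t_j
        if not delta.any():
            continue

        f = neighbor_fractions(values, codes, valid, spec.neighborhood_radius)
        # score_j(cell) = P[current class, j] * (epsilon + f_j)
        idx_grid = np.full(grid_t.shape, -1, dtype=np.int64)
        lut = np.full(max(codes) + 1, -1, dtype=np.int64)
        for i, c in enumerate(codes):
            lut[c] = i
        idx_grid[valid] = lut[values[valid]]

        released: list[np.ndarray] = []
        for j in np.flatnonzero(delta > 0):
            cells = np.flatnonzero(((values == codes[j]).ravel()) & flat_valid)
            stay = (model.P[j, j] * (spec.epsilon + f[j].ravel()[cells]))
            order = np.lexsort((tiebreak[cells], stay))
            released.append(cells[order[: delta[j]]])
        pool = np.concatenate(released) if released else np.array([], dtype=np.int64)

        deficit = np.maximum(t_j - cur, 0)
        claim_classes = np.flatnonzero(deficit > 0)
        if pool.size == 0 or claim_classes.size == 0:
            continue

        # Greedy claim: all (pool cell, claiming class) pairs by descending score.
        src_idx = idx_grid.ravel()[pool]
        scores = np.empty((pool.size, claim_classes.size))
        for col, j in enumerate(claim_classes):
            scores[:, col] = model.P[src_idx, j] * (
                spec.epsilon + f[j].ravel()[pool]
            )
        flat_scores = scores.ravel()
        flat_tb = np.repeat(tiebreak[pool], claim_classes.size)
        order = np.lexsort((flat_tb, -flat_scores))
        remaining = deficit[claim_classes].copy()
        taken = np.zeros(pool.size, dtype=bool)
        new_flat = values.ravel()
        for pair in order:
            cell_i, col = divmod(pair, claim_classes.size)
            if taken[cell_i] or remaining[col] == 0:
                continue
            new_flat[pool[cell_i]] = codes[claim_classes[col]]
            taken[cell_i] = True
            remaining[col] -= 1
            if not remaining.any():
                break
        values = new_flat.reshape(grid_t.shape)

    final = np.array([int(np.count_nonzero((values == c) & valid)) for c in codes])
    misfit = np.abs(final - targets[-1]).sum()
    if misfit > spec.area_tolerance * n_valid:
        raise RuntimeError(
            f"CA allocation missed targets by {misfit} cells "
            f"(> tolerance {spec.area_tolerance * n_valid:.1f})"
        )
    return grid_t.copy_with(values=values)
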