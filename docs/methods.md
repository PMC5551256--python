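# Methods

## Scope and data model

The package operates on co-registered single-band categorical rasters
with a fixed legend (the seven-class Chinese land-survey scheme by
default: cropland, forestland, grassland, wetland, waterbody,
construction land, unused land). Geospatial referencing is reduced to
the cell size in meters: every computation is per-cell, so cell area
(`cell_size_m²`, reported in km²; a 30 m cell is 0.0009 km²) is the only
geometric quantity that matters. Inputs must already be co-registered —
there is no reprojection or resampling. Zones (townships) are a second
integer raster aligned to the land-cover grids.

## Change metrics

The transition matrix holds converted areas in km², rows = start-date
class, columns = end-date class; cells that are nodata in either map
are excluded from both, so marginals are exact class areas over the
jointly valid region.

- SLUDD `K = (U_b − U_a)/U_a · (1/T) · 100` is undefined (flagged, not
  infinite) for a class absent at the start date.
- CLUDD counts every off-diagonal conversion once:
  `R = (Σ_{i≠j} A_ij) / (Σ_ij A_ij) · (1/T) · 100`, with the denominator
  the total analyzed area at period start. This is the interpretation
  under which the published Qinghai Lake decade value (1.61 %/a)
  reproduces exactly from its transition matrix (off-diagonal sum
  9,001.47 km² over 55,836.49 km² over 10 years).
- All computation is at full precision; rounding to the 2 decimals used
  in reporting happens only at output.
- Cohen's kappa is computed in closed form from the cell-by-cell
  confusion matrix (`κ = (p_o − p_e)/(1 − p_e)`); the test suite
  cross-checks it against scikit-learn's implementation.

A note on the shipped worked-example tables (`lucc.qinghai`): the
published matrix's printed marginal totals disagree with its recomputed
cell sums by up to 0.02 km², because each printed cell was rounded
independently from an unpublished full-precision table. Both are kept:
derived statistics quoted against published totals use the printed
marginals; matrix-level statistics (CLUDD, estimation) use the cells.

## Markov estimation and projection

`P_ij = A_ij / Σ_j A_ij` per row; a class absent at the start date gets
an identity row. `P` describes one period of `T` years. Projection is
the vector–matrix product `a_{t+T} = a_t P`, which conserves total area
exactly and, applied to the calibration start areas, reproduces the
calibration end areas by construction (this identity is a test).

## Cellular automaton

The CA turns projected areas into a map. Design choices, in order of
consequence:

- **Suitability is history-only.** `S_j(x) = P[class_t(x), j]` — the
  Markov conditional probability broadcast per cell. No covariates
  (slope, roads, climate) enter; this keeps the simulator a pure
  function of the calibration pair and is a known limitation (see
  below).
- **Neighborhood.** Von Neumann radius 2 (5×5, Manhattan ≤ 2, center
  excluded; 12 neighbors), truncated at borders and nodata: neighbor
  fractions `f_j` use only existing valid neighbors. The synthetic
  generator uses the same neighborhood, so one convention holds
  repo-wide.
- **Annual iteration with interpolated targets.** One iteration per
  year. Interim per-class cell targets are linearly interpolated
  between initial counts and the final Markov targets; a stochastic
  annual kernel need not exist (matrix roots of stochastic matrices can
  be complex or negative), so linear interpolation is the default and a
  `matrix-root` option attempts the fractional matrix power, falling
  back to linear when the root is not (approximately) stochastic.
- **Integer targets.** Fractional areas become integer cell counts by
  the largest-remainder method, preserving the total exactly.
- **Budgeted reallocation.** Per iteration, classes above target
  release their lowest-scoring cells; classes below target claim
  released cells greedily by descending score
  `S_j(x) · (epsilon + f_j(x))`. Only the released budget moves — all
  other cells keep their class, so a class below target never loses
  cells in an iteration (a tested invariant). `epsilon` (default 0.1)
  keeps scores positive where `f_j = 0`, letting new patches nucleate
  away from existing ones; larger values weaken spatial clustering.
- **Determinism.** Ties are broken by one seeded random priority per
  run; outputs are bit-identical for identical inputs and seed.
- **Exactness.** Because releases and claims reconcile exactly each
  iteration, final counts equal final targets; `area_tolerance`
  (default 0.005 of the landscape) is a guard that would turn any
  future accounting defect into a hard error rather than silent drift.

Identity kernels are a fixpoint (no targets differ, nothing moves), and
nodata cells never change.

## Valuation

`E_a = (1/7)·Σ_i m_i p_i q_i / M` in Yuan/hm²/a; the 1/7 factor is the
equivalent-factor method's fixed convention relating one "equivalent"
to the grain market value of a hectare of average cropland. Unit prices
`E_ij = e_ij · E_a` and `ESV = Σ_j A_j Σ_i E_ij` with areas converted
km² → hm² (×100). Values are nominal Yuan; no deflation or discounting.

The factor table has exactly nine service rows (food production, raw
material production, gas regulation, climate regulation, hydrology
regulation, waste treatment, soil conservation, biodiversity
maintenance, aesthetic landscape provision) and one column per
ecosystem type. The mapping from land-cover classes to ecosystem
columns is explicit user configuration, never guessed — a class may map
to `none`, which prices it at zero. Construction land is excluded
(zero) in the default mapping, following the method's usual treatment
of built land as having lost its ecosystem functions; mapping it to a
column is one config line if a user disagrees. The shipped factor
*values* are synthetic stand-ins with the conventional structure
(cropland food production = 1, wetland/waterbody dominating hydrology
regulation and waste treatment); real studies should substitute a
published calibration via `factors.csv`.

## Sensitivity index

`SI = |(ESV_t2 − ESV_t1)/R| · 1/(t2 − t1) · 100` with `R` the CLUDD as
a percentage number (1.61, not 0.0161). The ESV unit is configurable
and defaults to 10⁹ Yuan; SI scales inversely with that unit, so SI
values are only comparable under one stated convention. Zonal SI
restricts both the transition matrix (hence `R`) and the ESVs to each
zone's cells. `R = 0` (no change) makes SI undefined: it is flagged and
the zone is excluded from increase/decrease summaries, with ties kept
as a third category.

## Synthetic data

The generator emulates the *statistical* structure of classified
satellite land-cover series, not their appearance:

- **Landscapes**: the grid is split into ~`n_cells/patchiness`
  contiguous patches by nearest-seed (Voronoi) region growing; classes
  are assigned to patches by largest-remainder quota over the class
  weights, shuffled with the seed. Realized class shares concentrate
  within about ±1 percentage point of the weights at 256×256 and the
  like-class adjacency sits far above the shuffled (i.i.d.) null.
- **Evolution**: each cell's next class is drawn from its kernel row,
  optionally re-weighted by `(1 + clustering_strength · f_j)` toward
  classes present in the 12-cell neighborhood. With
  `clustering_strength = 0` the draws are exactly the kernel rows, so
  crosstab + row-normalization recovers the kernel (L1 row error ≤ 0.02
  at 512×512 for classes holding ≥ 2% of cells — a tested property).
- **Zones**: seeded Voronoi partitions; contiguous, non-empty,
  exhaustive. The default zone count (38) matches the number of
  townships in the worked-example region.
- **Tables**: a three-crop highland economics table (areas 10³–10⁴ hm²,
  prices 1,500–2,500 Yuan/t, yields 2–4 t/hm²/a) and the synthetic
  factor table above.

What passing synthetic tests does **not** show: robustness to
classification error (the generator draws clean classes), to
misregistration, or to real landscapes' anisotropic, terrain-driven
patch geometry. Conclusions about method correctness transfer;
conclusions about accuracy on Landsat-derived maps do not.

## Problem sizes in tests

The suite runs the CA at 256×256 × 10 iterations and kernel recovery at
512×512 — the smallest sizes at which the stated statistical bounds
(±1% binomial sampling, L1 ≤ 0.02) have comfortable margins — and the
end-to-end pipeline at 72×72–96×96 with 5–8 zones, where every
conservation identity is scale-free.

## Known limitations

- Suitability has no drivers; simulations extrapolate the calibration
  period's trend and stay close to the initial map (the worked example
  prints kappa ≈ 0.996 against the initial state for a slow decade).
- The CA's budgeted-reallocation rule is one defensible choice among
  several (e.g. full-relabeling CAs); only its invariants, not
  bit-compatibility with any GIS product, are guaranteed.
- Equivalent-factor valuation is benefit transfer: totals scale with
  `E_a` and the factor calibration, and no biophysical process model
  stands behind them.
- SLUDD for a class appearing from zero area is undefined by
  construction; studies reporting such classes need a different rate
  statistic.
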