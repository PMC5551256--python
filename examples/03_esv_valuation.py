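"""Equivalent-factor valuation of a synthetic landscape.

Derives the cropland food-production reference price E_a from a crop
economics table, scales the (synthetic) equivalent-factor table into
unit prices, and values a landscape by class and by service. The
by-class and by-service breakdowns are two decompositions of the same
total and must agree.
"""

import lucc

crops = lucc.synthetic_crop_economics()
e_a = lucc.food_production_unit_value(crops)
print(f"E_a (cropland food production): {e_a:.2f} Yuan/hm2/a")

prices = lucc.unit_price_table(
    e_a, lucc.synthetic_factor_table(), lucc.DEFAULT_CLASS_ECOSYSTEM_MAP
)

grid = lucc.generate_landscape(
    lucc.SyntheticSpec(shape=(256, 256), patchiness=40, seed=21), date_label="2010"
)
res = lucc.esv_totals(grid, prices)
print(f"\ntotal ESV: {res.total / 1e6:.2f} x 10^6 Yuan/a "
      f"over {grid.values.size * grid.cell_area_km2:.1f} km2")

print("\nby class (10^6 Yuan/a):")
for cls, v in res.by_class.sort_values(ascending=False).items():
    print(f"  {cls:<20}{v / 1e6:>10.2f}")

print("\nby service (10^6 Yuan/a):")
for svc, v in res.by_service.sort_values(ascending=False).items():
    print(f"  {svc:<30}{v / 1e6:>10.2f}")

assert abs(res.by_class.sum() - res.by_service.sum()) < 1e-6 * res.total
print("\nby-class and by-service totals agree (same money, two partitions)")
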