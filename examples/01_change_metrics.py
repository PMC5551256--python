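"""Dynamic degrees from a published decade of land-cover change.

Loads the published 1990–2000 Qinghai Lake transition matrix (km²) and
computes the comprehensive land-use dynamic degree (CLUDD) plus the
per-class single dynamic degrees (SLUDD) from the printed marginal
areas. A SLUDD of 3.32 %/a for cropland means cropland grew by 3.32%
of its 1990 area per year; the CLUDD of 1.61 %/a means 1.61% of the
whole region changed class per year.
"""

import lucc
from lucc import qinghai

tm = qinghai.transition_matrix_1990_2000()
print(f"total area analyzed: {tm.total_area:,.2f} km2")
print(f"area that changed class: {tm.changed_area:,.2f} km2")
print(f"CLUDD 1990-2000: {lucc.cludd(tm):.2f} % per year")
print()

a90, a00 = qinghai.AREAS_1990_KM2, qinghai.AREAS_2000_KM2
print(f"{'class':<20}{'1990 km2':>12}{'2000 km2':>12}{'SLUDD %/a':>12}")
for cls in tm.class_names:
    k = lucc.sludd(a90[cls], a00[cls], 10)
    print(f"{cls:<20}{a90[cls]:>12,.2f}{a00[cls]:>12,.2f}{k:>12.2f}")
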