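"""Published Qinghai Lake region tables used as worked-example inputs.

The Qinghai Lake region (northeastern Tibetan Plateau, ~55,700 km², 38
townships) is the canonical worked example for this toolkit: its
published 1990–2000 land-use transition matrix, decadal area changes,
ecosystem-service values, and township sensitivity-change areas are
small enough to enter verbatim and rich enough to exercise every change
metric. These are *inputs* (digitized published tables); everything
derived from them — dynamic degrees, projections, shares — is computed
by the package at run time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from lucc.change_metrics import TransitionMatrix

#: Class order of the published tables.
CLASS_NAMES = (
    "cropland",
    "forestland",
    "grassland",
    "wetland",
    "waterbody",
    "construction land",
    "unused land",
)

#: Land-use transition matrix 1990 → 2000, km². Rows: 1990 class;
#: columns: 2000 class. Grand total 55,836.49 km².
_TRANSITIONS_1990_2000 = np.array(
    [
        # cropland forestland grassland  wetland  waterbody constr.  unused
        [514.51,     0.14,    130.72,     9.82,     1.06,   11.97,    17.30],
        [  0.15,   492.14,    266.35,    19.88,     0.00,    0.02,     3.70],
        [384.13,   507.59,  34705.90,  1173.80,    13.23,   20.34,  2319.89],
        [  0.22,     9.24,   1009.59,  1959.90,     1.74,    1.17,    71.13],
        [  0.01,     0.14,     47.23,    25.94,  4287.87,    0.05,    22.64],
        [  2.63,     0.00,      1.14,     0.08,     0.00,    3.60,     0.00],
        [ 11.35,    15.43,   2585.72,   303.90,    11.35,    0.68,  4871.10],
    ]
)


def transition_matrix_1990_2000() -> TransitionMatrix:
    """The published 1990–2000 transition matrix as a TransitionMatrix
    (T = 10 years)."""
    return TransitionMatrix(
        areas=_TRANSITIONS_1990_2000.copy(),
        class_names=CLASS_NAMES,
        period_years=10.0,
        t1_label="1990",
        t2_label="2000",
    )


#: Published marginal class areas (km²). The printed marginals differ
#: from the recomputed cell sums by up to 0.02 km² (the source rounded
#: each cell of an unpublished full-precision table independently), so
#: statistics quoted against the published totals must use these, not
#: sums of the matrix entries.
AREAS_1990_KM2: dict[str, float] = {
    "cropland": 685.52,
    "forestland": 782.24,
    "grassland": 39124.88,
    "wetland": 3052.98,
    "waterbody": 4383.89,
    "construction land": 7.45,
    "unused land": 7799.54,
}

AREAS_2000_KM2: dict[str, float] = {
    "cropland": 913.00,
    "forestland": 1024.68,
    "grassland": 38746.64,
    "wetland": 3493.31,
    "waterbody": 4315.26,
    "construction land": 37.85,
    "unused land": 7305.76,
}

#: Published net area changes (km²) over 2000–2010 for the classes whose
#: decadal gains are printed; start areas are the 2000 marginals of the
#: 1990–2000 matrix.
NET_CHANGE_2000_2010_KM2: dict[str, float] = {
    "cropland": -171.94,
    "forestland": 151.35,
    "grassland": 664.66,
    "wetland": -454.01,
    "construction land": 47.81,
    "unused land": -267.31,
}


def esv_by_class_table() -> pd.DataFrame:
    """Published ecosystem-service values by class and year, 10⁹ Yuan.

    Rows are years (1990, 2000, 2010 observed; 2020 simulated); columns
    are the six valued classes. Construction land carries the published
    nonzero column even though the valuation method text excludes it —
    the table is entered as printed.
    """
    data = {
        "cropland": [4.37, 5.82, 4.72, 3.93],
        "forestland": [17.75, 23.25, 26.68, 28.09],
        "grassland": [368.35, 364.79, 371.05, 375.41],
        "wetland": [134.90, 154.35, 134.29, 122.50],
        "waterbody": [160.39, 157.88, 158.96, 159.07],
        "construction land": [8.75, 8.19, 7.89, 7.72],
    }
    return pd.DataFrame(data, index=[1990, 2000, 2010, 2020])


#: Published township-group areas (10⁴ km²) for the sensitivity-index
#: change comparison between the 1990–2000 and 2000–2010 periods.
SI_CHANGE_GROUP_AREAS_1E4_KM2 = {"decrease": 39.07, "increase": 16.68}
#: Same for the 2000–2010 vs 2010–2020 comparison.
SI_CHANGE_GROUP_AREAS_SECOND_1E4_KM2 = {"decrease": 22.20, "increase": 33.56}
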