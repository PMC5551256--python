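import numpy as np
import pytest

import lucc
from lucc.grids import ClassLegend, LandCoverGrid


@pytest.fixture(scope="session")
def legend():
    return lucc.DEFAULT_LEGEND


@pytest.fixture(scope="session")
def prices():
    """Unit-price table from the synthetic crop/factor fixtures with the
    default class→ecosystem mapping (construction land excluded)."""
    e_a = lucc.food_production_unit_value(lucc.synthetic_crop_economics())
    return lucc.unit_price_table(
        e_a, lucc.synthetic_factor_table(), lucc.DEFAULT_CLASS_ECOSYSTEM_MAP
    )


@pytest.fixture(scope="session")
def landscape_pair(legend):
    """A 128×128 patchy landscape and its one-step evolution under a
    known diagonal-dominant kernel (no clustering bias)."""
    spec = lucc.SyntheticSpec(shape=(128, 128), patchiness=30, seed=11)
    g0 = lucc.generate_landscape(spec, date_label="2000")
    kernel = lucc.default_evolution_kernel(legend.n_classes)
    g1 = lucc.evolve_landscape(g0, kernel, 0.0, seed=12, date_label="2010")
    return g0, g1, kernel


@pytest.fixture(scope="session")
def zones():
    return lucc.generate_zones((128, 128), 8, seed=13)


def make_grid(values, legend=lucc.DEFAULT_LEGEND, cell_size_m=30.0, label=""):
    return LandCoverGrid(
        values=np.asarray(values, dtype=np.int64),
        cell_size_m=cell_size_m,
        legend=legend,
        date_label=label,
    )


@pytest.fixture(scope="session")
def two_class_legend():
    return ClassLegend(entries=((1, "a"), (2, "b")), nodata_code=0)
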