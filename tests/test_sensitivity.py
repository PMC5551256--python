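"""Sensitivity index: closed forms, zonal decomposition, change summary."""

import numpy as np
import pytest

import lucc
from lucc.change_metrics import cludd, crosstab
from lucc.grids import ZoneMap

from conftest import make_grid


class TestSensitivityIndex:
    def test_no_esv_change_is_zero(self):
        assert lucc.sensitivity_index(100.0, 100.0, 1.5, 0, 10) == 0.0

    def test_hand_value(self):
        # |110-100| / 2 * (1/10) * 100 = 50
        assert lucc.sensitivity_index(100.0, 110.0, 2.0, 0, 10) == pytest.approx(50.0)

    def test_doubling_r_halves_si(self):
        si1 = lucc.sensitivity_index(3.0, 7.0, 1.0, 2000, 2010)
        si2 = lucc.sensitivity_index(3.0, 7.0, 2.0, 2000, 2010)
        assert si2 == pytest.approx(si1 / 2)

    def test_r_zero_flags_undefined(self):
        assert np.isnan(lucc.sensitivity_index(1.0, 2.0, 0.0, 0, 10))

    def test_shift_invariance_only_at_zero(self):
        """Adding a nonzero constant to both ESVs leaves SI unchanged
        (the formula uses only the difference) — asserted as the exact
        formula, not a false invariance of the magnitude."""
        base = lucc.sensitivity_index(5.0, 9.0, 1.0, 0, 10)
        shifted = lucc.sensitivity_index(5.0 + 3.0, 9.0 + 3.0, 1.0, 0, 10)
        assert shifted == pytest.approx(base)
        assert base == pytest.approx(abs(9.0 - 5.0) / 1.0 / 10 * 100)

    def test_bad_period_rejected(self):
        with pytest.raises(ValueError):
            lucc.sensitivity_index(1.0, 2.0, 1.0, 2010, 2000)


class TestSiByZone:
    def test_unchanged_zone_flagged_undefined(self, prices, two_class_legend):
        g1 = make_grid(np.ones((8, 8), dtype=np.int64))
        si = lucc.si_by_zone(
            g1, g1, lucc.generate_zones((8, 8), 2, seed=1), prices, 2000, 2010
        )
        assert len(si.undefined_zones) == 2
        assert si.si.isna().all()

    def test_single_zone_equals_regional(self, landscape_pair, prices):
        g0, g1, _ = landscape_pair
        zones = lucc.generate_zones(g0.shape, 1, seed=2)
        si = lucc.si_by_zone(g0, g1, zones, prices, 2000, 2010)
        tm = crosstab(g0, g1, 10)
        r = cludd(tm)
        e1 = lucc.esv_totals(g0, prices).total / 1e9
        e2 = lucc.esv_totals(g1, prices).total / 1e9
        assert si.si.iloc[0] == pytest.approx(
            lucc.sensitivity_index(e1, e2, r, 2000, 2010)
        )

    def test_only_changed_zone_has_positive_si(self, prices):
        """Four quadrant zones; land changes only in quadrant 0."""
        values = np.full((16, 16), 3, dtype=np.int64)
        g1 = make_grid(values)
        v2 = values.copy()
        v2[:4, :4] = 4  # wetland appears only in the top-left quadrant
        g2 = make_grid(v2)
        zvals = np.zeros((16, 16), dtype=np.int64)
        zvals[:8, 8:] = 1
        zvals[8:, :8] = 2
        zvals[8:, 8:] = 3
        si = lucc.si_by_zone(g1, g2, ZoneMap(values=zvals), prices, 2000, 2010)
        assert si.si[0] > 0
        assert si.si[[1, 2, 3]].isna().all()
        assert set(si.undefined_zones) == {1, 2, 3}

    def test_zonal_cludd_area_weighted_recovers_regional(self, landscape_pair, prices):
        g0, g1, _ = landscape_pair
        zones = lucc.generate_zones(g0.shape, 6, seed=5)
        si = lucc.si_by_zone(g0, g1, zones, prices, 2000, 2010)
        regional = cludd(crosstab(g0, g1, 10))
        weights = si.zone_areas_km2 / si.zone_areas_km2.sum()
        assert (si.r * weights).sum() == pytest.approx(regional, rel=1e-9)

    def test_zonal_esv_sums_to_regional(self, landscape_pair, prices):
        g0, g1, _ = landscape_pair
        zones = lucc.generate_zones(g0.shape, 6, seed=5)
        si = lucc.si_by_zone(g0, g1, zones, prices, 2000, 2010)
        assert si.esv_t1.sum() * 1e9 == pytest.approx(
            lucc.esv_totals(g0, prices).total, rel=1e-9
        )

    def test_service_subset_restricts_valuation(self, landscape_pair, prices):
        g0, g1, _ = landscape_pair
        zones = lucc.generate_zones(g0.shape, 4, seed=8)
        all_s = lucc.si_by_zone(g0, g1, zones, prices, 2000, 2010)
        one_s = lucc.si_by_zone(
            g0, g1, zones, prices, 2000, 2010, services=("hydrology regulation",)
        )
        assert (one_s.esv_t1 <= all_s.esv_t1 + 1e-12).all()
        assert not one_s.esv_t1.equals(all_s.esv_t1)


class TestClassifySiChange:
    def _series(self, d):
        import pandas as pd

        return pd.Series(d, dtype=float)

    def test_all_decrease_full_share(self):
        a = self._series({0: 2.0, 1: 3.0})
        b = self._series({0: 1.0, 1: 2.0})
        areas = self._series({0: 10.0, 1: 30.0})
        s = lucc.classify_si_change(a, b, areas)
        assert s.counts["decrease"] == 2
        assert s.area_shares_pct["decrease"] == pytest.approx(100.0)

    def test_published_group_areas_give_decrease_share(self):
        """Two groups with the published township areas (10⁴ km²):
        39.07 decrease vs 16.68 increase → 70.08% / 29.92%."""
        from lucc.qinghai import SI_CHANGE_GROUP_AREAS_1E4_KM2 as groups

        a = self._series({0: 2.0, 1: 1.0})
        b = self._series({0: 1.0, 1: 2.0})  # zone 0 decreases, zone 1 increases
        areas = self._series({0: groups["decrease"], 1: groups["increase"]})
        s = lucc.classify_si_change(a, b, areas)
        assert round(s.area_shares_pct["decrease"], 2) == 70.08
        assert round(s.area_shares_pct["increase"], 2) == 29.92

    def test_equal_areas_split_evenly_and_sum_100(self):
        a = self._series({0: 1.0, 1: 2.0})
        b = self._series({0: 2.0, 1: 1.0})
        areas = self._series({0: 5.0, 1: 5.0})
        s = lucc.classify_si_change(a, b, areas)
        assert s.area_shares_pct["increase"] == pytest.approx(50.0)
        assert sum(s.area_shares_pct.values()) == pytest.approx(100.0, abs=0.01)

    def test_undefined_si_excluded_with_warning(self):
        a = self._series({0: 1.0, 1: float("nan")})
        b = self._series({0: 2.0, 1: 1.0})
        areas = self._series({0: 5.0, 1: 5.0})
        with pytest.warns(UserWarning, match="undefined"):
            s = lucc.classify_si_change(a, b, areas)
        assert s.excluded_zones == (1,)
        assert sum(s.counts.values()) == 1

    def test_ties_form_third_category(self):
        a = self._series({0: 1.0, 1: 1.0})
        b = self._series({0: 1.0, 1: 2.0})
        areas = self._series({0: 4.0, 1: 6.0})
        s = lucc.classify_si_change(a, b, areas)
        assert s.counts["tie"] == 1
        assert s.counts["increase"] == 1
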