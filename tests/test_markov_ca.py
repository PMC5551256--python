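"""Markov estimation/projection and the CA allocator."""

import numpy as np
import pytest

import lucc
from lucc.change_metrics import TransitionMatrix
from lucc.markov_ca import (
    CASpec,
    MarkovModel,
    largest_remainder,
    neighbor_fractions,
    von_neumann_footprint,
)
from lucc import qinghai

from conftest import make_grid


class TestEstimation:
    def test_diagonal_matrix_gives_identity(self):
        tm = TransitionMatrix(
            areas=np.diag([5.0, 7.0, 3.0]), class_names=("a", "b", "c"), period_years=10
        )
        np.testing.assert_allclose(lucc.estimate_transition_probs(tm).P, np.eye(3))

    def test_published_cropland_row(self):
        model = lucc.estimate_transition_probs(qinghai.transition_matrix_1990_2000())
        assert round(model.P[0, 0], 4) == 0.7505  # 514.51 / 685.52

    def test_rows_sum_to_one(self, landscape_pair):
        g0, g1, _ = landscape_pair
        model = lucc.estimate_transition_probs(lucc.crosstab(g0, g1, 10))
        np.testing.assert_allclose(model.P.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_row_becomes_identity(self):
        areas = np.array([[4.0, 1.0], [0.0, 0.0]])
        model = lucc.estimate_transition_probs(
            TransitionMatrix(areas=areas, class_names=("a", "b"), period_years=1)
        )
        np.testing.assert_allclose(model.P[1], [0.0, 1.0])


class TestProjection:
    def test_identity_kernel_fixes_areas(self):
        model = MarkovModel(P=np.eye(3), class_names=("a", "b", "c"), period_years=10)
        areas = np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(lucc.project_areas(model, areas), areas)

    def test_calibration_pair_reproduces_end_areas(self):
        """areas_t1 · P equals the calibration column totals by construction."""
        tm = qinghai.transition_matrix_1990_2000()
        model = lucc.estimate_transition_probs(tm)
        proj = lucc.project_areas(model, tm.row_totals)
        np.testing.assert_allclose(proj, tm.col_totals, rtol=1e-12)
        assert proj[0] == pytest.approx(913.00)

    def test_total_area_conserved(self, landscape_pair):
        g0, g1, _ = landscape_pair
        model = lucc.estimate_transition_probs(lucc.crosstab(g0, g1, 10))
        areas = g0.class_areas_km2()
        assert lucc.project_areas(model, areas).sum() == pytest.approx(
            areas.sum(), abs=1e-6
        )


class TestSuitability:
    def test_identity_kernel_indicator_surfaces(self, two_class_legend):
        grid = make_grid([[1, 2], [2, 1]], legend=two_class_legend)
        model = MarkovModel(P=np.eye(2), class_names=("a", "b"), period_years=1)
        s = lucc.suitability_surfaces(grid, model)
        np.testing.assert_allclose(s.for_class("a"), (grid.values == 1).astype(float))

    def test_uniform_rows_constant_surfaces(self, two_class_legend):
        grid = make_grid([[1, 2], [2, 1]], legend=two_class_legend)
        model = MarkovModel(
            P=np.full((2, 2), 0.5), class_names=("a", "b"), period_years=1
        )
        s = lucc.suitability_surfaces(grid, model)
        np.testing.assert_allclose(s.surfaces, 0.5)

    def test_broadcast_of_conditional_probability(self, two_class_legend):
        grid = make_grid(np.full((3, 3), 1), legend=two_class_legend)
        model = MarkovModel(
            P=np.array([[0.7, 0.3], [0.0, 1.0]]), class_names=("a", "b"), period_years=1
        )
        np.testing.assert_allclose(
            lucc.suitability_surfaces(grid, model).for_class("b"), 0.3
        )


class TestFootprint:
    def test_radius2_has_12_neighbors(self):
        fp = von_neumann_footprint(2)
        assert fp.sum() == 12
        assert not fp[2, 2]

    def test_neighbor_fractions_sum_to_one_inside(self, two_class_legend):
        grid = make_grid(np.full((7, 7), 1), legend=two_class_legend)
        f = neighbor_fractions(grid.values, two_class_legend.codes, ~grid.nodata_mask)
        np.testing.assert_allclose(f.sum(axis=0), 1.0)


class TestLargestRemainder:
    def test_preserves_total_exactly(self):
        fr = np.array([3.4, 2.3, 4.3])
        out = largest_remainder(fr, 10)
        assert out.sum() == 10
        # floors (3,2,4) leave one unit; the largest remainder (0.4) gets it
        assert out.tolist() == [4, 2, 4]

    def test_integer_input_unchanged(self):
        np.testing.assert_array_equal(
            largest_remainder(np.array([2.0, 5.0, 3.0]), 10), [2, 5, 3]
        )

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            largest_remainder(np.array([-1.0, 11.0]), 10)


class TestCASimulate:
    def test_identity_kernel_is_fixpoint(self, landscape_pair):
        g0, _, _ = landscape_pair
        model = MarkovModel(
            P=np.eye(7), class_names=g0.legend.names, period_years=10
        )
        sim = lucc.ca_simulate(g0, model, CASpec(iterations=10, seed=1))
        np.testing.assert_array_equal(sim.values, g0.values)

    def test_deterministic_under_seed(self, landscape_pair):
        g0, g1, _ = landscape_pair
        model = lucc.estimate_transition_probs(lucc.crosstab(g0, g1, 10))
        spec = CASpec(iterations=10, seed=42)
        a = lucc.ca_simulate(g1, model, spec)
        b = lucc.ca_simulate(g1, model, spec)
        np.testing.assert_array_equal(a.values, b.values)

    def test_areas_hit_markov_targets(self, landscape_pair):
        g0, g1, _ = landscape_pair
        model = lucc.estimate_transition_probs(lucc.crosstab(g0, g1, 10))
        spec = CASpec(iterations=10, seed=7, area_tolerance=0.005)
        sim = lucc.ca_simulate(g1, model, spec)
        targets = largest_remainder(
            g1.class_counts().astype(float) @ model.P, g1.values.size
        )
        assert np.abs(sim.class_counts() - targets).sum() <= 0.005 * g1.values.size

    def test_nodata_never_changes_and_count_conserved(self, two_class_legend):
        values = np.ones((20, 20), dtype=np.int64)
        values[:2, :] = 0  # nodata band
        grid = make_grid(values, legend=two_class_legend)
        model = MarkovModel(
            P=np.array([[0.5, 0.5], [0.0, 1.0]]),
            class_names=("a", "b"),
            period_years=5,
        )
        sim = lucc.ca_simulate(grid, model, CASpec(iterations=5, seed=3))
        assert (sim.values[:2, :] == 0).all()
        assert (sim.values != 0).sum() == (values != 0).sum()

    def test_growth_is_clustered_not_scattered(self, two_class_legend):
        """Moving 25% of a single-class map to a new class should produce
        patchier growth than a seeded random placement of the same count
        (shuffle-null on like-class adjacency)."""
        grid = make_grid(np.ones((20, 20), dtype=np.int64), legend=two_class_legend)
        model = MarkovModel(
            P=np.array([[0.75, 0.25], [0.0, 1.0]]),
            class_names=("a", "b"),
            period_years=10,
        )
        sim = lucc.ca_simulate(grid, model, CASpec(iterations=10, seed=9))
        n_new = int((sim.values == 2).sum())
        assert n_new == pytest.approx(100, abs=0.005 * 400 + 1)

        def adjacency(values, code):
            same = 0
            pairs = 0
            for axis in (0, 1):
                a = np.take(values, range(values.shape[axis] - 1), axis=axis)
                b = np.take(values, range(1, values.shape[axis]), axis=axis)
                mask = (a == code) | (b == code)
                pairs += mask.sum()
                same += ((a == code) & (b == code)).sum()
            return same / pairs

        rng = np.random.default_rng(10)
        null = []
        for _ in range(20):
            flat = grid.values.ravel().copy()
            idx = rng.choice(flat.size, n_new, replace=False)
            flat[idx] = 2
            null.append(adjacency(flat.reshape(20, 20), 2))
        assert adjacency(sim.values, 2) > np.mean(null)

    def test_under_target_class_never_loses_cells(self, landscape_pair):
        """Monotone allocation: across one 1-iteration run, a class whose
        target exceeds its count only gains."""
        g0, g1, _ = landscape_pair
        model = lucc.estimate_transition_probs(lucc.crosstab(g0, g1, 10))
        before = g1.class_counts()
        targets = largest_remainder(before.astype(float) @ model.P, g1.values.size)
        sim = lucc.ca_simulate(g1, model, CASpec(iterations=1, seed=2))
        after = sim.class_counts()
        growing = targets > before
        assert (after[growing] >= before[growing]).all()

    def test_matrix_root_annualization_also_hits_targets(self, landscape_pair):
        g0, g1, _ = landscape_pair
        model = lucc.estimate_transition_probs(lucc.crosstab(g0, g1, 10))
        spec = CASpec(iterations=10, seed=7, annualize="matrix-root")
        sim = lucc.ca_simulate(g1, model, spec)
        targets = largest_remainder(
            g1.class_counts().astype(float) @ model.P, g1.values.size
        )
        assert np.abs(sim.class_counts() - targets).sum() <= 0.005 * g1.values.size

    def test_simulation_beats_random_baseline_kappa(self, legend):
        """Simulating t1 from t0 under the estimated kernel agrees with the
        true t1 better than a random relabeling with the same class mix."""
        spec = lucc.SyntheticSpec(shape=(96, 96), patchiness=30, seed=31)
        t0 = lucc.generate_landscape(spec)
        kernel = lucc.default_evolution_kernel(legend.n_classes)
        t1 = lucc.evolve_landscape(t0, kernel, 0.2, seed=32)
        model = lucc.estimate_transition_probs(lucc.crosstab(t0, t1, 10))
        sim = lucc.ca_simulate(t0, model, CASpec(iterations=10, seed=33))
        kappa_sim = lucc.cohen_kappa(sim, t1).kappa

        rng = np.random.default_rng(34)
        shuffled = sim.values.ravel().copy()
        rng.shuffle(shuffled)
        baseline = make_grid(shuffled.reshape(sim.shape))
        kappa_null = lucc.cohen_kappa(baseline, t1).kappa
        assert kappa_sim > kappa_null
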