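import math

import numpy as np
import pytest

from campath.fes_io import Axis, EnergyGrid, Temperature, mask_high_energy
from campath.mfep_core import (
    NoPathError,
    barrier_height,
    build_successor_map,
    edge_resistance,
    find_fixed_points,
    mfep,
    path_profile,
    profile_statistics,
    shortest_resistance_path,
)
from campath.synthetic import ToyLandscapeSpec, random_smooth_landscape, toy_landscape

from conftest import random_grid_2d


def grid_1d(values):
    values = np.asarray(values, dtype=float)
    return EnergyGrid((Axis("x", 0.0, len(values) - 1.0, len(values)),), values)


class TestSuccessorMap:
    def test_interior_minimum_attracts_neighbors(self, grid_1d_simple):
        sm = build_successor_map(grid_1d_simple)
        assert sm.successor.tolist() == [1, 1, 1]

    def test_monotone_ramp_points_downhill(self):
        sm = build_successor_map(grid_1d(np.arange(6.0)))
        assert sm.successor.tolist() == [0, 0, 1, 2, 3, 4]
        assert sm.is_fixed_point().tolist() == [True] + [False] * 5

    def test_successor_energy_never_higher(self):
        g = random_grid_2d(seed=11, n=20)
        sm = build_successor_map(g)
        e = g.values.ravel()
        assert np.all(e[sm.successor] <= e)

    def test_all_masked_raises(self):
        g = EnergyGrid(
            (Axis("x", 0, 1, 2),), np.zeros(2), mask=np.ones(2, dtype=bool)
        )
        with pytest.raises(ValueError, match="masked"):
            build_successor_map(g)


class TestBasins:
    def test_single_well_single_fixed_point(self):
        spec = ToyLandscapeSpec("bowl_2d", spacing=0.1)
        g = toy_landscape(spec)
        bd = find_fixed_points(build_successor_map(g))
        assert len(bd.fixed_points) == 1
        assert bd.fixed_points[0] == int(np.argmin(g.values))

    def test_shallow_middle_well_is_its_own_basin(self):
        # hand trace: nodes 0, 2 and 4 all see no lower neighbor, so the
        # successor definition yields three fixed points, with the shallow
        # E=0.5 middle well forming its own (single-node) basin
        bd = find_fixed_points(build_successor_map(grid_1d([0, 1, 0.5, 1, 0])))
        assert bd.fixed_points == (0, 2, 4)
        assert bd.basin_label.tolist() == [0, 0, 2, 4, 4]
        assert bd.cg_adjacency == frozenset({(0, 2), (2, 4)})

    def test_two_well_basin_boundary(self):
        bd = find_fixed_points(build_successor_map(grid_1d([0, 0.5, 1, 0.5, 0])))
        assert bd.fixed_points == (0, 4)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_basins_partition_unmasked_nodes(self, seed):
        g = mask_high_energy(random_grid_2d(seed, n=15), 4.5)
        bd = find_fixed_points(build_successor_map(g))
        labels = bd.basin_label
        unmasked = ~g.mask.ravel()
        assert np.all(labels[unmasked] >= 0)
        assert np.all(labels[~unmasked] == -1)
        assert set(labels[unmasked]) == set(bd.fixed_points)
        # successor chains terminate at the labelled fixed point
        sm = build_successor_map(g)
        for node in np.flatnonzero(unmasked):
            cur = node
            for _ in range(labels.size):
                if sm.successor[cur] == cur:
                    break
                cur = sm.successor[cur]
            assert cur == labels[node]


class TestEdgeResistance:
    def test_zero_energy_unit_spacing(self, grid_1d_flat, t310):
        assert edge_resistance(grid_1d_flat, 0, 1, t310) == pytest.approx(1.0)

    def test_rt_ln2_doubles_cost(self, t310):
        e = t310.rt * math.log(2.0)
        g = grid_1d([e, e, e])
        assert edge_resistance(g, 0, 1, t310) == pytest.approx(2.0)

    def test_diagonal_length_sqrt2(self, t310):
        g = EnergyGrid(
            (Axis("x", 0, 1, 2), Axis("y", 0, 1, 2)), np.zeros((2, 2))
        )
        assert edge_resistance(g, 0, 3, t310) == pytest.approx(math.sqrt(2))

    def test_masked_endpoint_rejected(self, t310):
        g = EnergyGrid(
            (Axis("x", 0, 2, 3),), np.zeros(3),
            mask=np.array([True, False, False]),
        )
        with pytest.raises(ValueError):
            edge_resistance(g, 0, 1, t310)


class TestShortestResistancePath:
    def test_flat_1d_path_and_cost(self, grid_1d_flat, t310):
        p = shortest_resistance_path(grid_1d_flat, 0, 4, t310)
        assert p.nodes == (0, 1, 2, 3, 4)
        assert p.cost == pytest.approx(4.0)

    def test_symmetric_cost(self, t310):
        g = random_grid_2d(seed=3, n=10)
        a, b = 0, g.values.size - 1
        ab = shortest_resistance_path(g, a, b, t310)
        ba = shortest_resistance_path(g, b, a, t310)
        assert ab.log_cost == pytest.approx(ba.log_cost, rel=1e-12)

    def test_corridor_beats_ridge_and_matches_enumeration(self, t310):
        # 4x4 grid: a high ridge across the middle except a low gap
        v = np.zeros((4, 4))
        v[:, 1:3] = 30.0
        v[3, 1:3] = 0.5  # corridor along the bottom edge
        g = EnergyGrid((Axis("x", 0, 3, 4), Axis("y", 0, 3, 4)), v)
        a, b = 0, 3  # (0,0) -> (0,3), separated by the ridge
        p = shortest_resistance_path(g, a, b, t310, connectivity="axis")
        assert all(np.unravel_index(n, (4, 4))[0] == 3 or
                   np.unravel_index(n, (4, 4))[1] in (0, 3)
                   for n in p.nodes)
        assert p.cost == pytest.approx(
            _enumerate_min_cost(g, a, b, t310), rel=1e-9
        )

    def test_disconnected_raises(self, t310):
        g = EnergyGrid(
            (Axis("x", 0, 2, 3),), np.zeros(3),
            mask=np.array([False, True, False]),
        )
        with pytest.raises(NoPathError):
            shortest_resistance_path(g, 0, 2, t310)

    def test_cost_strictly_increasing(self, t310):
        g = random_grid_2d(seed=5, n=12)
        p = shortest_resistance_path(g, 0, g.values.size - 1, t310)
        assert np.all(np.diff(p.log_cumulative_cost) > 0) or len(p.nodes) == 1


def _enumerate_min_cost(grid, a, b, T, connectivity="axis"):
    """Brute-force minimum resistance over all simple paths (tiny grids)."""
    from campath.mfep_core import log_edge_resistance, neighbor_offsets

    shape = grid.shape
    offs = neighbor_offsets(grid.ndim, connectivity)
    best = [math.inf]

    def neighbors(n):
        idx = np.array(np.unravel_index(n, shape))
        for o in offs:
            j = idx + o
            if np.all(j >= 0) and np.all(j < shape):
                yield int(np.ravel_multi_index(tuple(j), shape))

    def walk(node, visited, cost):
        if node == b:
            best[0] = min(best[0], cost)
            return
        for v in neighbors(node):
            if v in visited:
                continue
            c = cost + math.exp(log_edge_resistance(grid, node, v, T))
            if c < best[0]:
                walk(v, visited | {v}, c)

    walk(a, {a}, 0.0)
    return best[0]


class TestMfep:
    def test_bowl_path_passes_through_minimum(self, t310):
        g = toy_landscape(ToyLandscapeSpec("bowl_2d", spacing=0.1))
        res = mfep(g, (-1.0, 0.0), (1.0, 0.0), t310)
        center = int(np.argmin(g.values))
        assert center in res.path.nodes

    def test_double_well_barrier_and_saddle(self, t310):
        g = toy_landscape(ToyLandscapeSpec("double_well_2d", spacing=0.05))
        res = mfep(g, (-1.0, 0.0), (1.0, 0.0), t310)
        # analytic saddle 1 kJ/mol at the origin; energy resolution ~ the
        # grid-spacing change of the quartic near its steepest point
        assert res.barrier == pytest.approx(1.0, abs=0.15)
        saddle = res.path.coords[np.argmax(res.path.energies)]
        assert np.linalg.norm(saddle) < 0.11

    @pytest.mark.parametrize("seed", [0, 2, 3, 4, 5, 6])
    def test_cg_cost_equals_full_grid_dijkstra(self, seed, t310):
        # seeds chosen so each landscape has at least two basins
        g = random_smooth_landscape(seed, n_bins=25)
        bd = find_fixed_points(build_successor_map(g))
        fps = sorted(bd.fixed_points, key=lambda f: g.values.ravel()[f])
        assert len(fps) >= 2
        a, b = fps[0], fps[1]
        full = shortest_resistance_path(g, a, b, t310)
        ca = g.node_coords(np.unravel_index(a, g.shape))
        cb = g.node_coords(np.unravel_index(b, g.shape))
        res = mfep(g, ca, cb, t310)
        assert res.path.log_cost == pytest.approx(full.log_cost, rel=1e-9)

    def test_constant_energy_shift_leaves_path_unchanged(self, t310):
        import dataclasses
        g = random_smooth_landscape(9, n_bins=20)
        bd = find_fixed_points(build_successor_map(g))
        fps = sorted(bd.fixed_points)
        a, b = fps[0], fps[-1]
        ca = g.node_coords(np.unravel_index(a, g.shape))
        cb = g.node_coords(np.unravel_index(b, g.shape))
        res1 = mfep(g, ca, cb, t310)
        g2 = dataclasses.replace(g, values=g.values + 7.5)
        res2 = mfep(g2, ca, cb, t310)
        assert res1.path.nodes == res2.path.nodes
        # cost rescales by exp(shift/RT)
        assert res2.path.log_cost - res1.path.log_cost == pytest.approx(
            7.5 / t310.rt, rel=1e-9
        )

    def test_masked_unreachable_raises(self, t310):
        v = np.zeros((5, 5))
        g = EnergyGrid((Axis("x", 0, 4, 5), Axis("y", 0, 4, 5)), v)
        m = np.zeros((5, 5), dtype=bool)
        m[2, :] = True  # wall across the grid
        g = EnergyGrid(g.axes, v, mask=m)
        with pytest.raises(NoPathError):
            mfep(g, (0.0, 2.0), (4.0, 2.0), t310)

    def test_low_temperature_minimax_limit(self):
        import scipy.ndimage as ndi

        T1 = Temperature(1.0)
        for seed in range(5):
            g = random_smooth_landscape(seed, n_bins=18)
            bd = find_fixed_points(build_successor_map(g))
            fps = sorted(bd.fixed_points, key=lambda f: g.values.ravel()[f])
            if len(fps) < 2:
                continue
            a, b = fps[0], fps[1]
            path = shortest_resistance_path(g, a, b, T1)
            # oracle: lowest threshold at which a and b percolate
            ia = np.unravel_index(a, g.shape)
            ib = np.unravel_index(b, g.shape)
            minimax = None
            for h in np.unique(g.values):
                lab, _ = ndi.label(g.values <= h, structure=np.ones((3, 3)))
                if lab[ia] != 0 and lab[ia] == lab[ib]:
                    minimax = h
                    break
            assert path.energies.max() == pytest.approx(minimax, rel=1e-12)


class TestProfiles:
    def test_single_node_profile(self, t310):
        g = grid_1d([2.0, 1.0, 3.0])
        res = mfep(g, [1.0], [1.0], t310)
        assert res.profile.shape == (1, 2)
        assert res.profile[0, 1] == 1.0

    def test_uniform_spacing_reaction_coordinate(self, grid_1d_flat, t310):
        p = shortest_resistance_path(grid_1d_flat, 0, 4, t310)
        prof = path_profile(grid_1d_flat, p)
        assert prof[:, 0].tolist() == [0.0, 0.25, 0.5, 0.75, 1.0]

    def test_profile_max_is_path_max(self, t310):
        g = random_grid_2d(seed=8, n=10)
        p = shortest_resistance_path(g, 0, 99, t310)
        prof = path_profile(g, p)
        assert prof[:, 1].max() == p.energies.max()

    def test_identical_profiles_zero_sd(self):
        prof = np.column_stack([np.linspace(0, 1, 5), np.arange(5.0)])
        _, mean, sd = profile_statistics([prof, prof])
        assert np.all(sd == 0)
        assert mean[0] == prof[0, 1]

    def test_population_sd_convention(self):
        rc = np.linspace(0, 1, 4)
        p0 = np.column_stack([rc, np.zeros(4)])
        p2 = np.column_stack([rc, np.full(4, 2.0)])
        _, mean, sd = profile_statistics([p0, p2])
        assert np.all(mean == 1.0)
        assert np.all(sd == 1.0)

    def test_statistics_match_brute_force(self):
        rng = np.random.default_rng(4)
        rc = np.linspace(0, 1, 11)
        profs = [np.column_stack([rc, rng.standard_normal(11)]) for _ in range(5)]
        grid_rc, mean, sd = profile_statistics(profs, n_points=11)
        stack = np.stack([p[:, 1] for p in profs])
        np.testing.assert_allclose(mean, stack.mean(axis=0))
        np.testing.assert_allclose(sd, stack.std(axis=0))

    def test_single_profile_sd_undefined(self):
        prof = np.column_stack([np.linspace(0, 1, 5), np.arange(5.0)])
        with pytest.raises(ValueError):
            profile_statistics([prof])


class TestBarrierHeight:
    def test_monotone_decreasing_zero_barrier(self):
        prof = np.column_stack([np.linspace(0, 1, 4), [3.0, 2.0, 1.0, 0.0]])
        assert barrier_height(prof, "start_min") == 0.0

    def test_simple_peak(self):
        prof = np.column_stack([np.linspace(0, 1, 3), [0.0, 5.0, 2.0]])
        assert barrier_height(prof, "start_min") == 5.0
        assert barrier_height(prof, "global_min") == 5.0

    def test_global_min_reference(self):
        prof = np.column_stack([np.linspace(0, 1, 3), [1.0, 5.0, -2.0]])
        assert barrier_height(prof, "global_min") == 7.0
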