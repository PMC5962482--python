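"""Cell grid, pair enumeration vs the brute-force oracle, chunk schedule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mfdpd as m


class TestCellGrid:
    def test_unit_cells(self):
        grid = m.build_cell_grid(m.BoxGeometry([10, 10, 10]))
        assert tuple(grid.n_cells) == (10, 10, 10)
        assert np.allclose(grid.cell_size, 1.0)

    def test_floor_rule(self):
        grid = m.build_cell_grid(m.BoxGeometry([10.5, 10, 10]))
        assert grid.n_cells[0] == 10
        assert grid.cell_size[0] == pytest.approx(1.05)

    def test_too_small_axis_rejected(self):
        with pytest.raises(m.GeometryError):
            m.BoxGeometry([2, 10, 10])

    def test_26_distinct_neighbors_periodic(self):
        grid = m.build_cell_grid(m.BoxGeometry([6, 6, 6]))
        for c in range(grid.n_total):
            nbrs = grid.neighbors[c]
            assert np.all(nbrs >= 0)
            assert len(set(nbrs.tolist())) == 26
            assert c not in set(nbrs.tolist())

    def test_half_set_partitions_neighbor_relations(self):
        # every (cell, neighbor) relation appears in exactly one of the two
        # cells' designated half-sets
        grid = m.build_cell_grid(m.BoxGeometry([4, 5, 6]))
        half = [set(grid.half_neighbors[c].tolist()) - {-1}
                for c in range(grid.n_total)]
        for c in range(grid.n_total):
            assert len(half[c]) == 13
            for nb in grid.neighbors[c]:
                nb = int(nb)
                count = (nb in half[c]) + (c in half[nb])
                assert count == 1, (c, nb)

    def test_reflective_axis_truncates(self):
        grid = m.build_cell_grid(
            m.BoxGeometry([5, 5, 5], ("reflective", "periodic", "periodic")))
        corner = int(grid.flat_index(np.array([0, 0, 0])))
        assert (grid.neighbors[corner] == -1).sum() > 0


class TestAssign:
    def test_origin_particle(self):
        grid = m.build_cell_grid(m.BoxGeometry([5, 5, 5]))
        m.assign_particles(grid, np.array([[0.0, 0.0, 0.0]]))
        assert grid.cell_of[0] == 0

    def test_upper_edge_clamped(self):
        grid = m.build_cell_grid(m.BoxGeometry([5, 5, 5]))
        m.assign_particles(grid, np.array([[5.0, 0.0, 0.0]]))
        assert grid.cell_of[0] == int(grid.flat_index(np.array([4, 0, 0])))

    def test_occupancy_conserved(self):
        rng = np.random.default_rng(0)
        grid = m.build_cell_grid(m.BoxGeometry([10, 10, 10]))
        pos = rng.random((3000, 3)) * 10
        m.assign_particles(grid, pos)
        assert (grid.starts[1:] - grid.starts[:-1]).sum() == 3000
        head, nxt = grid.head_next
        seen = 0
        for c in range(grid.n_total):
            p = head[c]
            while p >= 0:
                seen += 1
                p = nxt[p]
        assert seen == 3000

    def test_outside_box_named(self):
        grid = m.build_cell_grid(m.BoxGeometry([5, 5, 5]))
        with pytest.raises(m.ConsistencyError, match="particle 1"):
            m.assign_particles(grid, np.array([[1.0, 1, 1], [7.0, 1, 1]]))


class TestEnumerate:
    def test_single_pair(self):
        grid = m.build_cell_grid(m.BoxGeometry([5, 5, 5]))
        pos = np.array([[1.0, 1, 1], [1.5, 1, 1]])
        m.assign_particles(grid, pos)
        cache = m.enumerate_pairs(grid, pos)
        assert len(cache) == 1
        assert cache.r[0] == pytest.approx(0.5)

    def test_cutoff_is_strict(self):
        grid = m.build_cell_grid(m.BoxGeometry([5, 5, 5]))
        pos = np.array([[1.0, 1, 1], [2.0, 1, 1]])
        m.assign_particles(grid, pos)
        assert len(m.enumerate_pairs(grid, pos)) == 0

    def test_minimum_image_across_boundary(self):
        grid = m.build_cell_grid(m.BoxGeometry([5, 5, 5]))
        pos = np.array([[0.1, 1, 1], [4.8, 1, 1]])
        m.assign_particles(grid, pos)
        cache = m.enumerate_pairs(grid, pos)
        assert len(cache) == 1
        assert cache.r[0] == pytest.approx(0.3)

    def test_stale_grid_rejected(self):
        grid = m.build_cell_grid(m.BoxGeometry([5, 5, 5]))
        pos = np.array([[1.0, 1, 1], [1.5, 1, 1]])
        m.assign_particles(grid, pos)
        with pytest.raises(m.ConsistencyError):
            m.enumerate_pairs(grid, pos.copy())

    @pytest.mark.parametrize("seed,n,box_len", [
        (0, 50, 5.0), (1, 400, 6.0), (2, 1500, 10.0), (3, 2000, 8.0)])
    def test_oracle_equivalence(self, seed, n, box_len):
        rng = np.random.default_rng(seed)
        box = m.BoxGeometry([box_len] * 3)
        pos = rng.random((n, 3)) * box_len
        grid = m.build_cell_grid(box)
        m.assign_particles(grid, pos)
        cache = m.enumerate_pairs(grid, pos)
        bi, bj, br, be = m.brute_force_pairs(pos, box)
        assert np.array_equal(cache.i, bi)
        assert np.array_equal(cache.j, bj)
        assert np.allclose(cache.r, br, atol=1e-12)
        assert np.allclose(cache.e, be, atol=1e-12)

    def test_traversal_order_does_not_matter(self):
        rng = np.random.default_rng(5)
        box = m.BoxGeometry([6, 6, 6])
        pos = rng.random((500, 3)) * 6
        grid = m.build_cell_grid(box)
        schedule = m.build_chunk_schedule(grid)
        m.assign_particles(grid, pos)
        a = m.enumerate_pairs(grid, pos, schedule=schedule)
        shuffled = schedule.cell_order(np.random.default_rng(99))
        b = m.enumerate_pairs(grid, pos, cell_order=shuffled)
        assert np.array_equal(a.i, b.i) and np.array_equal(a.j, b.j)
        assert np.array_equal(a.r, b.r) and np.array_equal(a.e, b.e)

    def test_linear_scaling_of_candidates(self):
        # candidate count at fixed density grows ~ linearly with N
        rng = np.random.default_rng(11)
        counts = {}
        for n, box_len in ((1_000, 10.0), (8_000, 20.0)):
            box = m.BoxGeometry([box_len] * 3)
            pos = rng.random((n, 3)) * box_len
            grid = m.build_cell_grid(box)
            m.assign_particles(grid, pos)
            counts[n] = m.enumerate_pairs(grid, pos).n_candidates
        exponent = np.log(counts[8_000] / counts[1_000]) / np.log(8.0)
        assert 0.9 <= exponent <= 1.1


class TestExpectedPairCount:
    def test_density_three_gives_forty_n(self):
        assert m.expected_pair_count(1, 3.0) == 40.0
        assert m.expected_pair_count(3000, 3.0) == 120000.0

    def test_density_one(self):
        assert m.expected_pair_count(10, 1.0) == 130.0

    def test_zero_particles(self):
        assert m.expected_pair_count(0, 3.0) == 0.0


class TestChunkSchedule:
    def test_six_cubed_gives_18_even_groups(self):
        grid = m.build_cell_grid(m.BoxGeometry([6, 6, 6]))
        schedule = m.build_chunk_schedule(grid)
        assert schedule.n_groups == 18
        assert all(len(g) == 12 for g in schedule.groups)

    @pytest.mark.parametrize("dims", [(6, 6, 6), (7, 7, 7), (4, 5, 6),
                                      (10, 10, 10), (3, 3, 3)])
    def test_partition_and_safety(self, dims):
        grid = m.build_cell_grid(m.BoxGeometry(list(map(float, dims))))
        schedule = m.build_chunk_schedule(grid)
        # verify_schedule raises on any partition/conflict violation
        m.verify_schedule(grid, schedule)
        covered = np.concatenate(schedule.groups)
        assert sorted(covered.tolist()) == list(range(grid.n_total))

    def test_same_group_cells_are_never_neighbors(self):
        grid = m.build_cell_grid(m.BoxGeometry([6, 6, 6]))
        schedule = m.build_chunk_schedule(grid)
        nbr_sets = [set(grid.neighbors[c].tolist())
                    for c in range(grid.n_total)]
        for group in schedule.groups:
            for a in group:
                for b in group:
                    if a != b:
                        assert b not in nbr_sets[a]

    def test_write_sets_disjoint_on_random_occupancy(self):
        # the lock-free contract at particle level: within one group, the
        # particles touched by two cells' accumulations never overlap
        rng = np.random.default_rng(21)
        box = m.BoxGeometry([6, 6, 6])
        pos = rng.random((600, 3)) * 6
        grid = m.build_cell_grid(box)
        schedule = m.build_chunk_schedule(grid)
        m.assign_particles(grid, pos)
        members = lambda c: set(
            grid.order[grid.starts[c]:grid.starts[c + 1]].tolist())
        for group in schedule.groups:
            touched = set()
            for c in group:
                mine = members(int(c))
                for h in grid.half_neighbors[int(c)]:
                    if h >= 0:
                        mine |= members(int(h))
                assert not (mine & touched)
                touched |= mine
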