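"""Force terms: printed-value checks, Newton's third law, noise moments,
energy-force consistency."""

import numpy as np
import pytest

import mfdpd as m
from mfdpd.forces import dissipative_forces, random_forces
from conftest import make_engine, make_fluid_spec, two_particle_cache


def test_weight_function_identity():
    r = np.linspace(0.0, 1.5, 301)
    assert np.array_equal(m.omega_r(r) ** 2, m.omega_d(r))
    assert np.all(m.omega_d(r[r >= 1.0]) == 0.0)


class TestConservative:
    def test_printed_example(self):
        state, box, cache = two_particle_cache(0.5)
        forces = np.zeros((2, 3))
        u, _ = m.conservative_dpd(cache, m.InteractionMatrix([[25.0]]),
                                  state.type_index, forces)
        # a (1 - r) = 25 * 0.5 = 12.5 on each partner, opposite directions
        assert np.linalg.norm(forces[0]) == pytest.approx(12.5)
        assert np.allclose(forces[0], -forces[1])
        # repulsion pushes the pair apart
        assert forces[0][0] < 0 < forces[1][0]
        assert u == pytest.approx(25.0 * 0.25 / 2.0)  # 3.125

    def test_zero_at_cutoff(self):
        state, box, cache = two_particle_cache(1.0)
        assert len(cache) == 0

    def test_type_index_bounds_checked(self):
        state, box, cache = two_particle_cache(0.5)
        state.type_index[:] = 3
        with pytest.raises(m.ParameterError):
            m.conservative_dpd(cache, m.InteractionMatrix([[25.0]]),
                               state.type_index, np.zeros((2, 3)))

    def test_newtons_third_law_full_field(self, fluid200):
        spec, (state, field, grid, schedule, cache, _) = fluid200
        res = m.compute_all_forces(state, field, cache, step=3)
        assert np.all(np.abs(res.forces.sum(axis=0)) < 1e-9)


class TestBonds:
    def _bonds(self, k=4.0, r0=1.0, kind="topological"):
        return {"i": np.array([0]), "j": np.array([1]),
                "k": np.array([k]), "r0": np.array([r0]),
                "kind": np.array([kind], dtype=object)}

    def test_equilibrium_is_force_free(self):
        state, box, _ = two_particle_cache(1.0)
        forces = np.zeros((2, 3))
        u, _ = m.bond_forces(self._bonds(), state.positions, box, forces)
        assert np.all(forces == 0.0)
        assert u == 0.0

    def test_stretched_restoring_force(self):
        state, box, _ = two_particle_cache(1.5)
        forces = np.zeros((2, 3))
        u, _ = m.bond_forces(self._bonds(), state.positions, box, forces)
        # -k (r - r0) = -4 * 0.5 = 2.0 pulling the pair together
        assert np.linalg.norm(forces[0]) == pytest.approx(2.0)
        assert forces[0][0] > 0 > forces[1][0]   # inward
        assert u == pytest.approx(0.5)

    def test_bond_kinds_are_equivalent(self):
        state, box, _ = two_particle_cache(1.3)
        f_topo = np.zeros((2, 3))
        f_back = np.zeros((2, 3))
        m.bond_forces(self._bonds(kind="topological"), state.positions, box,
                      f_topo)
        m.bond_forces(self._bonds(kind="backbone"), state.positions, box,
                      f_back)
        assert np.array_equal(f_topo, f_back)

    def test_zero_length_with_rest_length_flagged(self):
        state, box, _ = two_particle_cache(0.0)
        with pytest.raises(m.DivergenceError):
            m.bond_forces(self._bonds(), state.positions, box,
                          np.zeros((2, 3)))

    def test_minimum_image_bond(self):
        box = m.BoxGeometry([5, 5, 5])
        pos = np.array([[0.2, 1, 1], [4.9, 1, 1]])   # true separation 0.3
        forces = np.zeros((2, 3))
        u, _ = m.bond_forces(self._bonds(k=2.0, r0=0.3), pos, box, forces)
        assert u == pytest.approx(0.0)
        assert np.all(np.abs(forces) < 1e-12)


class TestDissipative:
    def test_no_relative_motion_no_force(self):
        state, box, cache = two_particle_cache(0.5)
        state.velocities[:] = [1.0, 2.0, 3.0]
        forces = np.zeros((2, 3))
        dissipative_forces(cache, state.velocities, 4.5, forces)
        assert np.all(forces == 0.0)

    def test_perpendicular_relative_velocity_no_force(self):
        state, box, cache = two_particle_cache(0.5)
        state.velocities[0] = [0.0, 1.0, 0.0]   # pair axis is x
        forces = np.zeros((2, 3))
        dissipative_forces(cache, state.velocities, 4.5, forces)
        assert np.all(np.abs(forces) < 1e-15)

    def test_printed_example(self):
        state, box, cache = two_particle_cache(0.5)
        # v_ij . e = 2 along the pair axis
        state.velocities[0] = [-2.0, 0.0, 0.0]
        forces = np.zeros((2, 3))
        dissipative_forces(cache, state.velocities, 4.5, forces)
        # gamma wD (e.v) = 4.5 * 0.25 * 2 = 2.25 opposing relative motion
        assert np.linalg.norm(forces[0]) == pytest.approx(2.25)
        assert forces[0][0] > 0   # slows particle 0 down


class TestRandom:
    def test_zero_sigma(self):
        state, box, cache = two_particle_cache(0.5)
        forces = np.zeros((2, 3))
        random_forces(cache, 0.0, 0.04, m.NoiseStream(1), 0, forces)
        assert np.all(forces == 0.0)

    def test_bad_dt_rejected(self):
        state, box, cache = two_particle_cache(0.5)
        with pytest.raises(m.ParameterError):
            random_forces(cache, 3.0, 0.0, m.NoiseStream(1), 0,
                          np.zeros((2, 3)))

    def test_deterministic_replay(self):
        state, box, cache = two_particle_cache(0.5)
        f1 = np.zeros((2, 3))
        f2 = np.zeros((2, 3))
        random_forces(cache, 3.0, 0.04, m.NoiseStream(7), 5, f1)
        random_forces(cache, 3.0, 0.04, m.NoiseStream(7), 5, f2)
        assert np.array_equal(f1, f2)

    @pytest.mark.parametrize("kind", ["uniform", "gaussian"])
    def test_moments_match_formula(self, kind):
        # pair-force magnitude over many steps at fixed r: mean ~ 0,
        # variance ~ sigma^2 wR(r)^2 / dt
        state, box, cache = two_particle_cache(0.4)
        sigma, dt = 3.0, 0.04
        noise = m.NoiseStream(123, kind)
        samples = np.empty(20000)
        for s in range(samples.size):
            f = np.zeros((2, 3))
            random_forces(cache, sigma, dt, noise, s, f)
            samples[s] = f[0, 0]
        expect_var = sigma ** 2 * (1 - 0.4) ** 2 / dt
        assert abs(samples.mean()) < 0.05 * np.sqrt(expect_var)
        assert samples.var() == pytest.approx(expect_var, rel=0.05)


class TestGravity:
    def test_zero_gravity_noop(self):
        forces = np.zeros((3, 3))
        m.gravity_forces(np.ones(3), np.zeros(3), forces)
        assert np.all(forces == 0.0)

    def test_mass_weighted(self):
        forces = np.zeros((1, 3))
        m.gravity_forces(np.array([2.0]), np.array([0, 0, -1.0]), forces)
        assert np.allclose(forces[0], [0, 0, -2.0])

    def test_external_field_breaks_momentum_conservation(self, fluid200):
        spec, (state, field, grid, schedule, cache, _) = fluid200
        field.gravity = np.array([0.0, 0.0, -1.0])
        res = m.compute_all_forces(state, field, cache, step=0)
        assert res.forces.sum(axis=0)[2] == pytest.approx(-state.masses.sum())


class TestEnergyForceConsistency:
    def test_gradient_matches_force(self):
        # central finite differences of U_dpd + U_bond against the
        # analytic conservative force, random small system with bonds
        rng = np.random.default_rng(17)
        spec = make_fluid_spec(n=30, box_len=4.0, sigma=0.0, seed=17)
        state, field, grid, schedule, cache, _ = make_engine(spec)
        bonds = {"i": np.array([0, 2]), "j": np.array([1, 3]),
                 "k": np.array([4.0, 2.0]), "r0": np.array([0.7, 0.0])}
        field.bonds = bonds

        def u_of(flat):
            pos = flat.reshape(-1, 3) % spec.box.lengths[None, :]
            m.assign_particles(grid, pos)
            c = m.enumerate_pairs(grid, pos)
            scratch = np.zeros_like(pos)
            u1, _ = m.conservative_dpd(c, field.interactions,
                                       state.type_index, scratch)
            u2, _ = m.bond_forces(bonds, pos, spec.box, scratch)
            return u1 + u2

        res = m.compute_all_forces(state, field, cache,
                                   include=("conservative", "bond"))
        flat = state.positions.ravel().copy()
        h = 1e-6
        idx = rng.choice(flat.size, size=25, replace=False)
        scale = max(1.0, np.abs(res.forces).max())
        for k in idx:
            fp = flat.copy()
            fp[k] += h
            fm = flat.copy()
            fm[k] -= h
            grad = (u_of(fp) - u_of(fm)) / (2 * h)
            force = res.forces.ravel()[k]
            assert abs(-grad - force) / scale < 1e-5


class TestDeterminismAndChunks:
    def test_forces_independent_of_traversal_order(self, fluid200):
        spec, (state, field, grid, schedule, cache, _) = fluid200
        res1 = m.compute_all_forces(state, field, cache, step=2)
        shuffled = schedule.cell_order(np.random.default_rng(4))
        cache2 = m.enumerate_pairs(grid, state.positions,
                                   cell_order=shuffled)
        res2 = m.compute_all_forces(state, field, cache2, step=2)
        assert np.array_equal(res1.forces, res2.forces)

    def test_bond_coloring_is_conflict_free(self):
        # a 30-bead chain: adjacent bonds share a particle and must take
        # different colors
        n = 30
        bonds = {"i": np.arange(n - 1), "j": np.arange(1, n),
                 "k": np.ones(n - 1), "r0": np.full(n - 1, 0.7)}
        color = m.forces.color_bonds(bonds, n)
        for a in range(n - 1):
            for b in range(a + 1, n - 1):
                if color[a] == color[b]:
                    assert len({bonds["i"][a], bonds["j"][a]} &
                               {bonds["i"][b], bonds["j"][b]}) == 0
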