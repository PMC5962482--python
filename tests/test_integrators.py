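"""Integration schemes: defining relationships, conservation laws,
minimization and the run loop."""

import numpy as np
import pytest

import mfdpd as m
from mfdpd.integrators import StepContext, _initial_forces
from mfdpd.reference import reference_vv_trajectory
from conftest import make_engine, make_fluid_spec


def make_ctx(spec, state, field, scheme=None):
    grid = m.build_cell_grid(spec.box)
    schedule = m.build_chunk_schedule(grid)
    ctx = StepContext(grid=grid, schedule=schedule, config=spec.config)
    ctx.refresh_cache(state)
    _initial_forces(state, field, ctx,
                    scheme or spec.config.integrator.scheme)
    return ctx


def run_steps(spec, n, scheme, **integ_kwargs):
    spec.config.integrator = m.IntegratorConfig(scheme=scheme,
                                                **integ_kwargs)
    spec.config.steps = n
    spec.config.output_every = max(n, 1)
    sim = m.Simulation(spec)
    return sim.run()


class TestFreeStreaming:
    def test_uniform_motion_without_forces(self):
        spec = make_fluid_spec(n=20, box_len=5.0, a=0.0, sigma=0.0, dt=0.01)
        state, field, grid, schedule, cache, _ = make_engine(spec)
        ctx = make_ctx(spec, state, field)
        v0 = state.velocities.copy()
        p0 = state.positions.copy()
        for s in range(1, 11):
            ctx.step = s
            m.step_gwmvv(state, field, ctx)
        assert np.array_equal(state.velocities, v0)
        expected = (p0 + 10 * 0.01 * v0) % spec.box.lengths[None, :]
        assert np.allclose(state.positions, expected, atol=1e-12)


class TestGWMVV:
    def test_half_lambda_matches_independent_vv(self):
        # lambda = 0.5 makes GWMVV coincide with velocity-Verlet; the
        # reference is the brute-force O(N^2) implementation
        spec = make_fluid_spec(n=100, box_len=5.0, sigma=3.0, dt=0.02,
                               seed=42)
        state, field, grid, schedule, cache, _ = make_engine(spec)
        ref_pos, ref_vel = reference_vv_trajectory(
            state.positions, state.velocities, state.masses,
            state.type_index, spec.interactions, spec.box,
            sigma=3.0, kBT=1.0, dt=0.02, n_steps=30, seed=42)
        ctx = make_ctx(spec, state, field)
        for s in range(1, 31):
            ctx.step = s
            m.step_gwmvv(state, field, ctx, lam=0.5)
        assert np.abs(state.positions - ref_pos).max() < 1e-12

    def test_other_lambda_diverges_from_vv(self):
        spec = make_fluid_spec(n=100, box_len=5.0, sigma=3.0, dt=0.02,
                               seed=42)
        state, field, grid, schedule, cache, _ = make_engine(spec)
        ref_pos, _ = reference_vv_trajectory(
            state.positions, state.velocities, state.masses,
            state.type_index, spec.interactions, spec.box,
            sigma=3.0, kBT=1.0, dt=0.02, n_steps=30, seed=42)
        ctx = make_ctx(spec, state, field)
        for s in range(1, 31):
            ctx.step = s
            m.step_gwmvv(state, field, ctx, lam=0.9)
        assert np.abs(state.positions - ref_pos).max() > 1e-7

    def test_dimer_oscillation_period(self, dimer_spec):
        # two unit masses on a k=4 spring: analytic period 2 pi sqrt(m/2k)
        state, bonds = m.build_system(dimer_spec)
        noise = m.NoiseStream(0)
        field = m.ForceField(interactions=dimer_spec.interactions,
                             bonds=bonds, thermostat=m.ThermostatParams(
                                 sigma=0.0, dt=0.01),
                             noise=noise, box=dimer_spec.box)
        # stretch the bond along x and release from rest
        state.positions[0] = [2.0, 3.0, 3.0]
        state.positions[1] = [3.3, 3.0, 3.0]
        state.velocities[:] = 0.0
        ctx = make_ctx(dimer_spec, state, field)
        seps = []
        for s in range(1, 501):
            ctx.step = s
            m.step_gwmvv(state, field, ctx, lam=0.5)
            seps.append(np.linalg.norm(state.positions[0]
                                       - state.positions[1]))
        seps = np.asarray(seps)
        # separation oscillates around r0 = 1; find the mean period from
        # downward crossings of the rest length
        crossings = np.nonzero((seps[:-1] > 1.0) & (seps[1:] <= 1.0))[0]
        period = np.diff(crossings).mean() * 0.01
        assert period == pytest.approx(2 * np.pi * np.sqrt(1.0 / 8.0),
                                       rel=0.02)


class TestSCMVV:
    def test_single_iteration_is_dpdmvv(self):
        spec1 = make_fluid_spec(n=150, seed=5)
        r1 = run_steps(spec1, 25, "SCMVV", n_self_consistent=1)
        spec2 = make_fluid_spec(n=150, seed=5)
        r2 = run_steps(spec2, 25, "DPDMVV")
        assert np.array_equal(r1.state.positions, r2.state.positions)
        assert np.array_equal(r1.state.velocities, r2.state.velocities)

    def test_iterations_irrelevant_without_friction(self):
        # gamma = 0 (sigma = 0): the dissipative term vanishes and any
        # iteration count produces the same trajectory
        outs = []
        for n_iter in (1, 5):
            spec = make_fluid_spec(n=150, sigma=0.0, seed=6)
            outs.append(run_steps(spec, 20, "SCMVV",
                                  n_self_consistent=n_iter))
        assert np.array_equal(outs[0].state.positions,
                              outs[1].state.positions)


class TestS1MVV:
    def test_reduces_to_vv_without_thermostat(self):
        spec = make_fluid_spec(n=100, sigma=0.0, dt=0.02, seed=8)
        state, field, grid, schedule, cache, _ = make_engine(spec)
        ref_pos, _ = reference_vv_trajectory(
            state.positions, state.velocities, state.masses,
            state.type_index, spec.interactions, spec.box,
            sigma=0.0, kBT=1.0, dt=0.02, n_steps=25, seed=8)
        ctx = make_ctx(spec, state, field, scheme="S1MVV")
        for s in range(1, 26):
            ctx.step = s
            m.step_s1mvv(state, field, ctx)
        assert np.abs(state.positions - ref_pos).max() < 1e-12

    def test_sweep_conserves_momentum_exactly(self):
        spec = make_fluid_spec(n=300, seed=9)
        state, field, grid, schedule, cache, _ = make_engine(spec)
        from mfdpd._kernels import _s1_sweep
        p_before = state.velocities.sum(axis=0)   # unit masses
        zeta = field.noise.pair_zeta(1, 0, cache.i, cache.j)
        _s1_sweep(cache.i, cache.j, cache.r, cache.e, state.velocities,
                  1.0 / state.masses, 4.5, 3.0, 0.04, zeta)
        p_after = state.velocities.sum(axis=0)
        assert np.all(np.abs(p_after - p_before) < 1e-11)


class TestPNHLN:
    def test_vanishing_coupling_recovers_conservative_dynamics(self):
        # with the coupling sent to zero the auxiliary friction stays at
        # zero and the noise stream becomes irrelevant: different seeds
        # must give bit-identical trajectories
        outs = []
        for seed_noise in (100, 200):
            spec = make_fluid_spec(n=120, seed=3)
            spec.config.integrator = m.IntegratorConfig(
                scheme="PNHLN", coupling=1e-300)
            state, field, grid, schedule, cache, _ = make_engine(spec)
            field.noise = m.NoiseStream(seed_noise)
            ctx = make_ctx(spec, state, field, scheme="PNHLN")
            for s in range(1, 21):
                ctx.step = s
                m.step_pnhln(state, field, ctx)
            outs.append(state.positions.copy())
        assert np.array_equal(outs[0], outs[1])

    def test_momentum_conserved(self):
        spec = make_fluid_spec(n=200, seed=10)
        res = run_steps(spec, 200, "PNHLN", coupling=1.0)
        p = (res.state.masses[:, None] * res.state.velocities).sum(axis=0)
        assert np.all(np.abs(p) < 1e-9)


class TestMomentumConservation:
    @pytest.mark.parametrize("scheme", ["GWMVV", "DPDMVV", "SCMVV",
                                        "S1MVV", "PNHLN"])
    def test_per_step_drift_tiny(self, scheme):
        spec = make_fluid_spec(n=200, seed=11)
        res = run_steps(spec, 100, scheme)
        p = (res.state.masses[:, None] * res.state.velocities).sum(axis=0)
        assert np.all(np.abs(p) / 100 < 1e-10)


class TestScaleVelocities:
    def test_already_at_target(self):
        spec = make_fluid_spec(n=100, seed=12)
        state, _ = m.build_system(spec)
        t = m.kinetic_temperature(state)
        assert m.scale_velocities(state, t) == pytest.approx(1.0)

    def test_double_temperature_gives_inverse_sqrt_two(self):
        spec = make_fluid_spec(n=100, seed=12)
        state, _ = m.build_system(spec)
        t = m.kinetic_temperature(state)
        factor = m.scale_velocities(state, t / 2.0)
        assert factor == pytest.approx(1 / np.sqrt(2))

    def test_postcondition_exact(self):
        spec = make_fluid_spec(n=100, seed=12)
        state, _ = m.build_system(spec)
        m.scale_velocities(state, 1.7)
        assert m.kinetic_temperature(state) == pytest.approx(1.7, abs=1e-13)

    def test_zero_kinetic_energy_warns(self):
        spec = make_fluid_spec(n=10, seed=12)
        state, _ = m.build_system(spec)
        state.velocities[:] = 0.0
        with pytest.warns(UserWarning):
            assert m.scale_velocities(state, 1.0) == 1.0


class TestMinimization:
    def test_zero_steps_is_identity(self):
        spec = make_fluid_spec(n=50, seed=13)
        state, field, grid, schedule, cache, _ = make_engine(spec)
        ctx = make_ctx(spec, state, field)
        before = state.positions.copy()
        m.minimize_start(state, field, ctx, 0)
        assert np.array_equal(before, state.positions)

    def test_overlapping_particles_relax(self):
        spec = make_fluid_spec(n=2, box_len=5.0, seed=14)
        state, field, grid, schedule, cache, _ = make_engine(spec)
        state.positions[0] = [2.0, 2.0, 2.0]
        state.positions[1] = [2.001, 2.0, 2.0]
        v_before = state.velocities.copy()
        ctx = make_ctx(spec, state, field)
        ctx.refresh_cache(state)
        res0 = m.compute_all_forces(state, field, ctx.cache,
                                    include=("conservative", "bond"))
        u_final = m.minimize_start(state, field, ctx, 50)
        sep = np.linalg.norm(state.positions[0] - state.positions[1])
        assert sep > 0.01
        assert u_final < res0.u_pot
        assert np.array_equal(state.velocities, v_before)

    def test_equilibrium_dimer_stays_put(self, dimer_spec):
        state, bonds = m.build_system(dimer_spec)
        field = m.ForceField(interactions=dimer_spec.interactions,
                             bonds=bonds,
                             thermostat=dimer_spec.config.thermostat,
                             noise=m.NoiseStream(0), box=dimer_spec.box)
        state.positions[0] = [2.0, 3.0, 3.0]
        state.positions[1] = [3.0, 3.0, 3.0]   # bond at rest length 1
        ctx = make_ctx(dimer_spec, state, field)
        before = state.positions.copy()
        m.minimize_start(state, field, ctx, 5)
        assert np.allclose(state.positions, before, atol=1e-12)


class TestRunLoop:
    def test_zero_steps_yields_one_record(self):
        spec = make_fluid_spec(n=50, steps=0, seed=15)
        res = m.Simulation(spec).run()
        assert len(res.records) == 1
        assert res.records[0].step == 0

    def test_bitwise_deterministic(self):
        a = m.Simulation(make_fluid_spec(n=150, steps=30, seed=16)).run()
        b = m.Simulation(make_fluid_spec(n=150, steps=30, seed=16)).run()
        assert np.array_equal(a.state.positions, b.state.positions)
        assert np.array_equal(a.state.velocities, b.state.velocities)

    def test_velocity_scaling_holds_target(self):
        spec = make_fluid_spec(n=150, steps=20, seed=17,
                               velocity_scaling=1)
        res = m.Simulation(spec).run()
        final_t = m.kinetic_temperature(res.state)
        assert final_t == pytest.approx(1.0, abs=1e-12)

    def test_divergence_reported(self):
        # a time step so large the position update overflows must abort
        # with a diagnostic, not propagate NaNs
        spec = make_fluid_spec(n=100, steps=50, seed=18, dt=1e200)
        with pytest.raises(m.DivergenceError):
            with np.errstate(over="ignore", invalid="ignore"):
                m.Simulation(spec).run()

    def test_kicked_molecules_drift(self):
        kick = ((0.5, 0.0, 0.0), 1)
        spec = m.SystemSpec(
            box=m.BoxGeometry([6, 6, 6]), type_names=["A", "B"],
            interactions=m.InteractionMatrix([[25.0, 25.0], [25.0, 25.0]]),
            molecules=[
                m.MoleculeDescription(name="driven",
                                      particle_type_sequence=(0,),
                                      copy_count=100, force_kick=kick),
                m.MoleculeDescription(name="idle",
                                      particle_type_sequence=(1,),
                                      copy_count=100),
            ],
            config=m.SimulationConfig(steps=400, output_every=400, seed=19))
        res = m.Simulation(spec).run()
        state = res.state
        v_driven = state.velocities[state.molecule_type == 0, 0].mean()
        v_idle = state.velocities[state.molecule_type == 1, 0].mean()
        assert v_driven > v_idle + 0.1
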