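"""Shared fixtures: small programmatically generated DPD systems."""

import numpy as np
import pytest
from hypothesis import settings

import mfdpd as m

settings.register_profile("kernel", derandomize=True, deadline=None)
settings.load_profile("kernel")


def make_fluid_spec(n=200, box_len=5.0, a=25.0, sigma=3.0, kBT=1.0,
                    dt=0.04, steps=0, seed=1, scheme="GWMVV", **cfg_kwargs):
    """One-type fluid system description with sensible DPD defaults."""
    integ = cfg_kwargs.pop("integrator", m.IntegratorConfig(scheme=scheme))
    return m.SystemSpec(
        box=m.BoxGeometry([box_len] * 3),
        type_names=["W"],
        interactions=m.InteractionMatrix([[a]]),
        molecules=[m.MoleculeDescription(
            name="w", particle_type_sequence=(0,), copy_count=n)],
        config=m.SimulationConfig(
            steps=steps, thermostat=m.ThermostatParams(sigma=sigma, kBT=kBT,
                                                       dt=dt),
            integrator=integ, seed=seed, **cfg_kwargs),
    )


def make_engine(spec):
    """(state, field, grid, schedule, cache, constraints) for direct use of
    the engine layers without the run loop."""
    state, bonds = m.build_system(spec)
    noise = m.NoiseStream(spec.config.seed, spec.config.rng_kind)
    field = m.ForceField(interactions=spec.interactions, bonds=bonds,
                         thermostat=spec.config.thermostat, noise=noise,
                         box=spec.box, gravity=spec.config.gravity)
    grid = m.build_cell_grid(spec.box)
    schedule = m.build_chunk_schedule(grid)
    m.assign_particles(grid, state.positions)
    cache = m.enumerate_pairs(grid, state.positions, schedule=schedule)
    constraints = m.ConstraintSet.from_molecules(spec.molecules, spec.box)
    return state, field, grid, schedule, cache, constraints


def two_particle_cache(r, box_len=5.0):
    """A hand-built state + cache holding exactly one pair at distance r."""
    pos = np.array([[1.0, 1.0, 1.0], [1.0 + r, 1.0, 1.0]])
    state = m.ParticleState(
        positions=pos,
        velocities=np.zeros((2, 3)),
        forces=np.zeros((2, 3)),
        masses=np.ones(2),
        type_index=np.zeros(2, dtype=np.int64),
        molecule_index=np.arange(2, dtype=np.int64),
        molecule_type=np.zeros(2, dtype=np.int64),
        charge=np.zeros(2),
        images=np.zeros((2, 3), dtype=np.int64),
    )
    box = m.BoxGeometry([box_len] * 3)
    grid = m.build_cell_grid(box)
    m.assign_particles(grid, state.positions)
    cache = m.enumerate_pairs(grid, state.positions)
    return state, box, cache


@pytest.fixture
def fluid200():
    spec = make_fluid_spec(n=200, box_len=5.0)
    return spec, make_engine(spec)


@pytest.fixture
def dimer_spec():
    bond = m.Bond(0, 1, k_bond=4.0, r_bond=1.0)
    return m.SystemSpec(
        box=m.BoxGeometry([6, 6, 6]),
        type_names=["A"],
        interactions=m.InteractionMatrix([[0.0]]),
        molecules=[m.MoleculeDescription(
            name="dimer", particle_type_sequence=(0, 0),
            topological_bonds=(bond,), copy_count=1)],
        config=m.SimulationConfig(
            steps=0, thermostat=m.ThermostatParams(sigma=0.0, dt=0.01)),
    )
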