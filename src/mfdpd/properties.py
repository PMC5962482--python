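"""Per-step and trajectory-level observables.

All quantities are in reduced DPD units (k_B = 1).  The pressure tensor
diagonal uses the virial form

    P_aa = ( sum_i m_i v_ia^2  +  sum_pairs r_a F_a ) / V

over the conservative pair forces (soft repulsion + bonds); the surface
tension along axis ``a`` is the planar virial difference

    st_a = L_a * ( P_aa - (P_bb + P_cc) / 2 ).

Radii of gyration are computed from unwrapped coordinates (positions plus
periodic-image counters), so they are invariant under box wrapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ParameterError
from .forces import bond_forces, conservative_dpd
from .model import CUTOFF, BoxGeometry, ParticleState


def kinetic_temperature(state: ParticleState,
                        free_mask: Optional[np.ndarray] = None) -> float:
    """Instantaneous kinetic temperature sum(m v^2) / (3 N_free).

    Particles under position or velocity fixation do not carry thermal
    degrees of freedom and are excluded via ``free_mask``.
    """
    if state.n == 0:
        raise ParameterError("kinetic temperature of an empty system")
    v = state.velocities
    m = state.masses
    if free_mask is not None:
        v = v[free_mask]
        m = m[free_mask]
        if v.shape[0] == 0:
            raise ParameterError(
                "kinetic temperature undefined: every particle is fixed")
    return float((m[:, None] * v * v).sum() / (3.0 * v.shape[0]))


def kinetic_energy(state: ParticleState) -> float:
    v = state.velocities
    return float(0.5 * (state.masses[:, None] * v * v).sum())


def potential_energy(state: ParticleState, cache, fieldspec) -> float:
    """U = sum_pairs a_ij (1-r)^2 / 2 + sum_bonds k (r-r0)^2 / 2."""
    scratch = np.zeros_like(state.positions)
    u_dpd, _ = conservative_dpd(cache, fieldspec.interactions,
                                state.type_index, scratch)
    u_bond, _ = bond_forces(fieldspec.bonds, state.positions,
                            fieldspec.box, scratch)
    return u_dpd + u_bond


def pressure_tensor_and_surface_tension(state: ParticleState, cache,
                                        fieldspec):
    """Virial pressure diagonal and per-axis surface tensions.

    Returns ``(P_diag, st)`` with ``P_diag = (P_xx, P_yy, P_zz)``.  The
    configurational part sums the conservative pair forces (repulsion and
    bonds); in a homogeneous isotropic fluid all three tensions vanish
    within sampling error, and with all interactions off the ideal-gas
    limit P = rho kBT is recovered.
    """
    box = fieldspec.box
    scratch = np.zeros_like(state.positions)
    _, vir_dpd = conservative_dpd(cache, fieldspec.interactions,
                                  state.type_index, scratch)
    _, vir_bond = bond_forces(fieldspec.bonds, state.positions, box, scratch)
    v = state.velocities
    kin = (state.masses[:, None] * v * v).sum(axis=0)
    p_diag = (kin + vir_dpd + vir_bond) / box.volume
    st = np.array([
        box.lengths[a] * (p_diag[a] - 0.5 * (p_diag[(a + 1) % 3]
                                             + p_diag[(a + 2) % 3]))
        for a in range(3)])
    return p_diag, st


def radius_of_gyration(state: ParticleState, box: BoxGeometry,
                       grouping: str = "molecule"):
    """Mass-weighted radius of gyration per group.

    ``grouping="molecule"`` gives one Rg per molecule instance from
    unwrapped coordinates; ``grouping="type"`` groups all particles of one
    particle type.  Empty groups are skipped.  Rg is invariant under rigid
    translation and box wrapping.
    """
    pos = state.unwrapped_positions(box)
    key = {"molecule": state.molecule_index,
           "type": state.type_index}.get(grouping)
    if key is None:
        raise ParameterError("grouping must be 'molecule' or 'type'")
    groups, inv = np.unique(key, return_inverse=True)
    ng = groups.shape[0]
    m = state.masses
    m_tot = np.bincount(inv, weights=m, minlength=ng)
    com = np.stack([np.bincount(inv, weights=m * pos[:, a], minlength=ng)
                    for a in range(3)], axis=1) / m_tot[:, None]
    d2 = ((pos - com[inv]) ** 2).sum(axis=1)
    rg = np.sqrt(np.bincount(inv, weights=m * d2, minlength=ng) / m_tot)
    return {int(g): float(v) for g, v in zip(groups, rg)}


def rg_by_molecule_type(state: ParticleState, box: BoxGeometry):
    """Mean radius of gyration over the instances of each molecule type."""
    per_instance = radius_of_gyration(state, box, grouping="molecule")
    insts, first_idx = np.unique(state.molecule_index, return_index=True)
    inst_type = state.molecule_type[first_idx]
    rgs = np.array([per_instance[int(i)] for i in insts])
    out = {}
    for mt in np.unique(inst_type):
        out[int(mt)] = float(rgs[inst_type == mt].mean())
    return out


def nearest_neighbor_analysis(state: ParticleState, cache,
                              radius: float = CUTOFF):
    """Averaged particle and molecule vicinities from the pair cache.

    Particle level: for each ordered type pair (A, B), the mean number of
    B particles within ``radius`` of an A particle.  Molecule level: the
    same contact counts aggregated by molecule type with intra-molecule
    contacts excluded, normalized per molecule instance.  Tracking these
    tables over the run monitors how the particles' and molecules'
    surroundings change with time.

    Returns ``(particle_counts, molecule_counts, n_types, n_mol_types)``
    where the count arrays are directed-mean matrices.
    """
    n_types = int(state.type_index.max()) + 1 if state.n else 0
    n_mt = int(state.molecule_type.max()) + 1 if state.n else 0
    keep = cache.r < radius
    ci, cj = cache.i[keep], cache.j[keep]

    ti, tj = state.type_index[ci], state.type_index[cj]
    contacts = np.zeros((n_types, n_types))
    np.add.at(contacts, (ti, tj), 1.0)
    np.add.at(contacts, (tj, ti), 1.0)
    type_pop = np.bincount(state.type_index, minlength=n_types).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        particle_mean = np.where(type_pop[:, None] > 0,
                                 contacts / type_pop[:, None], 0.0)

    inter = state.molecule_index[ci] != state.molecule_index[cj]
    mi, mj = state.molecule_type[ci][inter], state.molecule_type[cj][inter]
    mol_contacts = np.zeros((n_mt, n_mt))
    np.add.at(mol_contacts, (mi, mj), 1.0)
    np.add.at(mol_contacts, (mj, mi), 1.0)
    # population of molecule instances per type
    _, first_idx = np.unique(state.molecule_index, return_index=True)
    mol_pop = np.bincount(state.molecule_type[first_idx],
                          minlength=n_mt).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        molecule_mean = np.where(mol_pop[:, None] > 0,
                                 mol_contacts / mol_pop[:, None], 0.0)
    return particle_mean, molecule_mean, type_pop, mol_pop


@dataclass
class PropertyRecord:
    """One output step's observables."""

    step: int
    u_dpd: float
    u_bond: float
    e_kin: float
    temperature: float
    pressure: np.ndarray          # (3,) diagonal
    surface_tension: np.ndarray   # (3,)
    cache_pairs: int
    candidate_pairs: int
    rg: dict = field(default_factory=dict)          # molecule-type -> mean Rg
    nn_particle: Optional[np.ndarray] = None
    nn_molecule: Optional[np.ndarray] = None

    @property
    def u_pot(self) -> float:
        return self.u_dpd + self.u_bond

    def as_row(self, type_names=None, molecule_names=None) -> dict:
        """Flatten to a CSV-friendly dict with stable column names."""
        row = {
            "step": self.step,
            "U_pot": self.u_pot,
            "U_dpd": self.u_dpd,
            "U_bond": self.u_bond,
            "E_kin": self.e_kin,
            "temperature": self.temperature,
            "P_xx": self.pressure[0], "P_yy": self.pressure[1],
            "P_zz": self.pressure[2],
            "st_x": self.surface_tension[0],
            "st_y": self.surface_tension[1],
            "st_z": self.surface_tension[2],
            "cache_pairs": self.cache_pairs,
            "candidate_pairs": self.candidate_pairs,
        }
        for mt, rg in sorted(self.rg.items()):
            name = molecule_names[mt] if molecule_names else f"mol{mt}"
            row[f"rg_{name}"] = rg
        if self.nn_particle is not None:
            nt = self.nn_particle.shape[0]
            for a in range(nt):
                for b in range(nt):
                    na = type_names[a] if type_names else f"t{a}"
                    nb = type_names[b] if type_names else f"t{b}"
                    row[f"nn_{na}_{nb}"] = self.nn_particle[a, b]
        if self.nn_molecule is not None:
            nm = self.nn_molecule.shape[0]
            for a in range(nm):
                for b in range(nm):
                    na = molecule_names[a] if molecule_names else f"m{a}"
                    nb = molecule_names[b] if molecule_names else f"m{b}"
                    row[f"nnmol_{na}_{nb}"] = self.nn_molecule[a, b]
        return row


def collect_record(state: ParticleState, ctx, fieldspec,
                   labels: Optional[dict] = None) -> PropertyRecord:
    """Assemble the full per-step record from a fresh step context."""
    labels = labels or {}
    free_mask = None
    if ctx.constraints is not None and ctx.constraints.fixation:
        free_mask = ~ctx.constraints.fixed_mask(state)
        if not free_mask.any():
            free_mask = None    # fully constrained: report the raw value
    p_diag, st = pressure_tensor_and_surface_tension(state, ctx.cache,
                                                     fieldspec)
    nn_p, nn_m, _, _ = nearest_neighbor_analysis(state, ctx.cache)
    fr = ctx.force_result
    if fr is not None and (fr.u_dpd != 0.0 or fr.u_bond != 0.0):
        u_dpd, u_bond = fr.u_dpd, fr.u_bond
    else:
        scratch = np.zeros_like(state.positions)
        u_dpd, _ = conservative_dpd(ctx.cache, fieldspec.interactions,
                                    state.type_index, scratch)
        u_bond, _ = bond_forces(fieldspec.bonds, state.positions,
                                fieldspec.box, scratch)
    return PropertyRecord(
        step=ctx.step,
        u_dpd=u_dpd,
        u_bond=u_bond,
        e_kin=kinetic_energy(state),
        temperature=kinetic_temperature(state, free_mask=free_mask),
        pressure=p_diag,
        surface_tension=st,
        cache_pairs=len(ctx.cache),
        candidate_pairs=ctx.cache.n_candidates,
        rg=rg_by_molecule_type(state, fieldspec.box),
        nn_particle=nn_p,
        nn_molecule=nn_m,
    )


__all__ = [
    "PropertyRecord", "kinetic_temperature", "kinetic_energy",
    "potential_energy", "pressure_tensor_and_surface_tension",
    "radius_of_gyration", "rg_by_molecule_type",
    "nearest_neighbor_analysis", "collect_record",
]
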