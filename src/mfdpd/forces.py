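"""Pairwise and external force evaluations over the pair cache.

All DPD pair interactions share the cutoff-1 weight functions

    omega_R(r) = 1 - r          (r < 1, else 0)
    omega_D(r) = omega_R(r)^2

so the fluctuation-dissipation identity omega_R^2 == omega_D holds exactly
by construction.  Force terms accumulate into a per-particle force array;
every pairwise contribution is applied equal-and-opposite, so pairwise
forces conserve momentum to numerical precision.

Accumulation is order-canonical: the pair cache is sorted (i < j,
lexicographic) and scatter-adds run per component via ``bincount``, so the
accumulated forces are a pure function of the cache regardless of how the
cells were traversed — this, together with pair-keyed noise, is what makes
results independent of the thread count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import DivergenceError, ParameterError
from .model import BoxGeometry, InteractionMatrix, ThermostatParams
from .neighbors import PairCache
from .noise import NoiseStream


def omega_r(r: np.ndarray) -> np.ndarray:
    """Random-force distance weight: 1 - r below the cutoff, else 0."""
    return np.where(r < 1.0, 1.0 - r, 0.0)


def omega_d(r: np.ndarray) -> np.ndarray:
    """Dissipative-force distance weight, omega_R squared."""
    w = omega_r(r)
    return w * w


@dataclass
class ForceField:
    """Everything needed to evaluate forces on a state.

    ``bonds`` is the flat bond table from ``build_system`` (arrays i, j, k,
    r0); ``kicks`` is filled by the run loop, not here.
    """

    interactions: InteractionMatrix
    bonds: dict
    thermostat: ThermostatParams
    noise: NoiseStream
    box: "BoxGeometry" = None
    gravity: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.gravity = np.asarray(self.gravity, dtype=np.float64)
        if "i" not in self.bonds:
            self.bonds = {"i": np.empty(0, np.int64),
                          "j": np.empty(0, np.int64),
                          "k": np.empty(0, np.float64),
                          "r0": np.empty(0, np.float64)}


@dataclass
class ForceResult:
    """Accumulated forces plus the step's energy and virial bookkeeping."""

    forces: np.ndarray     # (N, 3)
    u_dpd: float = 0.0
    u_bond: float = 0.0
    virial: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def u_pot(self) -> float:
        return self.u_dpd + self.u_bond


def _scatter(forces: np.ndarray, i: np.ndarray, j: np.ndarray,
             f: np.ndarray, e: np.ndarray) -> None:
    """Add f*e to particle i and -f*e to particle j, per component."""
    n = forces.shape[0]
    for ax in range(3):
        comp = f * e[:, ax]
        forces[:, ax] += np.bincount(i, weights=comp, minlength=n)
        forces[:, ax] -= np.bincount(j, weights=comp, minlength=n)


def _pair_virial(f: np.ndarray, r: np.ndarray, e: np.ndarray) -> np.ndarray:
    # r_alpha * F_alpha for a central pair force f along e: f * r * e_alpha^2
    return np.einsum("k,ka,ka->a", f * r, e, e)


def conservative_dpd(cache: PairCache, interactions: InteractionMatrix,
                     type_index: np.ndarray, forces: np.ndarray):
    """Soft repulsion a_ij (1 - r) along the pair axis.

    Adds the force for every cached pair and returns (U, virial) where the
    pair potential is the integral of the force, a_ij (1 - r)^2 / 2.
    """
    if type_index.max(initial=-1) >= interactions.n_types:
        raise ParameterError("type index outside the interaction matrix")
    if len(cache) == 0:
        return 0.0, np.zeros(3)
    aij = interactions.a[type_index[cache.i], type_index[cache.j]]
    w = 1.0 - cache.r
    f = aij * w
    _scatter(forces, cache.i, cache.j, f, cache.e)
    u = float((aij * w * w).sum() / 2.0)
    return u, _pair_virial(f, cache.r, cache.e)


def bond_forces(bonds: dict, positions: np.ndarray, box,
                forces: np.ndarray):
    """Harmonic springs -k (r - r0) along the bond axis; no cutoff.

    Topological and backbone bonds are treated identically.  Minimum image
    on periodic axes.  Returns (U, virial).
    """
    bi, bj = bonds["i"], bonds["j"]
    if bi.shape[0] == 0:
        return 0.0, np.zeros(3)
    d = positions[bi] - positions[bj]
    L = box.lengths
    for ax in range(3):
        if box.periodic[ax]:
            d[:, ax] -= L[ax] * np.rint(d[:, ax] / L[ax])
    r = np.sqrt((d * d).sum(axis=1))
    bad = (r == 0) & (bonds["r0"] > 0)
    if np.any(bad):
        k = int(np.nonzero(bad)[0][0])
        raise DivergenceError(
            f"bond ({bi[k]}, {bj[k]}) has zero length but nonzero rest "
            f"length: the restoring direction is undefined")
    with np.errstate(invalid="ignore"):
        e = np.where(r[:, None] > 0, d / np.where(r == 0, 1, r)[:, None], 0.0)
    stretch = r - bonds["r0"]
    f = -bonds["k"] * stretch
    _scatter(forces, bi, bj, f, e)
    u = float((bonds["k"] * stretch * stretch).sum() / 2.0)
    return u, _pair_virial(f, r, e)


def dissipative_forces(cache: PairCache, velocities: np.ndarray,
                       gamma: float, forces: np.ndarray):
    """Pairwise friction -gamma omega_D(r) (e . v_ij) e.

    Opposes the projection of the relative velocity on the pair axis;
    returns the virial contribution.
    """
    if len(cache) == 0:
        return np.zeros(3)
    vij = velocities[cache.i] - velocities[cache.j]
    proj = (vij * cache.e).sum(axis=1)
    f = -gamma * omega_d(cache.r) * proj
    _scatter(forces, cache.i, cache.j, f, cache.e)
    return _pair_virial(f, cache.r, cache.e)


def random_forces(cache: PairCache, sigma: float, dt: float,
                  noise: NoiseStream, step: int, forces: np.ndarray,
                  substep: int = 0):
    """Pairwise noise sigma omega_R(r) zeta_ij / sqrt(dt) e.

    One keyed variate per pair and step (symmetric within the pair), so
    the draw is reproducible for any traversal order and on replay.
    Returns the virial contribution.
    """
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    if len(cache) == 0 or sigma == 0.0:
        return np.zeros(3)
    zeta = noise.pair_zeta(step, substep, cache.i, cache.j)
    f = sigma * omega_r(cache.r) * zeta / np.sqrt(dt)
    _scatter(forces, cache.i, cache.j, f, cache.e)
    return _pair_virial(f, cache.r, cache.e)


def gravity_forces(masses: np.ndarray, g: np.ndarray, forces: np.ndarray,
                   free_mask: Optional[np.ndarray] = None) -> None:
    """External acceleration acting on particle masses (F = m g).

    Position-fixed particles can be excluded via ``free_mask``.  An
    external field does not conserve total momentum.
    """
    contrib = masses[:, None] * np.asarray(g, dtype=np.float64)[None, :]
    if free_mask is not None:
        contrib = np.where(free_mask[:, None], contrib, 0.0)
    forces += contrib


def color_bonds(bonds: dict, n_particles: int):
    """Greedy coloring of the bond graph into parallel-safe chunks.

    Bonds of one color share no particle, so their accumulations never
    touch the same force slot — the bond-level analogue of the cell chunk
    schedule.  Returns an int color per bond.
    """
    bi, bj = bonds["i"], bonds["j"]
    color = np.full(bi.shape[0], -1, dtype=np.int64)
    used_until: list = []    # per color: set of particles already claimed
    order = np.lexsort((bj, bi))
    for k in order:
        a, b = int(bi[k]), int(bj[k])
        for col, claimed in enumerate(used_until):
            if a not in claimed and b not in claimed:
                color[k] = col
                claimed.add(a)
                claimed.add(b)
                break
        else:
            color[k] = len(used_until)
            used_until.append({a, b})
    return color


def compute_all_forces(state, fieldspec: ForceField, cache: PairCache,
                       schedule=None, threads: int = 1, step: int = 0,
                       substep: int = 0,
                       include=("conservative", "bond", "dissipative",
                                "random", "gravity"),
                       velocities: Optional[np.ndarray] = None,
                       free_mask: Optional[np.ndarray] = None) -> ForceResult:
    """Assemble the total force for one evaluation point.

    forces = soft repulsion + bonds + friction + noise + gravity.  The
    ``include`` tuple lets integrators evaluate sub-sums (e.g. the
    conservative part only, or a dissipative-only re-evaluation against
    corrected velocities reusing the same cache).  ``velocities`` defaults
    to ``state.velocities``.
    """
    res = ForceResult(forces=np.zeros_like(state.positions))
    th = fieldspec.thermostat
    if "conservative" in include:
        u, vir = conservative_dpd(cache, fieldspec.interactions,
                                  state.type_index, res.forces)
        res.u_dpd += u
        res.virial += vir
    if "bond" in include:
        u, vir = bond_forces(fieldspec.bonds, state.positions,
                             fieldspec.box, res.forces)
        res.u_bond += u
        res.virial += vir
    if "dissipative" in include and th.gamma > 0:
        v = state.velocities if velocities is None else velocities
        res.virial += dissipative_forces(cache, v, th.gamma, res.forces)
    if "random" in include and th.sigma > 0:
        res.virial += random_forces(cache, th.sigma, th.dt, fieldspec.noise,
                                    step, res.forces, substep=substep)
    if "gravity" in include and np.any(fieldspec.gravity != 0):
        gravity_forces(state.masses, fieldspec.gravity, res.forces,
                       free_mask=free_mask)
    return res


from .factory import FORCE_TERMS

# the "estat" slot is the reserved extension hook for an electrostatics
# model; registering a calculator there makes compute_all_forces users
# able to opt into it without engine changes
FORCE_TERMS.register("conservative", conservative_dpd)
FORCE_TERMS.register("bond", bond_forces)
FORCE_TERMS.register("dissipative", dissipative_forces)
FORCE_TERMS.register("random", random_forces)
FORCE_TERMS.register("gravity", gravity_forces)

__all__ = [
    "ForceField", "ForceResult", "omega_r", "omega_d",
    "conservative_dpd", "bond_forces", "dissipative_forces", "random_forces",
    "gravity_forces", "compute_all_forces", "color_bonds",
]
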