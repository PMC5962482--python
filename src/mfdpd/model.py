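"""Domain types, reduced-unit conventions and system assembly.

The kernel works in reduced DPD units throughout: the pair-interaction
cutoff defines the unit of length (``r_c = 1``), the target thermal energy
defines the unit of energy (``k_B T = 1`` by default) and the reference
particle mass is 1 (per-type masses may still differ).  A "particle" is a
molecular fragment — a small molecule of roughly 100 Da — and larger
molecules are chains of fragments joined by harmonic springs.

The central containers are

``ParticleState``
    per-particle arrays (positions, velocities, forces, masses, type and
    molecule indices, periodic-image counters),
``SystemSpec``
    the full declarative description of a simulation (box, particle types,
    repulsion matrix, molecule descriptions, run configuration), and
``build_system``
    which expands a ``SystemSpec`` into a concrete ``ParticleState`` plus a
    flat bond table.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import GeometryError, ParameterError

#: The DPD pair-interaction cutoff in reduced units.  It is the unit of
#: length by construction and is not configurable.
CUTOFF = 1.0

_FIXATION_KINDS = ("none", "position", "velocity")
_BOUNDARY_MODES = ("periodic", "reflective")


# ---------------------------------------------------------------------------
# particle state
# ---------------------------------------------------------------------------

@dataclass
class ParticleState:
    """Structure-of-arrays container for all per-particle data.

    Positions are wrapped coordinates in ``[0, L_axis)``; ``images`` counts
    how many times each particle crossed each periodic face so that
    unwrapped coordinates (needed e.g. for radii of gyration) are always
    recoverable as ``positions + images * L``.

    Charges are parsed and carried but exert no force; they are an
    extension hook for an electrostatics model.
    """

    positions: np.ndarray       # (N, 3) float64
    velocities: np.ndarray      # (N, 3) float64
    forces: np.ndarray          # (N, 3) float64, rewritten every step
    masses: np.ndarray          # (N,)  float64, > 0
    type_index: np.ndarray      # (N,)  int64 into the particle-type table
    molecule_index: np.ndarray  # (N,)  int64, molecule instance id
    molecule_type: np.ndarray   # (N,)  int64 into the molecule descriptions
    charge: np.ndarray          # (N,)  float64, carried but unused
    images: np.ndarray          # (N, 3) int64 periodic image counters

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def unwrapped_positions(self, box: "BoxGeometry") -> np.ndarray:
        return self.positions + self.images * box.lengths[None, :]

    def copy(self) -> "ParticleState":
        return ParticleState(*(getattr(self, f).copy() for f in (
            "positions", "velocities", "forces", "masses", "type_index",
            "molecule_index", "molecule_type", "charge", "images")))

    def validate(self, box: Optional["BoxGeometry"] = None) -> None:
        n = self.n
        for name in ("positions", "velocities", "forces", "images"):
            if getattr(self, name).shape != (n, 3):
                raise ParameterError(f"{name} must have shape ({n}, 3)")
        for name in ("masses", "type_index", "molecule_index",
                     "molecule_type", "charge"):
            if getattr(self, name).shape != (n,):
                raise ParameterError(f"{name} must have shape ({n},)")
        if np.any(self.masses <= 0):
            raise ParameterError("all particle masses must be > 0")
        if not np.all(np.isfinite(self.positions)):
            raise ParameterError("positions must be finite")
        if box is not None:
            lo = self.positions < 0
            hi = self.positions >= box.lengths[None, :]
            if np.any(lo | hi):
                bad = int(np.nonzero((lo | hi).any(axis=1))[0][0])
                raise ParameterError(
                    f"particle {bad} lies outside the box: "
                    f"{self.positions[bad]}")


@dataclass(frozen=True)
class BoxGeometry:
    """Orthorhombic simulation box with per-axis boundary modes.

    Every axis must be at least ``3 * cutoff`` long so that the cell grid
    has at least three cells per axis — the condition for each cell to own
    26 distinct neighbor cells and for the chunk schedule to exist.
    """

    lengths: np.ndarray                       # (3,) float64, > 0
    boundary_modes: tuple = ("periodic", "periodic", "periodic")

    def __post_init__(self):
        object.__setattr__(self, "lengths",
                           np.asarray(self.lengths, dtype=np.float64))
        if self.lengths.shape != (3,) or np.any(self.lengths <= 0):
            raise ParameterError("box lengths must be three positive numbers")
        if len(self.boundary_modes) != 3 or any(
                m not in _BOUNDARY_MODES for m in self.boundary_modes):
            raise ParameterError(
                f"boundary modes must be three of {_BOUNDARY_MODES}")
        if np.any(self.lengths < 3.0 * CUTOFF):
            raise GeometryError(
                f"every box axis must be >= {3.0 * CUTOFF} (3 cutoffs); "
                f"got {tuple(self.lengths)}")

    @property
    def periodic(self) -> np.ndarray:
        """Boolean mask of periodic axes."""
        return np.array([m == "periodic" for m in self.boundary_modes])

    @property
    def volume(self) -> float:
        return float(np.prod(self.lengths))


@dataclass(frozen=True)
class InteractionMatrix:
    """Symmetric matrix of maximum repulsion parameters ``a_ij >= 0``.

    ``a[i, j]`` is the strength of the soft conservative repulsion between
    particle types ``i`` and ``j``; the common water-like default in DPD at
    density 3 is ``a = 25``.
    """

    a: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.a, dtype=np.float64)
        object.__setattr__(self, "a", a)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ParameterError("interaction matrix must be square")
        if not np.allclose(a, a.T):
            raise ParameterError("interaction matrix must be symmetric")
        if np.any(a < 0):
            raise ParameterError("repulsion parameters a_ij must be >= 0")

    @property
    def n_types(self) -> int:
        return self.a.shape[0]


@dataclass(frozen=True)
class Bond:
    """Harmonic spring between two particles.

    ``kind`` records whether the bond encodes covalent connectivity
    ("topological") or maintains a 3D structure such as a ring or a protein
    backbone ("backbone"); both kinds are treated identically in every
    force evaluation.
    """

    i: int
    j: int
    k_bond: float
    r_bond: float
    kind: str = "topological"

    def __post_init__(self):
        if self.i == self.j:
            raise ParameterError("a bond must join two distinct particles")
        if self.i < 0 or self.j < 0:
            raise ParameterError("bond indices must be non-negative")
        if self.k_bond < 0 or self.r_bond < 0:
            raise ParameterError("k_bond and r_bond must be >= 0")
        if self.kind not in ("topological", "backbone"):
            raise ParameterError(f"unknown bond kind {self.kind!r}")


@dataclass(frozen=True)
class MoleculeDescription:
    """Template for one molecule species.

    ``particle_type_sequence`` lists the fragment types of one molecule
    copy in order; bond templates index into that sequence.  ``boundary``
    optionally confines every particle of every copy to an axis-aligned
    sub-box by reflective virtual walls, given as
    ``((x0, x1), (y0, y1), (z0, z1))``.  ``force_kick`` optionally applies
    a constant force vector to every particle of the species every
    ``period`` steps to smoothly drive the molecules in a direction.
    """

    name: str
    particle_type_sequence: tuple
    topological_bonds: tuple = ()
    backbone_bonds: tuple = ()
    copy_count: int = 1
    fixation: str = "none"
    boundary: Optional[tuple] = None
    force_kick: Optional[tuple] = None   # ((fx, fy, fz), period)
    placement: str = "random"            # random | lattice

    def __post_init__(self):
        if len(self.particle_type_sequence) == 0:
            raise ParameterError(f"molecule {self.name!r} has no particles")
        if self.copy_count < 1:
            raise ParameterError("copy_count must be >= 1")
        if self.fixation not in _FIXATION_KINDS:
            raise ParameterError(
                f"fixation must be one of {_FIXATION_KINDS}")
        size = len(self.particle_type_sequence)
        for b in self.topological_bonds + self.backbone_bonds:
            if not (0 <= b.i < size and 0 <= b.j < size):
                raise ParameterError(
                    f"molecule {self.name!r}: bond ({b.i}, {b.j}) indexes "
                    f"outside the {size}-particle template")
        if self.force_kick is not None:
            vec, period = self.force_kick
            if len(vec) != 3 or int(period) < 1:
                raise ParameterError("force_kick is ((fx,fy,fz), period>=1)")

    @property
    def size(self) -> int:
        return len(self.particle_type_sequence)

    @property
    def bonds(self) -> tuple:
        return self.topological_bonds + self.backbone_bonds


@dataclass
class ThermostatParams:
    """Fluctuation-dissipation-consistent thermostat triple.

    Only the noise amplitude ``sigma`` and the thermal energy ``kBT`` are
    free; the friction coefficient is always derived as
    ``gamma = sigma**2 / (2 * kBT)`` so that the canonical (NVT) ensemble
    is sampled.  ``gamma`` is a read-only property and can never drift out
    of step with (sigma, kBT).
    """

    sigma: float = 3.0
    kBT: float = 1.0
    dt: float = 0.04

    def __post_init__(self):
        if self.kBT <= 0:
            raise ParameterError("kBT must be > 0")
        if self.sigma < 0:
            raise ParameterError("sigma must be >= 0")
        if self.dt <= 0:
            raise ParameterError("dt must be > 0")

    @property
    def gamma(self) -> float:
        return derive_friction(self.sigma, self.kBT)


SCHEMES = ("GWMVV", "SCMVV", "DPDMVV", "S1MVV", "PNHLN")


@dataclass
class IntegratorConfig:
    """Selection and tuning of the time-stepping scheme.

    ``lam`` is the Groot-Warren velocity-prediction parameter (0.5 makes
    GWMVV coincide with plain velocity-Verlet); ``n_self_consistent`` is
    the number of dissipative-force iterations of SCMVV (1 makes SCMVV the
    DPDMVV variant by definition); ``coupling`` is the control gain of the
    pairwise Nose-Hoover-Langevin thermostat.
    """

    scheme: str = "GWMVV"
    lam: float = 0.65
    n_self_consistent: int = 5
    coupling: float = 1.0

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ParameterError(
                f"unknown scheme {self.scheme!r}; valid: {', '.join(SCHEMES)}")
        if not (0.0 < self.lam <= 1.0):
            raise ParameterError("lambda must be in (0, 1]")
        if self.n_self_consistent < 1:
            raise ParameterError("n_self_consistent must be >= 1")
        if self.coupling <= 0:
            raise ParameterError("coupling must be > 0")


@dataclass
class SimulationConfig:
    """Everything about a run that is not geometry or chemistry."""

    steps: int = 0
    output_every: int = 1
    thermostat: ThermostatParams = field(default_factory=ThermostatParams)
    integrator: IntegratorConfig = field(default_factory=IntegratorConfig)
    gravity: np.ndarray = field(
        default_factory=lambda: np.zeros(3))
    rng_kind: str = "uniform"
    seed: int = 0
    velocity_scaling: int = 0      # 0 = off, k = rescale every k steps
    minimization_steps: int = 0
    parallel_threads: int = 1

    def __post_init__(self):
        self.gravity = np.asarray(self.gravity, dtype=np.float64)
        if self.gravity.shape != (3,):
            raise ParameterError("gravity must be a 3-vector")
        if self.steps < 0:
            raise ParameterError("steps must be >= 0")
        if self.output_every < 1:
            raise ParameterError("output_every must be >= 1")
        if self.velocity_scaling < 0:
            raise ParameterError("velocity_scaling must be >= 0")
        if self.minimization_steps < 0:
            raise ParameterError("minimization_steps must be >= 0")
        if self.parallel_threads < 1:
            raise ParameterError("parallel_threads must be >= 1")


@dataclass
class SystemSpec:
    """Declarative description of a complete simulation.

    ``type_names``, ``type_masses`` and ``type_charges`` form the particle
    type table; ``interactions`` is indexed by positions in that table.
    """

    box: BoxGeometry
    type_names: Sequence[str]
    interactions: InteractionMatrix
    molecules: Sequence[MoleculeDescription]
    config: SimulationConfig
    type_masses: Optional[Sequence[float]] = None
    type_charges: Optional[Sequence[float]] = None

    def __post_init__(self):
        nt = len(self.type_names)
        if self.type_masses is None:
            self.type_masses = [1.0] * nt
        if self.type_charges is None:
            self.type_charges = [0.0] * nt
        if self.interactions.n_types != nt:
            raise ParameterError(
                f"interaction matrix is {self.interactions.n_types}x"
                f"{self.interactions.n_types} but {nt} types are declared")
        if any(m <= 0 for m in self.type_masses):
            raise ParameterError("type masses must be > 0")
        name_of = {}
        for m in self.molecules:
            for t in m.particle_type_sequence:
                if not (0 <= t < nt):
                    raise ParameterError(
                        f"molecule {m.name!r} references unknown type {t}")
            if m.name in name_of:
                raise ParameterError(f"duplicate molecule name {m.name!r}")
            name_of[m.name] = m

    def digest(self) -> str:
        """Stable hash of the full configuration, for restart validation."""
        def enc(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            if hasattr(o, "__dict__"):
                return {k: enc(v) for k, v in vars(o).items()}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            if isinstance(o, dict):
                return {k: enc(v) for k, v in o.items()}
            return o
        blob = json.dumps(enc(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def derive_friction(sigma: float, kBT: float) -> float:
    """Friction coefficient from the fluctuation-dissipation relation.

    gamma = sigma^2 / (2 kBT): dissipative (frictional) and random pair
    forces oppose each other and only this ratio samples the canonical
    ensemble at thermal energy ``kBT``.
    """
    if kBT <= 0:
        raise ParameterError("kBT must be > 0")
    if sigma < 0:
        raise ParameterError("sigma must be >= 0")
    return sigma * sigma / (2.0 * kBT)


def _expand_bonds(molecules, starts) -> dict:
    """Expand per-molecule bond templates over all copies into flat arrays."""
    bi, bj, bk, br = [], [], [], []
    kinds = []
    for mi, mol in enumerate(molecules):
        for start in starts[mi]:
            for b in mol.bonds:
                bi.append(start + b.i)
                bj.append(start + b.j)
                bk.append(b.k_bond)
                br.append(b.r_bond)
                kinds.append(b.kind)
    return {
        "i": np.asarray(bi, dtype=np.int64),
        "j": np.asarray(bj, dtype=np.int64),
        "k": np.asarray(bk, dtype=np.float64),
        "r0": np.asarray(br, dtype=np.float64),
        "kind": np.asarray(kinds, dtype=object),
    }


def _place_molecule(mol, box, rng):
    """Initial coordinates for one molecule copy.

    Single particles are placed uniformly; chains grow as random walks with
    step length r_bond (or half a cutoff when a bond has zero rest length)
    from a uniformly placed head, so bonded neighbors start near their
    equilibrium separation.  Coordinates are wrapped into the box.
    """
    size = mol.size
    pos = np.empty((size, 3))
    lo = np.zeros(3)
    span = box.lengths.copy()
    if mol.boundary is not None:
        b = np.asarray(mol.boundary, dtype=np.float64)
        lo = b[:, 0]
        span = b[:, 1] - b[:, 0]
    pos[0] = lo + rng.random(3) * span
    if size > 1:
        step_of = {}
        for b in mol.bonds:
            step_of[(b.i, b.j)] = b.r_bond if b.r_bond > 0 else 0.5
            step_of[(b.j, b.i)] = b.r_bond if b.r_bond > 0 else 0.5
        for k in range(1, size):
            step = step_of.get((k - 1, k), 0.5)
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            pos[k] = pos[k - 1] + step * u
    pos %= box.lengths[None, :]
    if mol.boundary is not None:
        b = np.asarray(mol.boundary, dtype=np.float64)
        pos = np.clip(pos, b[:, 0], b[:, 1] - 1e-9)
    return pos


def _lattice_points(count, box, rng):
    """Approximately uniform lattice of ``count`` anchor points."""
    per_axis = int(np.ceil(count ** (1.0 / 3.0)))
    axes = [(np.arange(per_axis) + 0.5) * L / per_axis for L in box.lengths]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    sel = rng.permutation(grid.shape[0])[:count]
    return grid[sel]


def build_system(spec: SystemSpec):
    """Instantiate particles and bonds from a system description.

    Expands every molecule description over its copy count, places the
    copies (random-walk or lattice anchored), expands bond templates, and
    draws initial velocities from a Maxwell-Boltzmann distribution at the
    target ``kBT`` with the net momentum removed.  Deterministic given
    (spec, spec.config.seed).

    Returns
    -------
    (ParticleState, bonds) where ``bonds`` is a dict of flat arrays
    ``i, j, k, r0, kind``.
    """
    if len(spec.molecules) == 0:
        raise ParameterError("system contains no molecules")
    rng = np.random.default_rng(np.random.SeedSequence(
        [spec.config.seed & 0x7FFFFFFF, 0xB111D]))
    box = spec.box

    n_total = sum(m.size * m.copy_count for m in spec.molecules)
    positions = np.empty((n_total, 3))
    type_index = np.empty(n_total, dtype=np.int64)
    molecule_index = np.empty(n_total, dtype=np.int64)
    molecule_type = np.empty(n_total, dtype=np.int64)

    starts = []          # per description: list of first-particle offsets
    offset = 0
    mol_id = 0
    for mi, mol in enumerate(spec.molecules):
        anchors = None
        if mol.placement == "lattice":
            anchors = _lattice_points(mol.copy_count, box, rng)
        mol_starts = []
        seq = np.asarray(mol.particle_type_sequence, dtype=np.int64)
        for c in range(mol.copy_count):
            pos = _place_molecule(mol, box, rng)
            if anchors is not None:
                pos = (pos - pos[0] + anchors[c]) % box.lengths[None, :]
            sl = slice(offset, offset + mol.size)
            positions[sl] = pos
            type_index[sl] = seq
            molecule_index[sl] = mol_id
            molecule_type[sl] = mi
            mol_starts.append(offset)
            offset += mol.size
            mol_id += 1
        starts.append(mol_starts)

    bonds = _expand_bonds(spec.molecules, starts)

    masses = np.asarray(spec.type_masses, dtype=np.float64)[type_index]
    charge = np.asarray(spec.type_charges, dtype=np.float64)[type_index]

    kBT = spec.config.thermostat.kBT
    velocities = rng.normal(size=(n_total, 3)) * np.sqrt(kBT / masses)[:, None]
    # remove net momentum so the center of mass is at rest
    p_net = (masses[:, None] * velocities).sum(axis=0)
    velocities -= p_net / masses.sum()

    state = ParticleState(
        positions=positions,
        velocities=velocities,
        forces=np.zeros((n_total, 3)),
        masses=masses,
        type_index=type_index,
        molecule_index=molecule_index,
        molecule_type=molecule_type,
        charge=charge,
        images=np.zeros((n_total, 3), dtype=np.int64),
    )
    state.validate(box)
    return state, bonds


def check_density_safeguards(state: ParticleState, box: BoxGeometry,
                             low: float = 0.25, high: float = 4.0):
    """Warn about unphysical local particle densities in a start geometry.

    The box is divided into blocks of edge >= 2 cutoffs (coarse enough
    that Poisson occupancy fluctuations of a healthy uniform fluid stay
    inside the band) and any block whose occupancy falls outside
    ``[low, high]`` times the global mean is reported.  Never mutates the
    state; returns a list of human-readable warnings.
    """
    if state.n == 0:
        return []
    n_blocks = np.maximum(1, np.floor(box.lengths / (2.0 * CUTOFF))).astype(int)
    size = box.lengths / n_blocks
    idx = np.minimum((state.positions / size).astype(np.int64), n_blocks - 1)
    flat = (idx[:, 0] * n_blocks[1] + idx[:, 1]) * n_blocks[2] + idx[:, 2]
    counts = np.bincount(flat, minlength=int(np.prod(n_blocks)))
    mean = state.n / counts.size
    warnings = []
    for b in np.nonzero((counts < low * mean) | (counts > high * mean))[0]:
        bx, rem = divmod(int(b), int(n_blocks[1] * n_blocks[2]))
        by, bz = divmod(rem, int(n_blocks[2]))
        warnings.append(
            f"block ({bx},{by},{bz}) holds {counts[b]} particles "
            f"(global mean {mean:.2f} per block): unphysical "
            f"{'low' if counts[b] < low * mean else 'high'} local density")
    return warnings


__all__ = [
    "CUTOFF", "ParticleState", "BoxGeometry", "InteractionMatrix", "Bond",
    "MoleculeDescription", "ThermostatParams", "IntegratorConfig",
    "SimulationConfig", "SystemSpec", "SCHEMES",
    "derive_friction", "build_system", "check_density_safeguards",
]
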