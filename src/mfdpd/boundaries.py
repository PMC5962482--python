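"""Periodic wrapping, reflective walls, molecule confinement, fixation, kicks.

Applied after every position update inside a step.  Periodic wrapping
keeps wrapped coordinates in [0, L) while the per-particle image counters
preserve the unwrapped trajectory for wrap-independent observables.
Reflective walls are elastic (specular): the coordinate is mirrored about
the wall plane and the normal velocity component negated, so reflection
preserves speed and kinetic energy exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import DivergenceError
from .model import BoxGeometry, ParticleState


@dataclass
class ConstraintSet:
    """Per-run constraints derived from the molecule descriptions.

    ``sub_boxes`` maps a molecule-type index to an axis-aligned
    ``(3, 2)`` array of reflective virtual walls; ``fixation`` maps a
    molecule-type index to "position" or "velocity"; ``kicks`` maps a
    molecule-type index to ``(force_vector, period)``.  Snapshots for
    fixation are taken by ``freeze_reference``.
    """

    sub_boxes: dict = field(default_factory=dict)
    fixation: dict = field(default_factory=dict)
    kicks: dict = field(default_factory=dict)
    _ref_positions: Optional[np.ndarray] = None
    _ref_velocities: Optional[np.ndarray] = None
    _ref_images: Optional[np.ndarray] = None

    @classmethod
    def from_molecules(cls, molecules, box: BoxGeometry) -> "ConstraintSet":
        cs = cls()
        for mi, mol in enumerate(molecules):
            if mol.boundary is not None:
                b = np.asarray(mol.boundary, dtype=np.float64)
                if np.any(b[:, 0] < 0) or np.any(b[:, 1] > box.lengths) \
                        or np.any(b[:, 0] >= b[:, 1]):
                    raise DivergenceError(
                        f"molecule {mol.name!r}: sub-box walls must lie "
                        f"inside the simulation box")
                cs.sub_boxes[mi] = b
            if mol.fixation != "none":
                cs.fixation[mi] = mol.fixation
            if mol.force_kick is not None:
                vec, period = mol.force_kick
                cs.kicks[mi] = (np.asarray(vec, dtype=np.float64), int(period))
        return cs

    def freeze_reference(self, state: ParticleState) -> None:
        """Snapshot positions/velocities that fixation will restore."""
        if self.fixation:
            self._ref_positions = state.positions.copy()
            self._ref_velocities = state.velocities.copy()
            self._ref_images = state.images.copy()

    def position_fixed_mask(self, state: ParticleState) -> np.ndarray:
        mask = np.zeros(state.n, dtype=bool)
        for mi, kind in self.fixation.items():
            if kind == "position":
                mask |= state.molecule_type == mi
        return mask

    def fixed_mask(self, state: ParticleState) -> np.ndarray:
        """Particles whose velocity is constrained (position or velocity
        fixation) — excluded from the kinetic temperature."""
        mask = np.zeros(state.n, dtype=bool)
        for mi in self.fixation:
            mask |= state.molecule_type == mi
        return mask


def apply_periodic(state: ParticleState, box: BoxGeometry) -> None:
    """Wrap coordinates on periodic axes into [0, L), tracking images."""
    pos = state.positions
    if not np.all(np.isfinite(pos)):
        bad = int(np.nonzero(~np.isfinite(pos).all(axis=1))[0][0])
        raise DivergenceError(
            f"particle {bad} has a non-finite coordinate; the integration "
            f"diverged (consider a smaller time step)")
    L = box.lengths
    for ax in range(3):
        if not box.periodic[ax]:
            continue
        x = pos[:, ax]
        wrapped = np.remainder(x, L[ax])
        # the sign adjustment inside remainder can round up to exactly L:
        # that point is 0 of the next periodic image
        on_edge = wrapped >= L[ax]
        shift = np.rint((x - wrapped) / L[ax]).astype(np.int64)
        if np.any(shift != 0) or np.any(on_edge):
            wrapped[on_edge] = 0.0
            shift[on_edge] += 1
            pos[:, ax] = wrapped
            state.images[:, ax] += shift


def _reflect_axis(pos, vel, ax, lo, hi, max_iter=16):
    moved = True
    it = 0
    while moved:
        moved = False
        below = pos[:, ax] < lo
        if np.any(below):
            pos[below, ax] = 2.0 * lo - pos[below, ax]
            vel[below, ax] = -vel[below, ax]
            moved = True
        above = pos[:, ax] > hi
        if np.any(above):
            pos[above, ax] = 2.0 * hi - pos[above, ax]
            vel[above, ax] = -vel[above, ax]
            moved = True
        it += 1
        if it > max_iter:
            raise DivergenceError(
                "a particle crossed a reflective wall more times than can "
                "be resolved in one step; the integration diverged")


def apply_reflective(state: ParticleState, box: BoxGeometry,
                     constraints: Optional[ConstraintSet] = None) -> None:
    """Mirror particles at reflective box walls and molecule sub-boxes.

    Multiple reflections within one step are resolved iteratively.  For a
    molecule sub-box every member particle is reflected individually.
    """
    span = box.lengths
    for ax in range(3):
        if not box.periodic[ax]:
            if np.any(np.abs(state.positions[:, ax] - span[ax] / 2)
                      > 1.5 * span[ax]):
                raise DivergenceError(
                    f"a particle moved more than a box length on axis {ax} "
                    f"in one step")
            _reflect_axis(state.positions, state.velocities, ax,
                          0.0, np.nextafter(span[ax], 0.0))
    if constraints is not None:
        for mi, walls in constraints.sub_boxes.items():
            sel = state.molecule_type == mi
            if not np.any(sel):
                continue
            pos = state.positions[sel]
            vel = state.velocities[sel]
            for ax in range(3):
                _reflect_axis(pos, vel, ax, walls[ax, 0],
                              np.nextafter(walls[ax, 1], walls[ax, 0]))
            state.positions[sel] = pos
            state.velocities[sel] = vel


def apply_boundaries(state: ParticleState, box: BoxGeometry,
                     constraints: Optional[ConstraintSet] = None) -> None:
    """Reflect first (walls see the raw overshoot), then wrap periodic axes."""
    apply_reflective(state, box, constraints)
    apply_periodic(state, box)


def apply_fixation(state: ParticleState,
                   constraints: Optional[ConstraintSet]) -> None:
    """Restore fixed molecules to their frozen snapshot.

    Position fixation pins coordinates and zeroes forces and velocities;
    velocity fixation restores the velocity each step while positions
    advance freely.  Fixation is exact, not approximate.
    """
    if constraints is None or not constraints.fixation:
        return
    for mi, kind in constraints.fixation.items():
        sel = state.molecule_type == mi
        if kind == "position":
            state.positions[sel] = constraints._ref_positions[sel]
            state.images[sel] = constraints._ref_images[sel]
            state.velocities[sel] = 0.0
            state.forces[sel] = 0.0
        else:
            state.velocities[sel] = constraints._ref_velocities[sel]


def apply_force_kicks(state: ParticleState,
                      constraints: Optional[ConstraintSet],
                      step: int, forces: np.ndarray) -> None:
    """Add periodic driving forces to kicked molecule types.

    On steps where ``step % period == 0`` the kick vector is added to the
    force of every particle of the molecule type, smoothly driving those
    molecules in the kick direction.
    """
    if constraints is None or not constraints.kicks:
        return
    for mi, (vec, period) in constraints.kicks.items():
        if step % period == 0:
            forces[state.molecule_type == mi] += vec[None, :]


__all__ = [
    "ConstraintSet", "apply_periodic", "apply_reflective",
    "apply_boundaries", "apply_fixation", "apply_force_kicks",
]
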