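"""Slow, independent reference implementations used as validation oracles.

Everything here deliberately bypasses the production machinery: pairs come
from the O(N^2) all-pairs scan (no cell grid, no chunk schedule, no
cache), and the velocity-Verlet stepper below is written directly from
the textbook update equations rather than through the scheme registry.
Only the keyed noise stream is shared, so a reference trajectory can be
driven by bit-identical random forces.

These functions are for testing and cross-validation; they scale
quadratically and are not part of the simulation engine.
"""

from __future__ import annotations

import numpy as np

from .forces import omega_d, omega_r
from .model import BoxGeometry
from .neighbors import brute_force_pairs
from .noise import NoiseStream


def reference_forces(positions, velocities, type_index, interactions,
                     box: BoxGeometry, sigma: float, gamma: float, dt: float,
                     noise: NoiseStream, step: int):
    """Total DPD pair force (repulsion + friction + noise) by brute force."""
    n = positions.shape[0]
    i, j, r, e = brute_force_pairs(positions, box)
    aij = interactions.a[type_index[i], type_index[j]]
    f = aij * omega_r(r)
    if gamma > 0:
        vij = velocities[i] - velocities[j]
        f = f - gamma * omega_d(r) * (vij * e).sum(axis=1)
    if sigma > 0:
        zeta = noise.pair_zeta(step, 0, i, j)
        f = f + sigma * omega_r(r) * zeta / np.sqrt(dt)
    forces = np.zeros_like(positions)
    for ax in range(3):
        comp = f * e[:, ax]
        forces[:, ax] += np.bincount(i, weights=comp, minlength=n)
        forces[:, ax] -= np.bincount(j, weights=comp, minlength=n)
    return forces


def reference_vv_trajectory(positions, velocities, masses, type_index,
                            interactions, box: BoxGeometry, sigma: float,
                            kBT: float, dt: float, n_steps: int, seed: int,
                            noise_kind: str = "uniform"):
    """Plain velocity-Verlet with the velocity-dependent force evaluated at
    the half-kicked velocity.

    The canonical modified-VV formulation: a half kick, a drift, a force
    evaluation against the half-kicked velocity, and a closing half kick.
    Returns (positions, velocities) after ``n_steps``.
    """
    noise = NoiseStream(seed, noise_kind)
    gamma = sigma * sigma / (2.0 * kBT)
    pos = positions.copy()
    vel = velocities.copy()
    m = masses[:, None]
    f = reference_forces(pos, vel, type_index, interactions, box,
                         sigma, gamma, dt, noise, 0)
    for s in range(1, n_steps + 1):
        v_half = vel + 0.5 * dt * f / m
        pos = pos + dt * v_half
        pos %= box.lengths[None, :]
        f = reference_forces(pos, v_half, type_index, interactions, box,
                             sigma, gamma, dt, noise, s)
        vel = v_half + 0.5 * dt * f / m
    return pos, vel


__all__ = ["reference_forces", "reference_vv_trajectory"]
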