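"""Modified velocity-Verlet time stepping for DPD.

Because dissipative forces depend on relative particle velocities, plain
velocity-Verlet (VV) must be modified.  Four schemes are provided:

``GWMVV``
    the Groot-Warren scheme: positions advance with the old force, the
    force at the new positions is evaluated against a predicted velocity
    ``v + lambda dt F / m``, and the velocity corrector averages old and
    new forces.  At ``lambda = 0.5`` the scheme coincides with VV
    integration (with the velocity-dependent force taken at the
    half-kicked velocity).
``SCMVV``
    self-consistent VV: conservative + random forces are evaluated once at
    the new positions, then the dissipative contribution is re-evaluated a
    fixed number of times against successively corrected velocities,
    reusing the cached pair distances.  A single iteration is by
    definition the ``DPDMVV`` variant.
``S1MVV``
    Shardlow's S1 operator splitting: the fluctuation-dissipation part is
    integrated pair-by-pair (half explicit, half implicit, conserving each
    pair's momentum exactly), followed by plain VV on the conservative
    forces.
``PNHLN``
    a pairwise Nose-Hoover-Langevin thermostat: a single auxiliary
    friction variable ``xi`` is steered by the pairwise kinetic
    temperature control law

        dxi/dt = c * < omega_D(r) [ (e.v_ij)^2 - kBT (1/m_i + 1/m_j) ] >

    (mean over cached pairs, gain ``c`` = the coupling parameter), and the
    pair velocities are damped with friction ``xi`` plus a pairwise random
    kick whose amplitude is tied to ``xi`` by fluctuation-dissipation, so
    the sampled ensemble stays canonical for any ``xi >= 0``.  As the
    coupling tends to zero ``xi`` stays at zero and the dynamics reduce to
    the un-thermostatted conservative motion.

All schemes rebuild the pair cache whenever positions change and reuse it
for every force evaluation at those positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._kernels import _pnhl_sweep, _s1_sweep
from .boundaries import (ConstraintSet, apply_boundaries, apply_fixation,
                         apply_force_kicks)
from .errors import DivergenceError, ParameterError
from .factory import INTEGRATORS
from .forces import ForceField, ForceResult, compute_all_forces, omega_d
from .model import ParticleState, SimulationConfig, check_density_safeguards
from .neighbors import (CellGrid, ChunkSchedule, assign_particles,
                        build_cell_grid, build_chunk_schedule, enumerate_pairs)

_CONSERVATIVE = ("conservative", "bond", "gravity")
_ALL = ("conservative", "bond", "dissipative", "random", "gravity")


@dataclass
class StepContext:
    """Mutable per-run bookkeeping shared by the stepping functions."""

    grid: CellGrid
    schedule: ChunkSchedule
    config: SimulationConfig
    constraints: Optional[ConstraintSet] = None
    cache: object = None          # PairCache for the current positions
    forces: Optional[np.ndarray] = None   # stored force array F(t)
    force_result: Optional[ForceResult] = None
    step: int = 0
    xi: float = 0.0               # PNHLN auxiliary friction variable

    def refresh_cache(self, state: ParticleState) -> None:
        """Re-bin particles and re-enumerate within-cutoff pairs."""
        assign_particles(self.grid, state.positions)
        order = None
        if self.config.parallel_threads > 1:
            # traversal order is shuffled per group to exercise the
            # lock-free contract; results are independent of it
            rng = np.random.default_rng(
                (self.config.seed & 0xFFFF) ^ (self.step << 16))
            order = self.schedule.cell_order(rng)
        self.cache = enumerate_pairs(self.grid, state.positions,
                                     schedule=self.schedule,
                                     cell_order=order)


def _check_finite(state: ParticleState) -> None:
    if not np.all(np.isfinite(state.positions)):
        raise DivergenceError(
            "non-finite positions after update; reduce the time step")


def _half_kick(state, forces, dt):
    state.velocities += 0.5 * dt * forces / state.masses[:, None]


# ---------------------------------------------------------------------------
# schemes
# ---------------------------------------------------------------------------

def step_gwmvv(state: ParticleState, fieldspec: ForceField, ctx: StepContext,
               lam: Optional[float] = None) -> None:
    """One Groot-Warren MVV step; ``lam`` defaults to the configured value."""
    if lam is None:
        lam = ctx.config.integrator.lam
    if not (0.0 < lam <= 1.0):
        raise ParameterError("lambda must be in (0, 1]")
    dt = fieldspec.thermostat.dt
    m = state.masses[:, None]
    f_old = ctx.forces
    state.positions += dt * state.velocities + 0.5 * dt * dt * f_old / m
    _check_finite(state)
    apply_boundaries(state, fieldspec.box, ctx.constraints)
    v_old = state.velocities
    v_pred = v_old + lam * dt * f_old / m
    ctx.refresh_cache(state)
    res = compute_all_forces(state, fieldspec, ctx.cache, step=ctx.step,
                             velocities=v_pred,
                             free_mask=_free_mask(state, ctx))
    state.velocities = v_old + 0.5 * dt * (f_old + res.forces) / m
    ctx.forces = res.forces
    ctx.force_result = res


def step_scmvv(state: ParticleState, fieldspec: ForceField, ctx: StepContext,
               n_iter: Optional[int] = None) -> None:
    """One self-consistent MVV step (``n_iter = 1`` is exactly DPDMVV)."""
    if n_iter is None:
        n_iter = ctx.config.integrator.n_self_consistent
    if n_iter < 1:
        raise ParameterError("n_self_consistent must be >= 1")
    th = fieldspec.thermostat
    dt = th.dt
    m = state.masses[:, None]
    _half_kick(state, ctx.forces, dt)
    v_half = state.velocities.copy()
    state.positions += dt * v_half
    _check_finite(state)
    apply_boundaries(state, fieldspec.box, ctx.constraints)
    # walls may have flipped velocity components; keep those as the basis
    v_half = state.velocities.copy()
    ctx.refresh_cache(state)
    base = compute_all_forces(
        state, fieldspec, ctx.cache, step=ctx.step,
        include=("conservative", "bond", "random", "gravity"),
        free_mask=_free_mask(state, ctx))
    from .forces import dissipative_forces
    v_guess = v_half
    f_new = base.forces
    vir_d = np.zeros(3)
    for _ in range(n_iter):
        f_d = np.zeros_like(base.forces)
        vir_d = dissipative_forces(ctx.cache, v_guess, th.gamma, f_d)
        f_new = base.forces + f_d
        v_guess = v_half + 0.5 * dt * f_new / m
    state.velocities = v_guess
    ctx.forces = f_new
    ctx.force_result = ForceResult(forces=f_new, u_dpd=base.u_dpd,
                                   u_bond=base.u_bond,
                                   virial=base.virial + vir_d)


def step_dpdmvv(state, fieldspec, ctx) -> None:
    """DPDMVV: the single-iteration special case of SCMVV."""
    step_scmvv(state, fieldspec, ctx, n_iter=1)


def step_s1mvv(state: ParticleState, fieldspec: ForceField,
               ctx: StepContext) -> None:
    """One Shardlow-S1 step.

    First the pairwise fluctuation-dissipation sweep over the cache for
    the current positions, then a plain velocity-Verlet step on the
    conservative forces (``ctx.forces`` holds the conservative-only force
    for this scheme).
    """
    th = fieldspec.thermostat
    dt = th.dt
    cache = ctx.cache
    if th.gamma > 0 or th.sigma > 0:
        zeta = fieldspec.noise.pair_zeta(ctx.step, 0, cache.i, cache.j)
        _s1_sweep(cache.i, cache.j, cache.r, cache.e, state.velocities,
                  1.0 / state.masses, th.gamma, th.sigma, dt, zeta)
    _half_kick(state, ctx.forces, dt)
    state.positions += dt * state.velocities
    _check_finite(state)
    apply_boundaries(state, fieldspec.box, ctx.constraints)
    ctx.refresh_cache(state)
    res = compute_all_forces(state, fieldspec, ctx.cache, step=ctx.step,
                             include=_CONSERVATIVE,
                             free_mask=_free_mask(state, ctx))
    _half_kick(state, res.forces, dt)
    ctx.forces = res.forces
    ctx.force_result = res


def _pnhl_control(cache, velocities, inv_m, kBT) -> float:
    """Mean pairwise kinetic-temperature error, omega_D weighted."""
    if len(cache) == 0:
        return 0.0
    vij = velocities[cache.i] - velocities[cache.j]
    proj = (vij * cache.e).sum(axis=1)
    s = inv_m[cache.i] + inv_m[cache.j]
    g = omega_d(cache.r) * (proj * proj - kBT * s)
    return float(g.mean())


def step_pnhln(state: ParticleState, fieldspec: ForceField, ctx: StepContext,
               coupling: Optional[float] = None) -> None:
    """One pairwise Nose-Hoover-Langevin step (symmetric BACAB-like split)."""
    if coupling is None:
        coupling = ctx.config.integrator.coupling
    if coupling <= 0:
        raise ParameterError("coupling must be > 0")
    th = fieldspec.thermostat
    dt = th.dt
    inv_m = 1.0 / state.masses
    _half_kick(state, ctx.forces, dt)                       # B/2
    state.positions += 0.5 * dt * state.velocities          # A/2
    _check_finite(state)
    apply_boundaries(state, fieldspec.box, ctx.constraints)
    ctx.refresh_cache(state)
    cache = ctx.cache
    ctx.xi += 0.5 * dt * coupling * _pnhl_control(
        cache, state.velocities, inv_m, th.kBT)
    zeta = fieldspec.noise.pair_zeta(ctx.step, 1, cache.i, cache.j)
    _pnhl_sweep(cache.i, cache.j, cache.r, cache.e, state.velocities,
                inv_m, max(ctx.xi, 0.0), th.kBT, dt, zeta)
    ctx.xi += 0.5 * dt * coupling * _pnhl_control(
        cache, state.velocities, inv_m, th.kBT)
    state.positions += 0.5 * dt * state.velocities          # A/2
    _check_finite(state)
    apply_boundaries(state, fieldspec.box, ctx.constraints)
    ctx.refresh_cache(state)
    res = compute_all_forces(state, fieldspec, ctx.cache, step=ctx.step,
                             include=_CONSERVATIVE,
                             free_mask=_free_mask(state, ctx))
    _half_kick(state, res.forces, dt)                       # B/2
    ctx.forces = res.forces
    ctx.force_result = res


INTEGRATORS.register("GWMVV", step_gwmvv)
INTEGRATORS.register("SCMVV", step_scmvv)
INTEGRATORS.register("DPDMVV", step_dpdmvv)
INTEGRATORS.register("S1MVV", step_s1mvv)
INTEGRATORS.register("PNHLN", step_pnhln)

#: Schemes whose stored inter-step force is conservative-only (the
#: fluctuation-dissipation part lives in their pairwise sweeps).
_SPLIT_SCHEMES = ("S1MVV", "PNHLN")


# ---------------------------------------------------------------------------
# auxiliary operations
# ---------------------------------------------------------------------------

def _free_mask(state, ctx):
    if ctx.constraints is None or not ctx.constraints.fixation:
        return None
    return ~ctx.constraints.position_fixed_mask(state)


def scale_velocities(state: ParticleState, kBT_target: float,
                     free_mask: Optional[np.ndarray] = None) -> float:
    """Rescale free velocities so the kinetic temperature equals the target.

    Returns the applied factor; a zero-kinetic-energy state is left
    untouched with a warning (the factor would be undefined).
    """
    from .properties import kinetic_temperature
    measured = kinetic_temperature(state, free_mask=free_mask)
    if measured == 0.0:
        warnings.warn("velocity scaling skipped: zero kinetic energy")
        return 1.0
    factor = np.sqrt(kBT_target / measured)
    if free_mask is None:
        state.velocities *= factor
    else:
        state.velocities[free_mask] *= factor
    return float(factor)


def minimize_start(state: ParticleState, fieldspec: ForceField,
                   ctx: StepContext, n_steps: int,
                   max_displacement: float = 0.1) -> float:
    """Capped steepest-descent relaxation of the start geometry.

    Each step displaces particles along the conservative forces with the
    largest single-particle displacement capped at ``max_displacement``;
    a step that would raise the potential energy is retried with half the
    displacement, so accepted potential energies are non-increasing.
    Velocities are untouched.  Returns the final potential energy.
    """
    def cons_energy():
        ctx.refresh_cache(state)
        res = compute_all_forces(state, fieldspec, ctx.cache,
                                 include=("conservative", "bond"))
        return res
    res = cons_energy()
    for _ in range(max(0, n_steps)):
        fmax = np.sqrt((res.forces ** 2).sum(axis=1)).max()
        if fmax == 0.0:
            break
        step_len = max_displacement
        old_pos = state.positions.copy()
        old_images = state.images.copy()
        u_old = res.u_pot
        for _ in range(20):
            state.positions = old_pos + (step_len / fmax) * res.forces
            state.positions %= fieldspec.box.lengths[None, :]
            np.clip(state.positions, 0.0,
                    np.nextafter(fieldspec.box.lengths, 0.0)[None, :],
                    out=state.positions)
            trial = cons_energy()
            if trial.u_pot <= u_old:
                res = trial
                break
            step_len *= 0.5
        else:
            state.positions = old_pos
            state.images = old_images
            res = cons_energy()
            break
    return res.u_pot


# ---------------------------------------------------------------------------
# the main loop
# ---------------------------------------------------------------------------

def _initial_forces(state, fieldspec, ctx, scheme):
    include = _CONSERVATIVE if scheme in _SPLIT_SCHEMES else _ALL
    res = compute_all_forces(state, fieldspec, ctx.cache, step=ctx.step,
                             include=include,
                             free_mask=_free_mask(state, ctx))
    ctx.forces = res.forces
    ctx.force_result = res


def run_simulation(state: ParticleState, fieldspec: ForceField,
                   config: SimulationConfig,
                   constraints: Optional[ConstraintSet] = None,
                   callbacks: Optional[dict] = None,
                   labels: Optional[dict] = None,
                   restart: Optional[dict] = None):
    """Drive a complete simulation.

    Per step: integrate (cache rebuilds happen inside the scheme),
    boundaries/fixation/kicks, optional velocity scaling, periodic
    property output and progress callbacks.  Deterministic for a given
    (state, config): same seed, same trajectory, bit for bit.

    ``callbacks`` may provide ``progress(fraction, record)``,
    ``on_record(record)``, ``on_frame(state, step)`` and
    ``log(level, message)``.  ``restart`` (a dict from
    ``mfdpd.io.RestartInfo.to_runtime``) resumes an earlier run mid-stream.

    Returns ``(state, records, runtime)`` where ``records`` is the list of
    per-output-step property records and ``runtime`` carries what a
    restart needs (step, forces, xi).
    """
    from .properties import collect_record

    callbacks = callbacks or {}
    log = callbacks.get("log", lambda level, msg: None)
    labels = labels or {}

    grid = build_cell_grid(fieldspec.box)
    schedule = build_chunk_schedule(grid)
    ctx = StepContext(grid=grid, schedule=schedule, config=config,
                      constraints=constraints)
    scheme_name = config.integrator.scheme
    stepper = INTEGRATORS.get(scheme_name)

    for warning in check_density_safeguards(state, fieldspec.box):
        log("WARN", warning)

    records = []
    start_step = 0
    if restart is not None:
        start_step = int(restart["step"])
        ctx.step = start_step
        ctx.xi = float(restart.get("xi", 0.0))
        if constraints is not None:
            # fixation restores the same coordinates every step, so the
            # restored state carries the original snapshot exactly
            constraints.freeze_reference(state)
        ctx.refresh_cache(state)
        if restart.get("forces") is not None:
            ctx.forces = restart["forces"].copy()
            ctx.force_result = ForceResult(forces=ctx.forces)
        else:
            _initial_forces(state, fieldspec, ctx, scheme_name)
    else:
        if constraints is not None:
            constraints.freeze_reference(state)
        if config.minimization_steps > 0:
            u = minimize_start(state, fieldspec, ctx,
                               config.minimization_steps)
            log("INFO", f"minimization finished at U = {u:.6g}")
        ctx.refresh_cache(state)
        _initial_forces(state, fieldspec, ctx, scheme_name)
        apply_force_kicks(state, constraints, 0, ctx.forces)
        rec = collect_record(state, ctx, fieldspec, labels=labels)
        records.append(rec)
        if "on_record" in callbacks:
            callbacks["on_record"](rec)
        if "on_frame" in callbacks:
            callbacks["on_frame"](state, 0)

    total = config.steps
    for s in range(start_step + 1, total + 1):
        ctx.step = s
        stepper(state, fieldspec, ctx)
        apply_fixation(state, ctx.constraints)
        apply_force_kicks(state, constraints, s, ctx.forces)
        if config.velocity_scaling and s % config.velocity_scaling == 0:
            scale_velocities(state, fieldspec.thermostat.kBT,
                             free_mask=_free_mask(state, ctx))
        if s % config.output_every == 0 or s == total:
            rec = collect_record(state, ctx, fieldspec, labels=labels)
            records.append(rec)
            if "on_record" in callbacks:
                callbacks["on_record"](rec)
            if "on_frame" in callbacks:
                callbacks["on_frame"](state, s)
            if "progress" in callbacks:
                callbacks["progress"](s / max(total, 1), rec)
            log("STEP", f"step {s}/{total}")

    runtime = {"step": total, "forces": ctx.forces, "xi": ctx.xi}
    return state, records, runtime


__all__ = [
    "StepContext", "step_gwmvv", "step_scmvv", "step_dpdmvv", "step_s1mvv",
    "step_pnhln", "scale_velocities", "minimize_start", "run_simulation",
]
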