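# Methods

## Model and units

The kernel integrates Newton's equations for soft particles interacting
through three pairwise forces below a cutoff: a conservative soft
repulsion `a_ij (1 − r) ê`, a dissipative friction
`−γ ω_D(r) (ê·v_ij) ê` and a random force `σ ω_R(r) ζ_ij/√Δt ê`, plus
harmonic springs `−k (r − r₀) ê` between bonded fragments (topological
and backbone bonds use the identical force law).  Reduced DPD units are
used throughout: the cutoff is the unit of length, `k_B T = 1` the unit
of energy, the reference mass 1.  The weight functions are
`ω_R = 1 − r` and `ω_D = ω_R²` (the identity holds exactly by
construction), and the friction is always derived from the
fluctuation–dissipation relation `γ = σ²/(2 k_B T)` — it is a read-only
property, never an independent input, so the triple cannot drift out of
consistency.

The conservative pair potential is taken as the integral of the printed
force, `a_ij (1 − r)²/2`, for energy reporting; likewise
`k (r − r₀)²/2` per bond.

Defaults: `a = 25` (the standard water-like repulsion at density 3),
`σ = 3`, `Δt = 0.04`, GWMVV `λ = 0.65` — the community-standard operating
point for a density-3 DPD fluid.

## Neighbor search, chunk schedule, pair cache

Cells of edge `≥ cutoff` partition the box (`floor(L/cutoff)` cells per
axis, at least 3 required per axis).  Every cell owns 26 neighbors under
periodic boundaries; a designated half-set of 13 (offsets with
`dz > 0`, or `dz = 0, dy > 0`, or `dz = dy = 0, dx > 0`) partitions the
neighbor relations so each candidate pair is examined exactly once.
Periodic wrapping is pre-resolved per (cell, neighbor) as a frame shift,
which is the exact minimum image for any pair below the cutoff.

A cell's force accumulation touches itself plus its 13 designated
neighbors; that write set extends one cell in +z but one cell either way
in x and y, so cells whose coordinates agree modulo (3, 3, 2) never
conflict: 18 chunk groups when the cell counts divide the strides.  For
incompatible grids a greedy coloring of the write-set conflict graph
(seeded by the residue classes) produces a still-safe, possibly ragged
cover; every schedule is verified against a brute-force disjointness
check at construction time.

All within-cutoff pairs of a position snapshot (indices, distance, unit
vector) are cached once and reused by every force term and every
self-consistent re-evaluation at those positions — pair distances are
never recomputed within a step.  The cutoff test is strict (`r < 1`);
the force vanishes at the cutoff, so the choice is observable only in
the cache-size statistic.  Coincident particles (r = 0) get a zero unit
vector and hence no pair force — relevant only for pathological starts,
which the minimizer resolves.

The cache is sorted canonically (i < j, lexicographic) after
enumeration.  Together with per-pair keyed noise this makes accumulated
forces a pure function of the positions: traversal order, chunk
shuffling and the `threads` setting cannot change any result.  This
deliberately strengthens the lock-free guarantee into full bitwise
reproducibility.  The Python engine executes the schedule serially; the
schedule's safety property is constructed, verified and tested, and the
`threads` setting exercises it by permuting the traversal order within
groups.

## Deterministic pair noise

Random pair forces draw one unit-variance variate per (pair, step),
symmetric within the pair, from a stateless 64-bit hash
(SplitMix64-style) of `(seed, step, substep, i, j)`.  The default
variate is uniform on `[−√3, √3]` (zero mean, unit variance — the cheap
standard choice in DPD); a Gaussian via Box–Muller is registered as an
alternative.  Because the "stream state" is just the step counter,
restart continuation replays noise bit-exactly.

## Integration schemes

Dissipative forces depend on velocities, so plain velocity-Verlet must
be modified.  The four schemes and their binding relationships:

* **GWMVV** — positions advance with the old force; the new force is
  evaluated against the predicted velocity `v + λ Δt F/m`; the corrector
  averages old and new forces.  At `λ = 0.5` this is algebraically
  velocity-Verlet with the velocity-dependent force taken at the
  half-kicked velocity; the test suite verifies < 1e−12 coincidence with
  an independent brute-force VV implementation over 100 steps.
* **SCMVV** — velocity-Verlet in which conservative + random forces are
  evaluated once at the new positions and the dissipative term is
  re-evaluated a fixed number of times against successively corrected
  velocities (no convergence tolerance), reusing the cached distances.
  One iteration *is* DPDMVV (asserted bit-for-bit).
* **S1MVV** — Shardlow splitting: a sequential pair-by-pair
  fluctuation–dissipation sweep (explicit half-step, then an implicit
  half-step solved in closed form for the relative-velocity projection;
  each pair update conserves its momentum exactly), followed by plain VV
  on the conservative forces.
* **PNHLN** — a pairwise Nosé–Hoover–Langevin thermostat.  A single
  auxiliary friction variable ξ follows the control law
  `dξ/dt = c ⟨ ω_D(r) [ (ê·v_ij)² − k_B T (1/m_i + 1/m_j) ] ⟩` (mean
  over cached pairs; gain `c` is the coupling parameter), whose fixed
  point is the target kinetic temperature.  Pair velocities are damped
  implicitly with friction ξ plus a pairwise random kick whose variance
  is matched so the discrete pair map has stationary projection variance
  exactly `k_B T (1/m_i + 1/m_j)` — a discrete fluctuation–dissipation
  condition, which removes the O(Δt) temperature bias a naive amplitude
  would give.  ξ starts at 0 and is clamped non-negative in the sweep;
  as `c → 0` the thermostat (friction *and* noise) vanishes and the
  dynamics reduce to conservative motion, which the tests exploit by
  checking seed-independence at vanishing coupling.  The equations for
  this scheme are this package's own formulation of the pairwise-NHL
  idea; the literature variants differ in splitting details.
  Default `c = 1` holds the long-run temperature at the target within
  a fraction of a percent at `Δt = 0.04`.

GWMVV and SCMVV carry the full force between steps; S1MVV and PNHLN
carry the conservative-only force (their fluctuation–dissipation part
lives in the pairwise sweeps).  PNHLN's symmetric
kick–drift–thermostat–drift–kick split rebuilds the pair cache twice per
step and is correspondingly the most expensive scheme.

## Boundaries, constraints, auxiliaries

Periodic wrapping maps coordinates into `[0, L)` via exact remainder
(robust even for runaway coordinates) while per-particle image counters
preserve unwrapped positions.  Reflective walls are elastic (specular):
mirror the coordinate, negate the normal velocity — speed and kinetic
energy are preserved exactly; multiple crossings resolve iteratively.
Molecule sub-box confinement reflects each member particle individually
(the simplest reading of reflective virtual walls).  Position fixation
restores the frozen snapshot and zeroes forces/velocities each step;
velocity fixation restores only the velocity.  Force kicks add a
constant vector to every particle of a molecule type on steps divisible
by the kick period.  Velocity scaling multiplies free velocities by
`√(T_target/T_measured)`, making the post-scaling temperature exact.
Start-geometry minimization is capped steepest descent (largest
single-particle displacement ≤ the cap, default 0.1) with step halving
on any energy increase, so accepted energies are non-increasing;
velocities are untouched.

Density safeguards inspect blocks of edge ≥ 2 cutoffs and warn when a
block's occupancy leaves `[0.25, 4] ×` the global mean.  The 2-cutoff
coarse-graining (mean occupancy ~24 at density 3) keeps ordinary Poisson
fluctuations of a healthy fluid inside the band, which cutoff-sized
cells (mean 3) could not.

## Observables

Kinetic temperature `Σ m v²/(3 N_free)` excludes fixed particles.  The
pressure diagonal is the virial form
`P_αα = (Σ m v_α² + Σ_pairs r_α F_α)/V` over the conservative pair
forces (repulsion + bonds); thermostat impulses are not counted as
virial contributions, which leaves time-averaged tensions unaffected.
Surface tension per axis is the planar difference
`L_α (P_αα − (P_ββ + P_γγ)/2)`.  Radii of gyration are mass-weighted and
computed from unwrapped coordinates, hence wrap-invariant; the
per-output-step record reports the mean over the instances of each
molecule type.  Nearest-neighbor analysis reports, per ordered type pair
(A, B), the mean number of B particles within the analysis radius
(default: the cutoff, configurable) of an A particle, and the same
contact counts aggregated by molecule type with intra-molecule contacts
excluded — tracked per output step for temporal monitoring.

## Synthetic systems and what the tests show

There are no external datasets: every test system is generated —
uniform-random or lattice-placed fluids at density 3 (the common DPD
operating point), bead-spring dimers/chains with harmonic bonds, and
Maxwell–Boltzmann initial velocities at the target temperature with net
momentum removed.  These fixtures probe the kernel's contracts
(conservation laws, oracle equivalence, scheme identities, thermostat
consistency at ρ=3, σ=3, Δt=0.04, N=3000 over 10⁴ steps) but are
homogeneous one- and two-type systems; passing them shows the engine is
correct and canonical, not that any particular real fluid's phase
behavior or transport is reproduced — mapping real chemistry onto
`a_ij` tables is the user's modelling step.

A note on the cache-size statistic: the equilibrated within-cutoff pair
count at ρ=3, a=25 measures ≈ 6.0 per particle — slightly below the
ideal-gas value `2π ≈ 6.28` because the soft repulsion depletes close
contacts.  Literature folklore quotes "about 7"; the measured value is
what this implementation's physics produces and is reported as such.

## Numerical choices

* Problem sizes: the thermostat-consistency suite runs N = 3000 for
  12 000 steps per scheme (2 000 equilibration + 10 000 measured); the
  GWMVV/VV coincidence check uses 100 particles at `Δt = 0.02` in a
  dilute box so floating-point round-off amplified by trajectory
  divergence stays orders of magnitude below the 1e−12 acceptance band.
* Forces accumulate per component via `bincount` over the canonically
  sorted cache — fixed summation order, hence bitwise reproducibility.
* The pair-enumeration kernel and the two pairwise sweeps are
  numba-compiled; pure-Python fallbacks with identical arithmetic exist,
  so results do not depend on the compiler.
* Restart files store arrays as base64-encoded little-endian IEEE-754
  bytes inside versioned JSON: a text format with bit-exact round trips.
* Degenerate inputs: zero-length bonds with nonzero rest length raise
  (undefined direction); zero kinetic energy makes velocity scaling a
  warned no-op; an all-fixed system reports its raw temperature.

## Known limitations

* Electrostatics is a hook only: charges are parsed, stored and written,
  but exert no force.
* Execution is single-threaded; the chunk schedule guarantees that a
  parallel implementation would be lock-free, but no threads are spawned.
* No Verlet skin lists, barostats/NPT, shear boundaries, angle/dihedral
  terms, or thermostats beyond the four schemes.
* The virial omits the thermostat impulses of S1MVV/PNHLN; instantaneous
  pressures under those schemes are conservative-only (time averages of
  the tension are unaffected).
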