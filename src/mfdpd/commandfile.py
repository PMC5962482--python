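"""Plain-text command files describing a complete simulation.

The dialect is sectioned key/value text with ``#`` comments::

    [Box]
    lengths = 10 10 10
    boundaries = periodic periodic periodic

    [ParticleTypes]
    # name  mass  charge
    W  1.0  0.0

    [Interactions]
    W W 25

    [Molecules]
    molecule water
        particles W
        count 3000
    end

    [Simulation]
    steps = 1000
    dt = 0.04
    sigma = 3
    kBT = 1
    integrator = GWMVV
    lambda = 0.65
    output_every = 100
    seed = 42

    [Constraints]
    # fixation <molecule> position|velocity
    # boundary <molecule> x0 x1 y0 y1 z0 z1
    # kick <molecule> fx fy fz <period>

Molecule blocks may also carry ``bond i j k r0`` (topological),
``backbone i j k r0``, ``placement random|lattice``.  Parsing is
whole-file: every problem is collected with its line number and reported
at once rather than stopping at the first error.  An interaction given
for (A, B) is mirrored to (B, A) automatically.
"""

from __future__ import annotations

import numpy as np

from .errors import CommandFileError
from .model import (SCHEMES, Bond, BoxGeometry, InteractionMatrix,
                    IntegratorConfig, MoleculeDescription, SimulationConfig,
                    SystemSpec, ThermostatParams)

_SECTIONS = ("Box", "ParticleTypes", "Interactions", "Molecules",
             "Simulation", "Constraints")

_SIM_KEYS = ("steps", "dt", "kbt", "sigma", "integrator", "lambda",
             "iterations", "coupling", "output_every", "seed", "rng",
             "gravity", "velocity_scaling", "minimization_steps", "threads")


def _tokenize(path):
    """(line_number, section, tokens) for every payload line."""
    out = []
    section = None
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("[") and line.endswith("]"):
                section = line[1:-1].strip()
                out.append((ln, "__section__", [section]))
                continue
            out.append((ln, section, line.split()))
    return out


def _floats(tokens, n, errors, ln, what):
    try:
        vals = [float(t) for t in tokens]
    except ValueError:
        errors.append(f"line {ln}: {what}: non-numeric value in "
                      f"{' '.join(tokens)!r}")
        return None
    if len(vals) != n:
        errors.append(f"line {ln}: {what}: expected {n} numbers, "
                      f"got {len(vals)}")
        return None
    return vals


def parse_command_file(path) -> SystemSpec:
    """Parse and fully validate a command file.

    Raises ``CommandFileError`` carrying the complete list of problems
    (each with its line number) if anything is invalid.
    """
    errors: list = []
    lines = _tokenize(path)

    seen_sections = set()
    for ln, sec, toks in lines:
        if sec == "__section__":
            if toks[0] not in _SECTIONS:
                errors.append(f"line {ln}: unknown section [{toks[0]}]; "
                              f"valid: {', '.join(_SECTIONS)}")
            seen_sections.add(toks[0])
        elif sec is None:
            errors.append(f"line {ln}: content before the first section")
    for required in ("Box", "ParticleTypes", "Molecules"):
        if required not in seen_sections:
            errors.append(f"missing required section [{required}]")

    def section_lines(name):
        return [(ln, toks) for ln, sec, toks in lines if sec == name]

    # --- box ----------------------------------------------------------
    lengths = None
    boundaries = ("periodic", "periodic", "periodic")
    for ln, toks in section_lines("Box"):
        key = toks[0].rstrip("=").lower()
        vals = [t for t in toks[1:] if t != "="]
        if key == "lengths":
            lengths = _floats(vals, 3, errors, ln, "box lengths")
        elif key == "boundaries":
            if len(vals) != 3 or any(v not in ("periodic", "reflective")
                                     for v in vals):
                errors.append(f"line {ln}: boundaries must be three of "
                              f"periodic|reflective")
            else:
                boundaries = tuple(vals)
        else:
            errors.append(f"line {ln}: unknown [Box] key {key!r}")
    if "Box" in seen_sections and lengths is None:
        errors.append("[Box] must define 'lengths'")

    # --- particle types ----------------------------------------------
    type_names, type_masses, type_charges = [], [], []
    for ln, toks in section_lines("ParticleTypes"):
        name = toks[0]
        if name in type_names:
            errors.append(f"line {ln}: duplicate particle type {name!r}")
            continue
        mass, charge = 1.0, 0.0
        if len(toks) > 1:
            v = _floats(toks[1:2], 1, errors, ln, f"type {name} mass")
            if v is None:
                continue
            mass = v[0]
        if len(toks) > 2:
            v = _floats(toks[2:3], 1, errors, ln, f"type {name} charge")
            if v is None:
                continue
            charge = v[0]
        if mass <= 0:
            errors.append(f"line {ln}: type {name!r} mass must be > 0")
        type_names.append(name)
        type_masses.append(mass)
        type_charges.append(charge)
    if "ParticleTypes" in seen_sections and not type_names:
        errors.append("[ParticleTypes] declares no types")
    tindex = {n: k for k, n in enumerate(type_names)}

    # --- interactions -------------------------------------------------
    nt = len(type_names)
    a = np.full((nt, nt), np.nan)
    default_a = None
    for ln, toks in section_lines("Interactions"):
        if toks[0].lower() == "default":
            v = _floats(toks[1:], 1, errors, ln, "default repulsion")
            if v is not None:
                default_a = v[0]
            continue
        if len(toks) != 3:
            errors.append(f"line {ln}: interaction lines are "
                          f"'<typeA> <typeB> <a_ij>'")
            continue
        ta, tb = toks[0], toks[1]
        missing = [t for t in (ta, tb) if t not in tindex]
        if missing:
            errors.append(f"line {ln}: undeclared particle type(s) "
                          f"{', '.join(repr(m) for m in missing)}")
            continue
        v = _floats(toks[2:], 1, errors, ln, f"a({ta},{tb})")
        if v is None:
            continue
        ia, ib = tindex[ta], tindex[tb]
        if not np.isnan(a[ia, ib]) and a[ia, ib] != v[0]:
            errors.append(f"line {ln}: conflicting values for a({ta},{tb})")
        a[ia, ib] = v[0]
        a[ib, ia] = v[0]          # symmetry completion
    if default_a is not None:
        a[np.isnan(a)] = default_a
    if "Interactions" not in seen_sections:
        a[np.isnan(a)] = 25.0       # documented default repulsion
    if nt and np.any(np.isnan(a)):
        for ia in range(nt):
            for ib in range(ia, nt):
                if np.isnan(a[ia, ib]):
                    errors.append(
                        f"[Interactions]: no repulsion given for "
                        f"({type_names[ia]}, {type_names[ib]}) and no "
                        f"default")
        a = np.nan_to_num(a)

    # --- molecules ----------------------------------------------------
    mol_args: list = []
    current = None
    for ln, toks in section_lines("Molecules"):
        key = toks[0].lower()
        if key == "molecule":
            if current is not None:
                errors.append(f"line {ln}: previous molecule block not "
                              f"closed with 'end'")
            if len(toks) != 2:
                errors.append(f"line {ln}: 'molecule <name>'")
                current = {"name": f"anonymous{ln}"}
            else:
                current = {"name": toks[1]}
            current.update(seq=None, tbonds=[], bbonds=[], count=1,
                           placement="random", line=ln)
            continue
        if current is None:
            errors.append(f"line {ln}: molecule attribute outside a "
                          f"'molecule ... end' block")
            continue
        if key == "end":
            mol_args.append(current)
            current = None
        elif key == "particles":
            missing = [t for t in toks[1:] if t not in tindex]
            if missing:
                errors.append(f"line {ln}: undeclared particle type(s) "
                              f"{', '.join(repr(m) for m in missing)}")
            else:
                current["seq"] = tuple(tindex[t] for t in toks[1:])
        elif key in ("bond", "backbone"):
            v = _floats(toks[1:], 4, errors, ln, f"{key} spec")
            if v is not None:
                try:
                    b = Bond(int(v[0]), int(v[1]), v[2], v[3],
                             kind="topological" if key == "bond"
                             else "backbone")
                    current["tbonds" if key == "bond" else "bbonds"].append(b)
                except Exception as exc:
                    errors.append(f"line {ln}: {exc}")
        elif key == "count":
            v = _floats(toks[1:], 1, errors, ln, "copy count")
            if v is not None:
                current["count"] = int(v[0])
        elif key == "placement":
            if len(toks) != 2 or toks[1] not in ("random", "lattice"):
                errors.append(f"line {ln}: placement is random|lattice")
            else:
                current["placement"] = toks[1]
        else:
            errors.append(f"line {ln}: unknown molecule attribute {key!r}")
    if current is not None:
        errors.append(f"line {current['line']}: molecule block not closed "
                      f"with 'end'")
        mol_args.append(current)
    if "Molecules" in seen_sections and not mol_args:
        errors.append("[Molecules] declares no molecules")

    # --- constraints --------------------------------------------------
    constraints: dict = {}
    mol_names = {m["name"] for m in mol_args}
    for ln, toks in section_lines("Constraints"):
        kind = toks[0].lower()
        if len(toks) < 2 or toks[1] not in mol_names:
            errors.append(f"line {ln}: constraint must name a declared "
                          f"molecule")
            continue
        entry = constraints.setdefault(toks[1], {})
        if kind == "fixation":
            if len(toks) != 3 or toks[2] not in ("position", "velocity"):
                errors.append(f"line {ln}: 'fixation <mol> "
                              f"position|velocity'")
            else:
                entry["fixation"] = toks[2]
        elif kind == "boundary":
            v = _floats(toks[2:], 6, errors, ln, "boundary walls")
            if v is not None:
                entry["boundary"] = ((v[0], v[1]), (v[2], v[3]),
                                     (v[4], v[5]))
        elif kind == "kick":
            v = _floats(toks[2:], 4, errors, ln, "kick spec")
            if v is not None:
                entry["force_kick"] = ((v[0], v[1], v[2]), int(v[3]))
        else:
            errors.append(f"line {ln}: unknown constraint {kind!r}")

    # --- simulation ---------------------------------------------------
    sim: dict = {}
    for ln, toks in section_lines("Simulation"):
        key = toks[0].rstrip("=").lower()
        vals = [t for t in toks[1:] if t != "="]
        if key not in _SIM_KEYS:
            errors.append(f"line {ln}: unknown [Simulation] key {key!r}; "
                          f"valid: {', '.join(_SIM_KEYS)}")
            continue
        if key == "integrator":
            if len(vals) != 1 or vals[0] not in SCHEMES:
                errors.append(f"line {ln}: unknown integrator "
                              f"{' '.join(vals)!r}; valid: "
                              f"{', '.join(SCHEMES)}")
            else:
                sim["integrator"] = vals[0]
        elif key == "rng":
            sim["rng"] = vals[0] if vals else ""
        elif key == "gravity":
            v = _floats(vals, 3, errors, ln, "gravity")
            if v is not None:
                sim["gravity"] = v
        else:
            v = _floats(vals, 1, errors, ln, key)
            if v is not None:
                sim[key] = v[0]

    if errors:
        raise CommandFileError(errors)

    molecules = []
    for m in mol_args:
        if m["seq"] is None:
            errors.append(f"line {m['line']}: molecule {m['name']!r} has "
                          f"no 'particles' line")
            continue
        extra = constraints.get(m["name"], {})
        try:
            molecules.append(MoleculeDescription(
                name=m["name"],
                particle_type_sequence=m["seq"],
                topological_bonds=tuple(m["tbonds"]),
                backbone_bonds=tuple(m["bbonds"]),
                copy_count=m["count"],
                placement=m["placement"],
                fixation=extra.get("fixation", "none"),
                boundary=extra.get("boundary"),
                force_kick=extra.get("force_kick"),
            ))
        except Exception as exc:
            errors.append(f"line {m['line']}: {exc}")

    try:
        box = BoxGeometry(lengths=np.asarray(lengths),
                          boundary_modes=boundaries)
    except Exception as exc:
        errors.append(f"[Box]: {exc}")
        box = None
    try:
        thermostat = ThermostatParams(sigma=sim.get("sigma", 3.0),
                                      kBT=sim.get("kbt", 1.0),
                                      dt=sim.get("dt", 0.04))
        integrator = IntegratorConfig(
            scheme=sim.get("integrator", "GWMVV"),
            lam=sim.get("lambda", 0.65),
            n_self_consistent=int(sim.get("iterations", 5)),
            coupling=sim.get("coupling", 1.0))
        config = SimulationConfig(
            steps=int(sim.get("steps", 0)),
            output_every=int(sim.get("output_every", 1)),
            thermostat=thermostat,
            integrator=integrator,
            gravity=np.asarray(sim.get("gravity", [0.0, 0.0, 0.0])),
            rng_kind=sim.get("rng", "uniform") or "uniform",
            seed=int(sim.get("seed", 0)),
            velocity_scaling=int(sim.get("velocity_scaling", 0)),
            minimization_steps=int(sim.get("minimization_steps", 0)),
            parallel_threads=int(sim.get("threads", 1)))
    except Exception as exc:
        errors.append(f"[Simulation]: {exc}")
        config = None

    if errors:
        raise CommandFileError(errors)
    try:
        return SystemSpec(box=box, type_names=type_names,
                          interactions=InteractionMatrix(a=a),
                          molecules=molecules, config=config,
                          type_masses=type_masses,
                          type_charges=type_charges)
    except Exception as exc:
        raise CommandFileError([str(exc)])


def write_command_file(spec: SystemSpec, path) -> None:
    """Serialize a spec back to command-file text (round-trip capable)."""
    cfg = spec.config
    th = cfg.thermostat
    ig = cfg.integrator
    lines = ["[Box]",
             "lengths = " + " ".join(f"{v:.17g}" for v in spec.box.lengths),
             "boundaries = " + " ".join(spec.box.boundary_modes),
             "", "[ParticleTypes]"]
    for n, m, c in zip(spec.type_names, spec.type_masses, spec.type_charges):
        lines.append(f"{n} {m:.17g} {c:.17g}")
    lines += ["", "[Interactions]"]
    for i in range(len(spec.type_names)):
        for j in range(i, len(spec.type_names)):
            lines.append(f"{spec.type_names[i]} {spec.type_names[j]} "
                         f"{spec.interactions.a[i, j]:.17g}")
    lines += ["", "[Molecules]"]
    names = {t: n for n, t in
             zip(spec.type_names, range(len(spec.type_names)))}
    for m in spec.molecules:
        lines.append(f"molecule {m.name}")
        lines.append("    particles " + " ".join(
            names[t] for t in m.particle_type_sequence))
        for b in m.topological_bonds:
            lines.append(f"    bond {b.i} {b.j} {b.k_bond:.17g} "
                         f"{b.r_bond:.17g}")
        for b in m.backbone_bonds:
            lines.append(f"    backbone {b.i} {b.j} {b.k_bond:.17g} "
                         f"{b.r_bond:.17g}")
        lines.append(f"    count {m.copy_count}")
        lines.append(f"    placement {m.placement}")
        lines.append("end")
    lines += ["", "[Simulation]",
              f"steps = {cfg.steps}",
              f"dt = {th.dt:.17g}",
              f"sigma = {th.sigma:.17g}",
              f"kBT = {th.kBT:.17g}",
              f"integrator = {ig.scheme}",
              f"lambda = {ig.lam:.17g}",
              f"iterations = {ig.n_self_consistent}",
              f"coupling = {ig.coupling:.17g}",
              f"output_every = {cfg.output_every}",
              f"seed = {cfg.seed}",
              f"rng = {cfg.rng_kind}",
              "gravity = " + " ".join(f"{v:.17g}" for v in cfg.gravity),
              f"velocity_scaling = {cfg.velocity_scaling}",
              f"minimization_steps = {cfg.minimization_steps}",
              f"threads = {cfg.parallel_threads}",
              "", "[Constraints]"]
    for m in spec.molecules:
        if m.fixation != "none":
            lines.append(f"fixation {m.name} {m.fixation}")
        if m.boundary is not None:
            flat = " ".join(f"{v:.17g}" for pair in m.boundary for v in pair)
            lines.append(f"boundary {m.name} {flat}")
        if m.force_kick is not None:
            vec, period = m.force_kick
            lines.append(f"kick {m.name} "
                         + " ".join(f"{v:.17g}" for v in vec)
                         + f" {period}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


__all__ = ["parse_command_file", "write_command_file"]
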