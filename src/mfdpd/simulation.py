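"""High-level driver tying a ``SystemSpec`` to the engine."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .boundaries import ConstraintSet
from .factory import NOISE_KINDS
from .forces import ForceField
from .integrators import run_simulation
from .io import RestartInfo, records_to_frame
from .model import SystemSpec, build_system


@dataclass
class SimulationResult:
    """Final state plus the property table and restart information."""

    state: object
    records: list
    restart: RestartInfo
    spec: SystemSpec

    @property
    def properties(self) -> pd.DataFrame:
        return records_to_frame(
            self.records, type_names=list(self.spec.type_names),
            molecule_names=[m.name for m in self.spec.molecules])


class Simulation:
    """One simulation task assembled from a declarative system description.

    Builds the particle state, bond table, force field and constraints,
    then drives the configured number of steps.  ``callbacks`` (optional)
    may carry ``log``, ``progress``, ``on_record`` and ``on_frame``
    hooks for logging, progress monitoring and streaming output.
    """

    def __init__(self, spec: SystemSpec,
                 restart: Optional[RestartInfo] = None):
        self.spec = spec
        cfg = spec.config
        if restart is None:
            self.state, bonds = build_system(spec)
        else:
            self.state = restart.state.copy()
            _, bonds = build_system(spec)   # bond table is config-derived
        noise = NOISE_KINDS.get(cfg.rng_kind)(cfg.seed)
        self.field = ForceField(
            interactions=spec.interactions, bonds=bonds,
            thermostat=cfg.thermostat, noise=noise, box=spec.box,
            gravity=cfg.gravity)
        self.constraints = ConstraintSet.from_molecules(
            spec.molecules, spec.box)
        self.restart = restart

    def run(self, callbacks: Optional[dict] = None) -> SimulationResult:
        cfg = self.spec.config
        labels = {"type_names": list(self.spec.type_names),
                  "molecule_names": [m.name for m in self.spec.molecules]}
        state, records, runtime = run_simulation(
            self.state, self.field, cfg, constraints=self.constraints,
            callbacks=callbacks, labels=labels,
            restart=self.restart.to_runtime() if self.restart else None)
        info = RestartInfo(
            step=runtime["step"], state=state.copy(),
            forces=runtime["forces"], xi=runtime["xi"], seed=cfg.seed,
            noise_kind=cfg.rng_kind, config_digest=self.spec.digest())
        return SimulationResult(state=state, records=records, restart=info,
                                spec=self.spec)


__all__ = ["Simulation", "SimulationResult"]
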