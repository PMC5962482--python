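"""File I/O: extended-XYZ trajectories, restart files, property tables, logging.

Trajectory frames are human-readable extended XYZ: the particle count, a
comment line carrying step / box / boundary modes, then one line per
particle with type label, wrapped coordinates, velocities and molecule
index, printed at full round-trip precision (%.17g).

Restart files are single self-describing JSON documents (versioned) with
every float array stored as base64-encoded little-endian IEEE-754 bytes,
so a save/load round trip is bit-exact — including the noise "stream
state", which for keyed noise is just the step counter.
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass
from typing import Optional, TextIO

import numpy as np
import pandas as pd

from .errors import RestartError
from .model import BoxGeometry, ParticleState

RESTART_FORMAT_VERSION = 1

LOG_LEVELS = ("ERROR", "WARN", "INFO", "STEP", "PAIR-DEBUG")


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------

class TrajectoryWriter:
    """Appends extended-XYZ frames to an open text stream."""

    def __init__(self, stream: TextIO, type_names, box: BoxGeometry):
        self.stream = stream
        self.type_names = list(type_names)
        self.box = box
        self.n_frames = 0

    def write_frame(self, state: ParticleState, step: int) -> None:
        s = self.stream
        L = self.box.lengths
        s.write(f"{state.n}\n")
        s.write(
            f"step={step} box={L[0]:.17g},{L[1]:.17g},{L[2]:.17g} "
            f"boundaries={','.join(self.box.boundary_modes)} "
            f"columns=type,x,y,z,vx,vy,vz,molecule\n")
        pos = state.positions
        vel = state.velocities
        for k in range(state.n):
            s.write(
                f"{self.type_names[state.type_index[k]]} "
                f"{pos[k, 0]:.17g} {pos[k, 1]:.17g} {pos[k, 2]:.17g} "
                f"{vel[k, 0]:.17g} {vel[k, 1]:.17g} {vel[k, 2]:.17g} "
                f"{state.molecule_index[k]}\n")
        self.n_frames += 1


def read_trajectory(path):
    """Parse an extended-XYZ trajectory written by ``TrajectoryWriter``.

    Yields dicts with step, box, boundary modes and the per-particle
    arrays (type labels, positions, velocities, molecule indices).
    """
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            n = int(header.strip())
            meta = dict(kv.split("=", 1)
                        for kv in fh.readline().split() if "=" in kv)
            labels = []
            pos = np.empty((n, 3))
            vel = np.empty((n, 3))
            mol = np.empty(n, dtype=np.int64)
            for k in range(n):
                parts = fh.readline().split()
                labels.append(parts[0])
                pos[k] = [float(x) for x in parts[1:4]]
                vel[k] = [float(x) for x in parts[4:7]]
                mol[k] = int(parts[7])
            yield {
                "step": int(meta["step"]),
                "box": np.array([float(x)
                                 for x in meta["box"].split(",")]),
                "boundaries": tuple(meta["boundaries"].split(",")),
                "types": labels,
                "positions": pos,
                "velocities": vel,
                "molecule_index": mol,
            }


# ---------------------------------------------------------------------------
# restart
# ---------------------------------------------------------------------------

def _encode(arr: np.ndarray) -> dict:
    a = np.ascontiguousarray(arr)
    if a.dtype.byteorder == ">":           # pragma: no cover
        a = a.astype(a.dtype.newbyteorder("<"))
    return {"dtype": a.dtype.str, "shape": list(a.shape),
            "data": base64.b64encode(a.tobytes()).decode("ascii")}


def _decode(obj: dict) -> np.ndarray:
    raw = base64.b64decode(obj["data"])
    return np.frombuffer(raw, dtype=np.dtype(obj["dtype"])).reshape(
        obj["shape"]).copy()


@dataclass
class RestartInfo:
    """Complete serialized simulation state for exact continuation."""

    step: int
    state: ParticleState
    forces: Optional[np.ndarray]     # stored inter-step force array
    xi: float                        # PNHLN auxiliary variable
    seed: int
    noise_kind: str
    config_digest: str

    def to_runtime(self) -> dict:
        """The dict ``run_simulation(..., restart=...)`` consumes."""
        return {"step": self.step, "forces": self.forces, "xi": self.xi}


_STATE_FIELDS = ("positions", "velocities", "forces", "masses", "type_index",
                 "molecule_index", "molecule_type", "charge", "images")


def save_restart(info: RestartInfo, path) -> None:
    doc = {
        "format": "mfdpd-restart",
        "version": RESTART_FORMAT_VERSION,
        "step": info.step,
        "xi": float(info.xi).hex(),
        "seed": info.seed,
        "noise_kind": info.noise_kind,
        "config_digest": info.config_digest,
        "state": {f: _encode(getattr(info.state, f)) for f in _STATE_FIELDS},
        "stored_forces": (_encode(info.forces)
                          if info.forces is not None else None),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_restart(path, config_digest: Optional[str] = None,
                 log=None) -> RestartInfo:
    """Load a restart file; never applies a partial state.

    A differing configuration digest is permitted — restarting with
    altered settings is an intended workflow — but it is reported through
    ``log`` as a warning.
    """
    try:
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format") != "mfdpd-restart":
            raise RestartError(f"{path} is not a restart file")
        if doc.get("version") != RESTART_FORMAT_VERSION:
            raise RestartError(
                f"unsupported restart version {doc.get('version')}")
        arrays = {f: _decode(doc["state"][f]) for f in _STATE_FIELDS}
        state = ParticleState(**arrays)
        state.validate()
        forces = (_decode(doc["stored_forces"])
                  if doc["stored_forces"] is not None else None)
        info = RestartInfo(
            step=int(doc["step"]),
            state=state,
            forces=forces,
            xi=float.fromhex(doc["xi"]),
            seed=int(doc["seed"]),
            noise_kind=doc["noise_kind"],
            config_digest=doc["config_digest"],
        )
    except RestartError:
        raise
    except Exception as exc:
        raise RestartError(f"corrupt or truncated restart file {path}: "
                           f"{exc}") from exc
    if config_digest is not None and config_digest != info.config_digest \
            and log is not None:
        log("WARN", "restart was written under a different configuration; "
                    "continuing with the altered settings")
    return info


# ---------------------------------------------------------------------------
# property tables
# ---------------------------------------------------------------------------

def records_to_frame(records, type_names=None,
                     molecule_names=None) -> pd.DataFrame:
    """Flatten property records into a DataFrame with a stable header."""
    rows = [r.as_row(type_names=type_names, molecule_names=molecule_names)
            for r in records]
    return pd.DataFrame(rows)


def write_properties_csv(records, path, type_names=None,
                         molecule_names=None) -> None:
    records_to_frame(records, type_names, molecule_names).to_csv(
        path, index=False)


# ---------------------------------------------------------------------------
# logging & progress
# ---------------------------------------------------------------------------

class MemoryLogger:
    """Collects (level, step-tag, message) records, respecting a threshold.

    PAIR-DEBUG is only recorded when explicitly enabled — it is a
    per-pair-volume level that would otherwise swamp the log.
    """

    def __init__(self, level: str = "INFO"):
        if level not in LOG_LEVELS:
            raise ValueError(f"unknown log level {level!r}")
        self.level = level
        self.records = []

    def enabled(self, level: str) -> bool:
        return LOG_LEVELS.index(level) <= LOG_LEVELS.index(self.level)

    def __call__(self, level: str, message: str) -> None:
        if self.enabled(level):
            self.records.append((level, message))


class FileLogger(MemoryLogger):
    """Streams log lines to a text file as they arrive."""

    def __init__(self, stream: TextIO, level: str = "INFO"):
        super().__init__(level)
        self.stream = stream

    def __call__(self, level: str, message: str) -> None:
        if self.enabled(level):
            self.stream.write(f"[{level}] {message}\n")


__all__ = [
    "TrajectoryWriter", "read_trajectory", "RestartInfo", "save_restart",
    "load_restart", "records_to_frame", "write_properties_csv",
    "MemoryLogger", "FileLogger", "LOG_LEVELS", "RESTART_FORMAT_VERSION",
]
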