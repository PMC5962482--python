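"""Counter-based, pair-keyed random number streams.

Every random pair force draws exactly one variate zeta_ij with zero mean
and unit variance, symmetric within the pair.  To make force accumulation
independent of traversal order and thread count, zeta is not drawn from a
sequential stream but *keyed*: a stateless 64-bit mix of
(seed, step, substep, i, j) is mapped to the variate.  Replaying any step
therefore reproduces its noise bit-exactly, which is also what makes
restart continuation exact — the "stream state" is just the step counter.

Two variate kinds are registered: ``uniform`` (uniform on
[-sqrt(3), sqrt(3)], the cheap standard choice in DPD) and ``gaussian``
(Box-Muller from two keyed uniforms).
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)
_PRIME = np.uint64(0xD6E8FEB86659FD93)
_SQRT3 = np.sqrt(3.0)
_INV64 = 1.0 / 2.0 ** 64


def _splitmix64(x: np.ndarray) -> np.ndarray:
    # standard SplitMix64 finalizer; uint64 arithmetic wraps mod 2^64
    # (the overflow is the point — silence numpy's scalar warning)
    with np.errstate(over="ignore"):
        x = (x + _GOLDEN).astype(np.uint64)
        x ^= x >> np.uint64(30)
        x *= _MIX1
        x ^= x >> np.uint64(27)
        x *= _MIX2
        x ^= x >> np.uint64(31)
    return x


def _keyed_uniform(base: np.uint64, i: np.ndarray, j: np.ndarray,
                   salt: int) -> np.ndarray:
    """Uniform variates in [0, 1) keyed by (base, i, j, salt)."""
    with np.errstate(over="ignore"):
        x = _splitmix64(base + np.uint64(salt) * _PRIME)
        h = _splitmix64(x + i.astype(np.uint64) * _GOLDEN)
        h = _splitmix64(h ^ (j.astype(np.uint64) * _PRIME))
    return h.astype(np.float64) * _INV64


class NoiseStream:
    """Deterministic pair-noise source for one simulation.

    Parameters
    ----------
    seed : int
        Run seed; the whole noise history is a pure function of it.
    kind : {"uniform", "gaussian"}
        Distribution of the unit-variance variates.
    """

    KINDS = ("uniform", "gaussian")

    def __init__(self, seed: int, kind: str = "uniform"):
        if kind not in self.KINDS:
            raise ParameterError(
                f"unknown noise kind {kind!r}; valid: {', '.join(self.KINDS)}")
        self.seed = int(seed)
        self.kind = kind

    def _base(self, step: int, substep: int) -> np.uint64:
        with np.errstate(over="ignore"):
            b = np.uint64(self.seed & 0xFFFFFFFFFFFFFFFF)
            b = _splitmix64(np.uint64(b) + np.uint64(step) * _GOLDEN)
            return _splitmix64(b ^ (np.uint64(substep) * _PRIME))

    def pair_zeta(self, step: int, substep: int,
                  i: np.ndarray, j: np.ndarray) -> np.ndarray:
        """One zero-mean unit-variance variate per (i, j) pair."""
        base = self._base(step, substep)
        u = _keyed_uniform(base, i, j, 0)
        if self.kind == "uniform":
            return (2.0 * u - 1.0) * _SQRT3
        # Box-Muller; clamp u away from 0 to keep log finite
        u = np.maximum(u, 1e-300)
        u2 = _keyed_uniform(base, i, j, 1)
        return np.sqrt(-2.0 * np.log(u)) * np.cos(2.0 * np.pi * u2)


__all__ = ["NoiseStream"]
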