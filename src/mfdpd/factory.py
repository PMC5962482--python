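"""Named registries for the pluggable kernel components.

The factory pattern keeps integration schemes, noise kinds and force terms
replaceable without touching the engine: registering a new constructor
under a string key is all an extension needs.
"""

from __future__ import annotations

from .errors import ParameterError


class Registry:
    """A named string-key -> constructor mapping with helpful errors."""

    def __init__(self, name: str):
        self.name = name
        self._entries: dict = {}

    def register(self, key: str, ctor) -> None:
        self._entries[key] = ctor

    def get(self, key: str):
        if key not in self._entries:
            raise ParameterError(
                f"unknown {self.name} {key!r}; valid keys: "
                f"{', '.join(sorted(self._entries))}")
        return self._entries[key]

    def keys(self):
        return sorted(self._entries)

    def __contains__(self, key) -> bool:
        return key in self._entries


#: Integration schemes, filled in by :mod:`mfdpd.integrators` on import.
INTEGRATORS = Registry("integration scheme")

#: Random-variate kinds for the pair noise.
NOISE_KINDS = Registry("noise kind")

#: Force terms assembled by ``compute_all_forces``; the "estat" slot is the
#: extension hook for an electrostatics model (not implemented here).
FORCE_TERMS = Registry("force term")


def _register_noise_kinds():
    from .noise import NoiseStream
    for kind in NoiseStream.KINDS:
        NOISE_KINDS.register(
            kind, lambda seed, _k=kind: NoiseStream(seed, _k))


_register_noise_kinds()

__all__ = ["Registry", "INTEGRATORS", "NOISE_KINDS", "FORCE_TERMS"]
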