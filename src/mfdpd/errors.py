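"""Exception hierarchy for the simulation kernel."""


class MfdpdError(Exception):
    """Base class for all kernel errors."""


class ParameterError(MfdpdError):
    """An input parameter violates its contract (sign, range, shape)."""


class GeometryError(MfdpdError):
    """Box/grid geometry is unusable (e.g. an axis shorter than 3 cutoffs)."""


class ConsistencyError(MfdpdError):
    """Internal state is inconsistent (stale caches, out-of-box positions)."""


class DivergenceError(MfdpdError):
    """The integration produced non-finite or runaway coordinates."""


class ScheduleError(MfdpdError):
    """A valid lock-free chunk schedule could not be constructed."""


class RestartError(MfdpdError):
    """A restart file is corrupt, truncated or of an unknown version."""


class CommandFileError(MfdpdError):
    """Command-file parsing failed; ``errors`` lists every problem found."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("command file invalid:\n" + "\n".join(self.errors))
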