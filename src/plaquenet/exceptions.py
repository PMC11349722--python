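"""Exception hierarchy shared across the package."""


class PlaqueNetError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PlaqueNetError, ValueError):
    """An operator or model was configured with invalid hyperparameters."""


class ShapeError(PlaqueNetError, ValueError):
    """Array shapes are incompatible with the requested operation."""


class DataError(PlaqueNetError, ValueError):
    """Input data violates the operation's contract (labels, paths, formats)."""


class UsageError(PlaqueNetError, RuntimeError):
    """A component was invoked in a state that forbids it (e.g. disabled branch)."""


class InvariantViolation(PlaqueNetError, AssertionError):
    """A guaranteed model invariant failed at run time."""
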