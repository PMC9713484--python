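"""Exception hierarchy for shootphys."""


class ShootPhysError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ShootPhysError, ValueError):
    """A parameter set or config file is internally inconsistent or incomplete."""


class InvalidInputError(ShootPhysError, ValueError):
    """A physically impossible or degenerate input was supplied."""


class ParseError(ShootPhysError, ValueError):
    """A weather/config/table file violates its schema."""


class NoRootError(ShootPhysError, RuntimeError):
    """The energy-balance residual has no sign change in the search bracket."""


class StateCorruptionError(ShootPhysError, RuntimeError):
    """An internal state variable left its admissible region (e.g. negative reserves)."""
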