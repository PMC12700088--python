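"""Exception hierarchy shared across the package."""


class HifdynError(Exception):
    """Base class for all package errors."""


class ValidationError(HifdynError, ValueError):
    """An input value violates a documented precondition."""


class ConfigurationError(HifdynError):
    """A model/parameter/config inconsistency (e.g. missing parameter key)."""


class SimulationError(HifdynError):
    """ODE integration failed.

    Attributes
    ----------
    t_fail : float
        Time at which the integrator gave up.
    last_state : dict | None
        Last valid state vector, keyed by species name.
    """

    def __init__(self, message, t_fail=None, last_state=None):
        super().__init__(message)
        self.t_fail = t_fail
        self.last_state = last_state


class ParseError(HifdynError, ValueError):
    """A delimited input file could not be parsed."""
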