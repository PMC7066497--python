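"""Exception hierarchy for bgtcsim."""


class BgtcError(Exception):
    """Base class for all bgtcsim errors."""


class ConfigurationError(BgtcError):
    """Invalid parameter, option or configuration file."""


class IntegrationError(BgtcError):
    """The ODE solver failed to advance the solution.

    Attributes
    ----------
    time : float or None
        Simulation time (seconds) at which integration failed.
    """

    def __init__(self, message: str, time: float | None = None):
        super().__init__(message)
        self.time = time


class AnalysisError(BgtcError):
    """A spectral or phase analysis could not be performed on the input."""
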