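"""Exception hierarchy shared across the pipeline stages."""


class Mhc2xError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(Mhc2xError, ValueError):
    """A parameter violates a documented precondition."""


class InsufficientDataError(Mhc2xError, ValueError):
    """Not enough data points / records to perform the operation."""


class FitFailureError(Mhc2xError, RuntimeError):
    """A least-squares fit did not converge or produced an invalid result.

    Carries optional diagnostics in ``details``.
    """

    def __init__(self, message: str, details: dict | None = None):
        super().__init__(message)
        self.details = details or {}


class DisconnectedDataError(Mhc2xError, ValueError):
    """Trajectory data has no usable strongly connected state set."""


class DecompositionError(Mhc2xError, RuntimeError):
    """Spectral metastable decomposition is not supported by the data."""


class NumericalFailureError(Mhc2xError, RuntimeError):
    """A numerical routine failed beyond recoverable regularization."""


class ConfigError(Mhc2xError, ValueError):
    """Pipeline configuration does not validate."""
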