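"""Exception hierarchy for mvarnet."""


class MvarnetError(Exception):
    """Base class for all mvarnet errors."""


class ParameterError(MvarnetError, ValueError):
    """Invalid user-supplied parameter (density, alpha, weight range, ...)."""


class ShapeError(MvarnetError, ValueError):
    """Array with incompatible or non-square shape."""


class StabilityError(MvarnetError):
    """Connectivity whose companion spectral radius is >= 1 (non-stationary)."""


class DegenerateConfigurationError(MvarnetError):
    """Network configuration that could not be stabilized."""


class ConditioningError(MvarnetError):
    """Covariance matrix too ill-conditioned to invert safely."""

    def __init__(self, message, nodes=None):
        super().__init__(message)
        self.nodes = nodes


class UndefinedMetricError(MvarnetError):
    """Metric undefined for the given inputs (e.g. ROC with one class)."""
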