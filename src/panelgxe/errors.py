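"""Exception types shared across the pipeline."""


class PanelGxeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PanelGxeError, ValueError):
    """A scenario / model configuration is internally inconsistent."""


class CoverageError(PanelGxeError, ValueError):
    """Exposure series does not cover a requested date (plus lags)."""


class DataError(PanelGxeError, ValueError):
    """Input table violates a structural precondition."""


class ConvergenceError(PanelGxeError, RuntimeError):
    """An iterative fit failed to converge.

    ``last_state`` carries the final iterate for diagnostics.
    """

    def __init__(self, message, last_state=None):
        super().__init__(message)
        self.last_state = last_state
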