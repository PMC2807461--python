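"""Exception hierarchy shared across the package."""


class EmbImputeError(Exception):
    """Base class for all package errors."""


class PanelParseError(EmbImputeError):
    """A panel file could not be parsed (malformed rows, bad headers)."""


class ValidationError(EmbImputeError):
    """Input data or a mask specification violates an invariant."""


class ConfigError(EmbImputeError):
    """An imputation/tuning configuration is invalid."""


class SingularMatrixError(EmbImputeError):
    """A pivot or covariance block is numerically singular."""

    def __init__(self, message: str, index: int | None = None):
        super().__init__(message)
        self.index = index


class DegenerateDataError(EmbImputeError):
    """Too little observed data to estimate the model."""


class UndefinedCorrelationError(EmbImputeError):
    """Pearson correlation is undefined (constant input)."""


class TrialError(EmbImputeError):
    """A single tuning trial failed; carries the reason for the record."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason
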