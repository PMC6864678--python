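"""Exception hierarchy shared across the pipeline stages."""


class TeafluorError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TeafluorError):
    """Inconsistent or invalid pipeline configuration (grid, LED count, spec arithmetic)."""


class FormatError(TeafluorError):
    """Malformed measurement or file contents (wrong row count, bad CSV dialect)."""


class ParameterError(TeafluorError):
    """Invalid operation parameter (even smoothing window, too many components, ...)."""


class DegenerateSpectrumError(TeafluorError):
    """A spectrum cannot be normalized: non-positive maximum in the reference region."""

    def __init__(self, message: str, measurement_id: str | None = None):
        super().__init__(message)
        self.measurement_id = measurement_id
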