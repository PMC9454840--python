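"""Exception hierarchy shared across the package."""


class WellfieldError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(WellfieldError, ValueError):
    """A chamber description violates a geometric constraint."""


class InvalidWaveformError(WellfieldError, ValueError):
    """A pulse waveform is physically impossible (e.g. duty cycle > 1)."""


class InvalidScaleError(WellfieldError, ValueError):
    """Linear rescaling requested from a degenerate (0 V) solution."""


class ConfigurationError(WellfieldError, ValueError):
    """A run configuration or solve setup is invalid (schema violation,
    missing Dirichlet boundary, ...)."""


class IncompleteDataError(WellfieldError, ValueError):
    """A measurement set lacks the rows a diagnostic requires."""


class DataError(WellfieldError, ValueError):
    """A data file cannot be parsed; carries the offending line number
    when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
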