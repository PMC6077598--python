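"""Exception hierarchy shared across the pipeline stages."""


class HjdnetError(Exception):
    """Base class for all package-specific errors."""


class ParseError(HjdnetError):
    """Malformed input file; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DimensionMismatchError(HjdnetError, ValueError):
    """Descriptor vectors of unequal length were compared."""


class UndefinedInputError(HjdnetError, ValueError):
    """Input for which the requested quantity is mathematically undefined."""


class EmptyInputError(HjdnetError, ValueError):
    """An operation that requires at least one record received none."""


class DegenerateGraphError(HjdnetError, ValueError):
    """Graph too small (or otherwise degenerate) for the requested analysis."""


class ConfigError(HjdnetError, ValueError):
    """Invalid generator or pipeline configuration."""
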