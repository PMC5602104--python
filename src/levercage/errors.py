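"""Exception hierarchy for the lever-cage toolkit."""


class LeverCageError(Exception):
    """Base class for all package-specific errors."""


class MalformedTraceError(LeverCageError):
    """Lever trace is structurally invalid (too short, non-uniform sampling)."""


class InsufficientTraceError(LeverCageError):
    """Trace does not cover the requested analysis window."""


class AngleRangeError(LeverCageError):
    """Trace contains angles outside the lever's physical range."""


class AttributionError(LeverCageError):
    """A trial was detected while no animal was inside the chamber."""


class ConfigError(LeverCageError):
    """Task configuration violates an invariant."""


class ValidationError(LeverCageError):
    """Input stream violates an ordering/alternation contract."""


class ParseError(LeverCageError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
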