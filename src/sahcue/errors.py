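"""Exception hierarchy for the cost-utility engine."""


class SahcueError(Exception):
    """Base class for all package-specific errors."""


class ConfigFormatError(SahcueError):
    """The config file could not be parsed (carries line context when known)."""


class ConfigValidationError(SahcueError):
    """A parsed config value violates a model invariant; names the field."""


class DomainError(SahcueError, ValueError):
    """An operation argument is outside its mathematical domain."""


class CalibrationError(SahcueError):
    """Calibration anchors are internally inconsistent."""


class ConfigurationError(SahcueError):
    """A computation was requested that the supplied config cannot support."""


class UndefinedIcerError(SahcueError, ZeroDivisionError):
    """ICER requested with a zero QALY difference; not representable as a number."""
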