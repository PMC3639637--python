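"""Exception hierarchy shared by all aneuflow modules."""


class AneuflowError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AneuflowError, ValueError):
    """Invalid physical or numerical parameter combination."""


class GeometryError(AneuflowError, ValueError):
    """Inconsistent or degenerate domain geometry."""


class StabilityError(AneuflowError, RuntimeError):
    """A solver left its stable operating regime (NaN, supersonic velocity)."""


class AnalysisError(AneuflowError, ValueError):
    """Post-processing requested on incompatible or degenerate data."""
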