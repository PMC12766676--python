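"""Exception hierarchy shared across the package."""


class SunburstError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(SunburstError):
    """Input file does not conform to the expected tabular schema."""


class ValidationError(SunburstError):
    """A record or parameter violates a documented invariant."""


class DegenerateNullError(SunburstError):
    """The chance reference distribution is undefined (K < 2, N = 0 or sigma = 0)."""


class AnalysisError(SunburstError):
    """A pipeline stage could not be completed."""
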