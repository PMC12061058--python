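"""Exception hierarchy shared across the pipeline.

Every stage raises a subclass of :class:`FixtrackError`, so callers (and the
command-line front-end) can distinguish pipeline failures from programming
errors and report the offending stage.
"""


class FixtrackError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(FixtrackError):
    """A file does not conform to an interchange format (missing column, bad header)."""


class ValidationError(FixtrackError):
    """Parsed content violates a type invariant (e.g. non-monotone timestamps)."""


class DomainError(FixtrackError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class ArityError(FixtrackError):
    """Too few landmarks / samples for the requested estimation."""


class DegeneracyError(FixtrackError):
    """Geometrically degenerate configuration (collinear points, parallel lines)."""


class ChainingError(FixtrackError):
    """Two objects expressed in incompatible coordinate frames were combined."""


class MetadataError(FixtrackError):
    """Required metadata (laterality, fixation loss, ...) is absent or invalid."""


class InsufficientDataError(FixtrackError):
    """Not enough samples to compute the requested statistic."""
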