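"""Exception hierarchy.

All package errors derive from :class:`BrainGraphError` so callers can catch
one type; subclasses distinguish parse, validation, and numerical failures.
"""


class BrainGraphError(Exception):
    """Base class for all package errors."""


class ParseError(BrainGraphError, ValueError):
    """A file could not be parsed; the message names the offending line/element."""


class ValidationError(BrainGraphError, ValueError):
    """Input violates a structural invariant (duplicate labels, bad mode, ...)."""


class DimensionError(BrainGraphError, ValueError):
    """Array shape inconsistent with the atlas or with a paired input."""


class RankDeficiencyError(BrainGraphError, ValueError):
    """A regression design matrix is rank deficient."""


class UndefinedCorrelationError(BrainGraphError, ValueError):
    """Correlation undefined because one input has zero variance."""


class UndefinedMeasureError(BrainGraphError, ValueError):
    """A graph measure is undefined on this input (e.g. edgeless graph)."""


class ConfigError(BrainGraphError, ValueError):
    """Analysis configuration invalid."""
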