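"""Exception hierarchy.

Every error raised by this package derives from :class:`RehabCompassError`
so callers (and the CLI) can separate data problems from programming bugs.
"""


class RehabCompassError(Exception):
    """Base class for all package errors."""


class DefinitionError(RehabCompassError):
    """An instrument or mapping definition document is invalid."""


class ResponseValidationError(RehabCompassError):
    """An item-level response record violates its instrument definition."""


class ScoringError(RehabCompassError):
    """A scoring request cannot be fulfilled (unknown domain, bad raw value)."""


class ConsistencyError(RehabCompassError):
    """Cross-object inconsistency (mapping/score mismatch, snapshot mismatch)."""


class ConfigError(RehabCompassError):
    """A configuration value (palette, profile, render spec) is invalid."""
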