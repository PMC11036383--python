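"""Exception hierarchy for isowash.

All package-specific failures derive from :class:`IsowashError` so callers
can catch one base class at the CLI boundary.
"""


class IsowashError(Exception):
    """Base class for all isowash errors."""


class InvalidArgumentError(IsowashError, ValueError):
    """A scalar argument violates a documented precondition."""


class InvalidCompositionError(IsowashError, ValueError):
    """A liquid composition does not satisfy the sum-to-one invariant."""


class MissingSpeciesError(IsowashError, KeyError):
    """A composition references a species absent from the property table."""


class InvalidSeriesError(IsowashError, ValueError):
    """A filtrate volume-time series is too short or non-monotone."""


class InvalidStateError(IsowashError, ValueError):
    """An operation was applied to a cake/result in the wrong state."""

class InvalidCurveError(IsowashError, ValueError):
    """A washing curve violates monotonicity requirements."""


class InvalidSweepError(IsowashError, ValueError):
    """A design-space sweep is unsuitable for the requested analysis."""


class ConfigError(IsowashError, ValueError):
    """A run configuration failed schema validation."""
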