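"""Exception types shared across the pipeline."""


class TripwalkError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TripwalkError, ValueError):
    """A configuration field is out of its valid range; names the field."""


class OrderingError(TripwalkError, ValueError):
    """Input points are not sorted / deduplicated in time."""


class CoverageError(TripwalkError, ValueError):
    """Two streams that must cover the same clock span do not."""


class RoutingError(TripwalkError, ValueError):
    """No path exists between the requested endpoints."""


class SchemaError(TripwalkError, ValueError):
    """An unknown mode label or malformed record was encountered."""


class GridError(TripwalkError, ValueError):
    """The accelerometer epoch grid has gaps or misaligned epochs."""


class UndefinedRateError(TripwalkError, ZeroDivisionError):
    """A rate was requested with a zero denominator (e.g. zero wear time)."""


class IdentityError(TripwalkError, ValueError):
    """Participant identities of two inputs that must match do not."""


class InvalidStageError(TripwalkError, ValueError):
    """A trip stage is degenerate (e.g. empty polyline)."""
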