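"""Exception hierarchy.

All package errors derive from :class:`RYGBTrajError` so callers (and the
CLI) can distinguish domain failures from programming errors.
"""


class RYGBTrajError(Exception):
    """Base class for all package errors."""


class InvalidInputError(RYGBTrajError, ValueError):
    """A scalar/array input is non-finite, non-positive, or otherwise malformed."""


class RangeError(RYGBTrajError, ValueError):
    """A query lies outside a model's validity ranges and extrapolation is off."""


class SchemaError(RYGBTrajError, ValueError):
    """A serialized document (JSON/CSV) does not match the documented schema."""


class EmptyInputError(RYGBTrajError, ValueError):
    """An operation that requires at least one record received none."""


class ConfigurationError(RYGBTrajError, ValueError):
    """Inconsistent or incomplete configuration (missing profile fields, bad spec)."""


class RankError(RYGBTrajError, ValueError):
    """Design matrix is rank deficient."""


class ConvergenceError(RYGBTrajError, RuntimeError):
    """The optimizer failed to certify an optimum."""

    def __init__(self, message: str, metadata: dict | None = None):
        super().__init__(message)
        self.metadata = metadata or {}


class CrossingError(RYGBTrajError, RuntimeError):
    """Quantile curves cross at a query point where non-crossing is required."""
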