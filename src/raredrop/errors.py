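"""Exception hierarchy for raredrop.

All library errors derive from :class:`RaredropError` so callers can catch
domain failures without masking programming errors.
"""


class RaredropError(Exception):
    """Base class for all raredrop domain errors."""


class InvalidParameterError(RaredropError, ValueError):
    """A parameter violates its contract (sign, range, or count)."""


class SchemaError(RaredropError, ValueError):
    """An input table is missing required columns for its dialect."""


class ValidationError(RaredropError, ValueError):
    """An input row carries a value that violates a field invariant."""


class MissingDataError(RaredropError):
    """A required value is null/absent where the operation needs it."""


class SaturatedWellError(RaredropError):
    """Every partition is positive: the Poisson estimate is unbounded."""


class EmptyWellError(RaredropError):
    """A well contains no partition records."""


class EmptyCohortError(RaredropError):
    """No cohort rows survive filtering."""


class UndefinedVafError(RaredropError):
    """Variant allele frequency is undefined (both concentrations zero)."""


class UnfittableModelError(RaredropError):
    """Too few usable observations to fit the requested model."""


class UnreachableTargetError(RaredropError):
    """The requested detection probability cannot be reached."""
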