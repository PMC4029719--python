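"""Exception hierarchy used across the package.

All errors derive from :class:`EmgExoError` so callers can catch the whole
family; most also derive from ``ValueError`` for ergonomic use in scripts.
"""


class EmgExoError(Exception):
    """Base class for all package errors."""


class InvalidConfigurationError(EmgExoError, ValueError):
    """A configuration object violates its invariants."""


class InvalidInputError(EmgExoError, ValueError):
    """Operation input violates a precondition (shape, finiteness, range)."""


class EmptyFeatureError(EmgExoError, ValueError):
    """A trace is too short to yield a single feature window."""


class CannotSplitError(EmgExoError, ValueError):
    """Dataset has too few trials to be partitioned."""


class TrainingFailureError(EmgExoError, RuntimeError):
    """Training diverged; carries the offending epoch."""

    def __init__(self, message: str, epoch: int | None = None):
        super().__init__(message)
        self.epoch = epoch


class RangeExceededError(EmgExoError, ValueError):
    """A contraction rate left its admissible interval; names the muscle."""


class SaturationError(EmgExoError, ValueError):
    """A pressure or voltage command left its admissible interval."""


class SingularConfigurationError(EmgExoError, ValueError):
    """Force/pressure inversion hit a zero denominator."""


class UndefinedStatisticError(EmgExoError, ValueError):
    """A statistic is undefined for the given data (e.g. zero variance)."""
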