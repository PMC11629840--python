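"""Exception hierarchy for the premo package.

All errors raised by the library derive from :class:`PremoError` so callers
(and the CLI) can distinguish domain failures from programming errors.
"""


class PremoError(Exception):
    """Base class for all premo-specific errors."""


class InputError(PremoError, ValueError):
    """A supplied value violates an input contract (missing field, bad range)."""


class AlreadyMyopicError(InputError):
    """Baseline selected SER is at or below the myopia threshold (-0.50 D).

    The risk indicator is defined only for children who are not yet myopic,
    so scoring a myopic baseline is refused rather than silently clamped.
    """


class BandError(InputError):
    """Baseline age falls outside the supported 6-8 / 9-10 year age bands."""


class OutcomeUnresolvableError(InputError):
    """The available outcome information cannot be turned into a myopia label."""


class SchemaError(InputError):
    """A cohort file is missing mandatory columns or has a malformed header."""


class SingleClassError(PremoError):
    """ROC analysis requires at least one myope and one non-myope."""


class UndefinedMetricError(PremoError):
    """A diagnostic metric has a zero denominator (empty outcome class)."""
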