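"""Exception hierarchy for nirsmvpa.

All validation failures raise a subclass of :class:`NirsMvpaError` whose
message names the offending subject, channel or condition, so callers can
surface actionable diagnostics rather than bare assertion failures.
"""


class NirsMvpaError(Exception):
    """Base class for all package-specific errors."""


class DatasetValidationError(NirsMvpaError):
    """A dataset (or one of its recordings/events) violates an invariant."""


class MissingSubjectFileError(DatasetValidationError):
    """A time-series or events file declared in the config is absent."""


class ChannelMismatchError(DatasetValidationError):
    """A subject's time-series file does not expose a required channel."""


class UnknownConditionError(DatasetValidationError):
    """An event carries a condition label outside the declared set."""


class MissingConditionTrialsError(DatasetValidationError):
    """A subject has zero trials for one of the conditions."""


class EventOutOfBoundsError(DatasetValidationError):
    """An event onset lies outside the recording duration."""


class TrialOutOfBoundsError(NirsMvpaError):
    """An analysis window shifted to a trial onset exceeds recording bounds."""


class NonFiniteDataError(NirsMvpaError):
    """Non-finite HbO samples inside an analysis window."""


class DegeneratePatternError(NirsMvpaError):
    """A pattern vector is constant across channels: Pearson r is undefined."""


class InsufficientSubjectsError(NirsMvpaError):
    """Too few subjects for the requested analysis."""


class ResultWriteError(NirsMvpaError):
    """A result object cannot be serialised (e.g. empty outcome list)."""
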