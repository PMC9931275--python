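"""Exception hierarchy for sleepval.

All package-specific errors derive from :class:`SleepvalError` so callers can
catch everything from one base class while tests target the precise failure.
"""


class SleepvalError(Exception):
    """Base class for all sleepval errors."""


class CohortFormatError(SleepvalError):
    """A cohort CSV file does not conform to the expected layout."""


class StageVocabularyError(CohortFormatError):
    """A stage string is not one of W, N1, N2, N3, R, U."""


class CohortIntegrityError(SleepvalError):
    """Rows parse but violate a dataset invariant (gaps, length mismatch)."""


class EpochIncompatibilityError(SleepvalError):
    """Two hypnograms cannot be compared (different epoch durations)."""


class AlignmentError(SleepvalError):
    """Two labelings passed to an epoch-wise comparison differ in length."""


class EmptyComparisonError(SleepvalError):
    """No co-scored epochs exist for a requested scorer pair."""


class InsufficientDataError(SleepvalError):
    """Too few complete observations for the requested statistic."""


class UndefinedOnsetError(SleepvalError):
    """An operation requires a sleep onset that does not exist."""


class ConfigurationError(SleepvalError):
    """A run or generator configuration is invalid."""


class PipelineError(SleepvalError):
    """A pipeline stage failed; the message names the stage and cause."""
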