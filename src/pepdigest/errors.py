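"""Exception hierarchy.

Every error raised by this package derives from :class:`PepdigestError`,
so callers (and the CLI) can catch pipeline failures in one place.
"""


class PepdigestError(Exception):
    """Base class for all package errors."""


class SequenceFormatError(PepdigestError):
    """Malformed sequence input (empty FASTA stream, missing header, ...)."""


class SequenceValidationError(PepdigestError):
    """A residue outside the 20-letter amino-acid alphabet."""

    def __init__(self, message: str, record: str | None = None, position: int | None = None):
        super().__init__(message)
        self.record = record
        self.position = position  # 1-based


class SchemaError(PepdigestError):
    """A tabular input is missing a required column."""


class TableParseError(PepdigestError):
    """A cell failed to parse (carries the offending 0-based row index)."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class DuplicateRecordError(PepdigestError):
    """Duplicate (sequence, activity_class) pair in an activity table."""


class UnknownEnzymeError(PepdigestError, LookupError):
    """Requested enzyme is not in the built-in registry."""


class ConsistencyError(PepdigestError):
    """Inputs that must describe the same protein or activity class do not."""


class MissingScoreError(PepdigestError):
    """A record lacks the bioactivity-score annotation needed for ranking."""


class UndefinedStatisticError(PepdigestError):
    """A statistic is undefined for the given input (e.g. constant vector)."""


class PlacementError(PepdigestError):
    """Synthetic motif placement failed after bounded retries."""
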