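"""Exception hierarchy for broilerseq.

Every declared failure mode raises a subclass of :class:`BroilerSeqError`,
so callers (and the CLI) can catch one base class and still discriminate.
"""

from __future__ import annotations


class BroilerSeqError(Exception):
    """Base class for all broilerseq errors."""


class UnknownCodeError(BroilerSeqError):
    """A behavior token is not present in the ethogram registry."""


class EnvironmentViolationError(BroilerSeqError):
    """An enriched-only behavior was used in a non-enriched environment."""


class OverlapError(BroilerSeqError):
    """Two bouts of the same broiler overlap in time within one window."""


class WindowRangeError(BroilerSeqError):
    """A bout refers to a window index or onset outside the configured grid."""


class DuplicateSidError(BroilerSeqError):
    """Two sequences in one database share a Sequence-Id."""


class PatternParseError(BroilerSeqError):
    """Malformed pattern notation (unbalanced braces, unknown codes, ...)."""


class SchemaError(BroilerSeqError):
    """A tabular input file violates the documented schema.

    ``rows`` lists the offending 1-based row numbers when applicable.
    """

    def __init__(self, message: str, rows: list[int] | None = None):
        self.rows = rows or []
        if self.rows:
            message = f"{message} (rows: {', '.join(map(str, self.rows))})"
        super().__init__(message)


class EmptyDatabaseError(BroilerSeqError):
    """Mining or support counting was requested on an empty database."""


class MixedSizeError(BroilerSeqError):
    """Candidate generation received seed patterns of unequal item counts."""


class InvalidMinsupError(BroilerSeqError):
    """Minimum support outside the half-open interval (0, 1]."""


class BudgetExceededError(BroilerSeqError):
    """The brute-force oracle was asked to enumerate beyond its bounds."""


class InvalidLevelsError(BroilerSeqError):
    """A sweep level grid is not strictly decreasing within (0, 1]."""


class CapacityError(BroilerSeqError):
    """A pattern cannot be spliced into the configured window grid."""


class InvalidPresetError(BroilerSeqError):
    """A simulation preset has an unnormalizable transition row."""
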