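"""Exception hierarchy shared across the package."""

from __future__ import annotations


class TherapyRecError(Exception):
    """Base class for all package errors."""


class CatalogFormatError(TherapyRecError):
    """The catalog (or lexicon/log) file could not be parsed.

    Carries the offending location in the message where known.
    """


class ValidationError(TherapyRecError):
    """One or more invariant violations, collected exhaustively.

    ``violations`` lists every problem found so that authors can fix a
    file in one pass instead of replaying fail-fast errors.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "%d validation error(s):\n  - %s"
            % (len(self.violations), "\n  - ".join(self.violations))
        )


class DomainError(TherapyRecError):
    """A well-formed request referencing something that does not exist
    (unknown sub-tag, unknown step id, ...)."""


class UsageError(TherapyRecError):
    """The caller supplied unusable arguments (blank query, empty log
    where a denominator is required)."""


class StateError(TherapyRecError):
    """An operation was invoked in the wrong state (e.g. finishing a
    chat before the dialog is done)."""
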