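"""Exception hierarchy for engagekit.

All package errors derive from :class:`EngageKitError` so callers can catch a
single base class at pipeline boundaries (the CLI maps them to stage-named
diagnostics and a nonzero exit status).
"""

from __future__ import annotations


class EngageKitError(Exception):
    """Base class for all engagekit errors."""


class ConfigurationError(EngageKitError):
    """An invalid simulator or pipeline configuration; names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field {field!r}: {message}")


class CohortValidationError(EngageKitError):
    """Structural violations in a cohort; carries record locators."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        shown = "; ".join(self.problems[:5])
        more = "" if len(self.problems) <= 5 else f" (+{len(self.problems) - 5} more)"
        super().__init__(f"{len(self.problems)} validation problem(s): {shown}{more}")


class UndefinedInputError(EngageKitError):
    """An operation was called on input for which it is mathematically undefined
    (e.g. a subindex for a participant with zero sessions)."""


class DegenerateDistributionError(EngageKitError):
    """Distribution diagnostics requested for a constant (zero-variance) sample."""


class EmptyCohortError(EngageKitError):
    """No analyzable participant remains after validation/filtering."""


class ConsistencyError(EngageKitError):
    """Internally inconsistent inputs (e.g. a count exceeding its cohort maximum)."""


class BoundsError(EngageKitError):
    """A value fell outside its documented bounds (e.g. a subindex outside [0, 100])."""
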