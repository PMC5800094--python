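"""Exception hierarchy.

Every error a caller is expected to branch on has its own class; the CLI maps
a subset of these to distinct exit codes.
"""


class DiaplanError(Exception):
    """Base class for all package errors."""


class MalformedProfileError(DiaplanError):
    """A profile document violates the profile schema."""


class UnknownCodeError(DiaplanError):
    """A clinical record code does not resolve against the KB vocabulary."""


class UnitError(DiaplanError):
    """A lab result carries the wrong unit for its test."""


class UnresolvedCodeError(DiaplanError):
    """A knowledge-base entry references a code that is not defined."""


class KBConflictError(DiaplanError):
    """Conflicting knowledge-base content (duplicate ids, invalid templates)."""


class UnsafeRuleError(DiaplanError):
    """A rule uses a variable outside the bindings of its positive antecedent."""


class InvalidAnthropometryError(DiaplanError, ValueError):
    """Non-positive weight or height passed to the metabolic-rate formula."""


class UnknownActivityLevelError(DiaplanError, KeyError):
    """Activity level not present in the activity-factor table."""


class NoEligibleDrugError(DiaplanError):
    """No drug in the requested class survives contraindication/cost filters."""


class NotIndicatedError(DiaplanError):
    """No diabetes diagnosis was derived; drug planning is not indicated."""


class ManualReviewRequiredError(DiaplanError):
    """Every candidate drug class is contraindicated; a clinician must decide."""


class NothingToFollowUpError(DiaplanError):
    """Follow-up requested for a patient without an active, due plan."""


class UnsupportedQueryError(DiaplanError):
    """Cohort query selector is not one of the supported competency questions."""


class BadCohortSpecError(DiaplanError):
    """Synthetic-cohort specification fails validation."""
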