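"""Exception hierarchy for superrec.

Input problems raise a subclass of :class:`ValidationError`; the two
existence conditions have dedicated error classes so callers can tell a
curable gene-order conflict (switch to the unordered model) from a fatal
tree conflict.
"""


class SuperRecError(Exception):
    """Base class for all superrec errors."""


class ValidationError(SuperRecError):
    """An input object violates a model invariant."""


class DuplicateGeneError(ValidationError):
    """The same gene identifier occurs twice."""


class UnknownGeneError(ValidationError):
    """A gene tree leaf has no entry in the synteny table."""


class FamilyInjectivityError(ValidationError):
    """Two genes of the same family occur in one synteny."""


class NonBinaryTreeError(ValidationError):
    """An input tree that must be binary is not."""


class SyntenyTableError(ValidationError):
    """Malformed synteny table (bad header, positions, species, ...)."""


class InvalidHistoryError(ValidationError):
    """A labeled history violates the event model's edge constraints."""


class OrderInconsistencyError(SuperRecError):
    """Gene orders conflict: the precedence graph is cyclic, so no
    ordered Super-Reconciliation exists (the unordered model may still
    apply)."""


class TreeInconsistencyError(SuperRecError):
    """The synteny trees are incompatible: no supertree displays them
    all, so no Super-Reconciliation of any kind exists."""


class ResourceLimitError(SuperRecError):
    """A computation would exceed a configured size budget."""


class OracleGuardError(SuperRecError):
    """A brute-force oracle was called on an instance above its size
    guard."""
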