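"""Exception hierarchy for the threemode package.

All errors raised deliberately by this package derive from
:class:`ThreeModeError`, which itself derives from :class:`ValueError`,
so callers can catch either the specific condition or everything at once.
"""


class ThreeModeError(ValueError):
    """Base class for all errors raised by threemode."""


class ValidationError(ThreeModeError):
    """An input failed a precondition (shape, range, or consistency)."""


class RankAdmissibilityError(ValidationError):
    """A Tucker3 rank triple violates P <= Q*R (and cyclic variants)."""


class DuplicateRecordError(ValidationError):
    """A long-format table contains the same (person, time, item) cell twice."""


class ParseError(ValidationError):
    """A long-format table cell could not be parsed as a number."""


class EmptySelectionError(ThreeModeError):
    """Sample selection removed every person."""


class IncompleteInputError(ValidationError):
    """An operation requiring a complete cube received masked cells."""


class DegenerateItemError(ThreeModeError):
    """An item slab has zero variance and cannot be normalized."""


class DegenerateDesignError(ValidationError):
    """A factorial decomposition needs at least two levels per mode."""


class UnimputableColumnError(ThreeModeError):
    """A flattened column has no observed entries at all."""


class UndefinedFitError(ThreeModeError):
    """Fit percentage requested against a cube with zero sum of squares."""


class UndefinedCongruenceError(ThreeModeError):
    """Congruence requested for a zero vector."""


class PoolingError(ThreeModeError):
    """Objects to be pooled do not share keys or shapes."""


class SelectionError(ThreeModeError):
    """Model-complexity selection received an empty or unusable grid."""


class MissingArtifactError(ThreeModeError):
    """A pipeline stage needs an artifact that a previous stage did not write."""
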