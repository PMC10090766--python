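"""Exception hierarchy for data and design errors.

All exceptions derive from :class:`CommdecayError` so callers can catch
package errors as a group; most also derive from ``ValueError`` because they
signal invalid input values or shapes.
"""


class CommdecayError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CommdecayError, ValueError):
    """A file is missing required columns or has a malformed header."""


class ConsistencyError(CommdecayError, ValueError):
    """Cross-record contradiction (e.g. one host mapped to two species)."""


class RangeError(CommdecayError, ValueError):
    """A value falls outside its documented domain (e.g. latitude 95)."""


class AlignmentError(CommdecayError, ValueError):
    """Sequences in an alignment are not all the same length."""


class AlphabetError(CommdecayError, ValueError):
    """A sequence contains characters outside {A, C, G, T, N, -, U}."""


class DimensionError(CommdecayError, ValueError):
    """Vector or matrix shapes do not match."""


class DomainError(CommdecayError, ValueError):
    """A mathematically undefined operation was requested."""


class UndefinedSimilarityError(DomainError):
    """Similarity requested between two communities with no content."""


class UndefinedDistanceError(DomainError):
    """A sequence pair has zero comparable sites under pairwise deletion."""


class DesignError(CommdecayError, ValueError):
    """A statistical design is degenerate (e.g. a single group)."""


class SingularDesignError(DesignError):
    """The model matrix is rank deficient / perfectly collinear."""


class ConvergenceError(CommdecayError, RuntimeError):
    """An iterative fit failed to converge within its iteration budget."""


class ConfigError(CommdecayError, ValueError):
    """An unknown option or inconsistent configuration was supplied."""
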