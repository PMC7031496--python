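"""Named error types raised by input validation.

Validation is fail-fast: malformed inputs raise a specific exception rather
than being silently coerced, so a pipeline run either sees exactly the data
it was given or stops.
"""


class CulpritError(Exception):
    """Base class for all package-specific errors."""


class MalformedHeaderError(CulpritError):
    """Expression TSV header row is missing or not parseable."""


class NonNumericValueError(CulpritError):
    """A cell of the expression matrix is not a finite number >= 0."""


class DuplicateIdError(CulpritError):
    """Duplicate gene or sample identifiers in an input table."""


class UnannotatedSampleError(CulpritError):
    """A sample in the expression matrix has no group annotation."""


class MalformedGeneSetError(CulpritError):
    """A GMT line has fewer than the required name/description/member fields."""


class InvalidConfigError(CulpritError):
    """Inconsistent generator or analysis parameters."""


class DegenerateInputError(CulpritError):
    """An operation received input on which its statistic is undefined
    (e.g. a stratum with too few samples, a constant score vector)."""
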