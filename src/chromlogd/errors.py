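"""Exception hierarchy.

Every error raised on a bad input names the offending compound, field or
measurement so that failures in multi-stage runs are attributable.
"""


class ChromLogDError(Exception):
    """Base class for all package-specific errors."""


class TableParseError(ChromLogDError):
    """A cell in a compound or retention table could not be parsed."""


class DuplicateIdError(ChromLogDError):
    """A compound id occurs more than once where uniqueness is required."""


class UnknownIdError(ChromLogDError, KeyError):
    """A requested compound id is not present in the dataset."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message plain
        return Exception.__str__(self)


class MissingValueError(ChromLogDError):
    """A required descriptor or response value is missing for a compound."""


class RetentionDomainError(ChromLogDError, ValueError):
    """Retention input outside its physical domain (e.g. t_R < t_0)."""


class SingularDesignError(ChromLogDError):
    """A regression design matrix is rank deficient or degenerate."""


class AssemblyError(ChromLogDError):
    """A cascade training set did not assemble to its required size."""


class LeakageError(ChromLogDError):
    """A validation compound appears in the training set it must be held out of."""


class LowPointCountWarning(UserWarning):
    """Fewer retention points than the recommended minimum for an LSS fit."""


class FitQualityWarning(UserWarning):
    """A fit fell below the configured quality gate (warn, never drop)."""


class DataQualityWarning(UserWarning):
    """A dataset invariant that is advisory rather than fatal was violated."""
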