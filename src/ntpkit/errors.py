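"""Exception and warning types shared across the package."""


class NtpkitError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(NtpkitError, ValueError):
    """Input violates a documented precondition or container invariant."""


class ParseError(NtpkitError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class CoverageError(ValidationError):
    """Too few of a template class's genes are present in the data."""


class DerivationError(NtpkitError):
    """Template derivation left a class with no genes."""


class UndefinedStatisticError(NtpkitError):
    """A requested statistic is undefined for the given input (e.g. a
    zero-norm vector in a cosine similarity, or an accuracy over zero
    assigned samples)."""


class SmallCohortWarning(UserWarning):
    """Centering/scaling statistics are estimated from few samples.

    Cross-sample standardization makes predictions sensitive to cohort
    composition; below roughly forty samples this introduces appreciable
    prediction uncertainty.
    """


class DegenerateDataWarning(UserWarning):
    """Degenerate input (constant rows/values, empty results) handled by a
    documented fallback rather than an error."""
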