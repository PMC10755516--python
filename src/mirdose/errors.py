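"""Exception hierarchy for the dosimetry pipeline.

Every error raised by mirdose derives from :class:`DosimetryError`, so callers
(and the CLI, which maps them to exit code 2) can catch one type.
"""


class DosimetryError(Exception):
    """Base class for all mirdose errors."""


class InsufficientDataError(DosimetryError):
    """Too few data points for the requested operation."""


class DegenerateInputError(DosimetryError):
    """Input is structurally valid but carries no usable signal (e.g. all zeros)."""


class FitFailureError(DosimetryError):
    """Curve fit did not converge after multi-start."""


class InvalidFitError(DosimetryError):
    """A TACFit violates its invariants (e.g. non-positive rate)."""


class MissingInputError(DosimetryError):
    """A required optional input was not supplied (e.g. hybrid TIA without data)."""


class UnscalableError(DosimetryError):
    """Reference curve value at the measurement time is at or below the floor."""


class MissingReferenceError(DosimetryError):
    """No cycle-1 reference fit for the requested patient/region."""


class SchemaError(DosimetryError):
    """Unknown organ label against the S-matrix schema."""


class InvalidInputError(DosimetryError):
    """Numerically invalid input (negative activity, out-of-range p-value, ...)."""


class InvalidActivityError(InvalidInputError):
    """Injected activity must be strictly positive."""


class InvalidParameterError(DosimetryError):
    """Physical model parameter out of its admissible range."""


class InconsistencyError(DosimetryError):
    """Mass-balance inconsistency (organ activity exceeding whole body)."""


class UndefinedRatioError(DosimetryError):
    """Relative difference undefined because the denominator is not positive."""


class RankDeficiencyError(DosimetryError):
    """Hotelling test needs more subjects than variables (n > p)."""


class SingularCovarianceError(DosimetryError):
    """Sample covariance of paired differences is singular."""


class NoTerminalPhaseError(DosimetryError):
    """No decreasing terminal phase found in the concentration data."""


class AlignmentError(DosimetryError):
    """Truth and estimate tables do not share the same keys."""


class DesignError(DosimetryError):
    """Inconsistent synthetic-cohort design."""


class ParseError(DosimetryError):
    """Malformed input file; message carries the offending row/column."""


class ConfigError(DosimetryError):
    """Invalid run configuration."""
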