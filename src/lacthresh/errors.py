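"""Exception hierarchy for the lacthresh pipeline.

Every contract violation raises a subclass of :class:`LacthreshError`, so
callers can catch pipeline-specific failures without masking programming
errors.
"""


class LacthreshError(Exception):
    """Base class for all lacthresh errors."""


class SchemaError(LacthreshError):
    """A required column or schema entry is missing or malformed."""


class ValidationError(LacthreshError):
    """Cohort data violates a schema invariant (e.g. outcome not in {0,1})."""


class UnimputableError(LacthreshError):
    """A column scheduled for imputation has no observed values."""


class DegenerateBinningError(LacthreshError):
    """Exposure has too few distinct values to form quartile bins."""


class DegenerateTableError(LacthreshError):
    """A contingency table has a zero row or column marginal."""


class DegenerateOutcomeError(LacthreshError):
    """Outcome has a single class; a logistic model cannot be fit."""


class SeparationError(LacthreshError):
    """Complete or quasi-complete separation detected during fitting."""


class CollinearityError(LacthreshError):
    """Design matrix is rank deficient; names the aliased terms."""

    def __init__(self, message, aliased=()):
        super().__init__(message)
        self.aliased = tuple(aliased)


class SegmentDegeneracyError(LacthreshError):
    """A piecewise segment contains no events or no non-events."""

    def __init__(self, message, side):
        super().__init__(message)
        self.side = side  # "below" or "above"


class SearchFailureError(LacthreshError):
    """No feasible turning-point candidate could be fit."""


class NestingError(LacthreshError):
    """Likelihood-ratio nesting violated (piecewise LL below linear LL)."""


class UnstableBootstrapError(LacthreshError):
    """More than the tolerated fraction of bootstrap replicates failed."""

    def __init__(self, message, n_failed, n_total):
        super().__init__(message)
        self.n_failed = n_failed
        self.n_total = n_total


class StratificationError(LacthreshError):
    """A stratifier produced an empty or constant stratum."""


class BasisError(LacthreshError):
    """Spline basis construction failed (rank deficient / too few values)."""


class CalibrationError(LacthreshError):
    """Generator intercept calibration could not reach the target rate."""


class ProvenanceError(LacthreshError):
    """Operation requires a cohort generated by the synthetic module."""


class ConfigError(LacthreshError):
    """Run configuration is invalid."""
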