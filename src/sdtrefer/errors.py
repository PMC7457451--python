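"""Exception hierarchy for study-data validation and model fitting."""


class SdtReferError(Exception):
    """Base class for all package errors."""


class ValidationError(SdtReferError):
    """Base class for input-table validation failures."""


class MissingColumnError(ValidationError):
    """A required column is absent from an input table."""


class UnknownLabelError(ValidationError):
    """A categorical field holds a value outside its enumeration."""


class OrphanReferenceError(ValidationError):
    """A response references a responder or vignette that does not exist."""


class DuplicateResponseError(ValidationError):
    """The same (responder, vignette, task) key appears more than once."""


class SignalClassMismatchError(ValidationError):
    """A vignette's stored class contradicts the 3% risk threshold."""


class EmptyDatasetError(ValidationError):
    """An operation received a dataset with no usable responses."""


class UndefinedRatesError(SdtReferError):
    """Hit/false-alarm rates are undefined for a responder (no positive
    or no negative trials)."""


class RateDomainError(SdtReferError):
    """A rate of exactly 0 or 1 was passed where an interior rate is
    required; apply the 0.5 count correction first."""


class SeparationError(SdtReferError):
    """A probit fit met complete separation on some covariate."""


class NotConvergedError(SdtReferError):
    """A model result flagged as non-converged was used where a converged
    fit is required."""


class RankDeficientError(SdtReferError):
    """The regression design matrix is rank deficient."""


class UndefinedProportionError(SdtReferError):
    """Proportion mediated is undefined because the total effect is zero."""
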