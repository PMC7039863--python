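"""Exception and warning types shared across the pipeline."""


class SulfurCensusError(Exception):
    """Base class for all package errors."""


class MissingTrainingError(SulfurCensusError):
    """A training set has no positive sequences."""


class AlignmentShapeError(SulfurCensusError):
    """Aligned training sequences do not share a common length."""


class AlphabetError(SulfurCensusError):
    """A sequence contains symbols outside the protein alphabet."""


class EmptyInputError(SulfurCensusError):
    """An operation received an empty sequence or collection it cannot handle."""


class CalibrationUnderpoweredError(SulfurCensusError):
    """Too few decoys requested for a stable extreme-value fit."""


class CalibrationMissingError(SulfurCensusError):
    """A profile is used for searching before its cutoff/E-value calibration."""


class ParameterError(SulfurCensusError):
    """A numeric parameter is outside its valid range."""


class DivisionGuardError(SulfurCensusError):
    """A length or mass that would be used as a divisor is zero."""


class UndefinedDenominatorError(SulfurCensusError):
    """A community fraction was requested for a sample with no marker signal."""


class TaxonomyIntegrityError(SulfurCensusError):
    """A hit references a taxon absent from the taxonomy tree."""


class CalibrationInputError(SulfurCensusError):
    """Calibration standards are insufficient (fewer than three distinct points)."""


class DegenerateCalibrationError(SulfurCensusError):
    """The fitted calibration line has zero slope."""


class GroupingError(SulfurCensusError):
    """An environment-ratio group is empty or has a zero mean."""


class UnitMismatchError(SulfurCensusError):
    """Sediment (per-gram) and seawater (per-litre) values mixed without a bridge flag."""


class NonSeparableTrainingWarning(UserWarning):
    """Negatives overlap positives; the family cutoff falls back to the minimum positive score."""


class MissingNegativesWarning(UserWarning):
    """A family has no negative references; verification falls back to cutoff-only."""


class MultiCopyFractionWarning(UserWarning):
    """A community fraction exceeded 100%, as can happen for multi-copy families."""


class AbsentFamilyWarning(UserWarning):
    """A requested carriage fraction rounded to zero carriers in a synthetic community."""
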