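"""Exception types raised across the toolkit.

Every error that callers are expected to handle programmatically gets its
own class; all inherit from :class:`ClonerxError` so a pipeline driver can
catch the package's failures without masking genuine bugs.
"""


class ClonerxError(Exception):
    """Base class for all clonerx errors."""


# --- reference database assembly ---------------------------------------------


class OutOfRangeError(ClonerxError):
    """Query dose lies outside the measured span of a viability curve."""


class EmptyJoinError(ClonerxError):
    """No perturbation record survived the inner join with viability curves."""


class ParseError(ClonerxError):
    """A SMILES string could not be parsed."""


# --- response model -----------------------------------------------------------


class InsufficientDataError(ClonerxError):
    """Too few training rows to fit the inhibition regressor."""


class SchemaMismatchError(ClonerxError):
    """Signature or fingerprint length differs from the fitted feature schema."""


# --- clone pipeline ------------------------------------------------------------


class AllCellsRemovedError(ClonerxError):
    """Quality-control filtering removed every cell."""


class ZeroCellError(ClonerxError):
    """A cell has zero total counts and cannot be normalized."""


class NoMarkersFoundError(ClonerxError):
    """None of the marker genes are present in the expression matrix."""


class NoReferenceError(ClonerxError):
    """No (or too few) normal reference cells available for CNV centring."""


class TooFewMalignantCellsError(ClonerxError):
    """Not enough consensus-malignant cells for subclone detection."""


class GroupTooSmallError(ClonerxError):
    """A differential-expression group has fewer than the minimum cells."""


# --- therapy design -------------------------------------------------------------


class EmptyAfterFiltersError(ClonerxError):
    """No prediction survived the confidence and dose filters."""


class NoValidPairsError(ClonerxError):
    """Every candidate drug pair shares a drug; no combination can be formed."""


# --- pharmacometrics -------------------------------------------------------------


class DegenerateControlsError(ClonerxError):
    """Positive-control signal is not below the negative control."""


class FitFailureError(ClonerxError):
    """Nonlinear dose-response fit failed to converge."""


class InvalidRangeError(ClonerxError):
    """Requested integration range is empty or non-positive."""


class OneClassOnlyError(ClonerxError):
    """ROC analysis requires both positive and negative labels."""
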