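"""Exception and warning hierarchy shared by all vcgrn modules."""


class VcgrnError(Exception):
    """Base class for all package-specific errors."""


class DuplicateIdentifier(VcgrnError):
    """A gene, sample or set identifier occurs more than once."""


class ParseError(VcgrnError):
    """A file cell or line could not be interpreted."""


class MissingValue(VcgrnError):
    """An expression cell is empty/NaN and the policy is to reject."""


class IOFailure(VcgrnError):
    """A path could not be read or written."""


class EmptySeed(VcgrnError):
    """A seed gene set shares no members with the expression matrix."""


class CoherenceFailure(VcgrnError):
    """Coherence filtering left fewer genes than the required minimum."""


class DegenerateInput(VcgrnError):
    """Input carries no usable signal (e.g. a constant submatrix)."""


class InvalidBandwidth(VcgrnError):
    """Kernel bandwidth must be strictly positive."""


class DegenerateDesign(VcgrnError):
    """Every candidate predictor has zero weighted variance."""


class ConvergenceFailure(VcgrnError):
    """Coordinate descent did not converge within the sweep budget."""


class InvalidParameter(VcgrnError):
    """A numeric parameter is outside its admissible range."""


class FoldTooSmall(VcgrnError):
    """A cross-validation fold leaves too few training samples."""


class UnknownIdentifier(VcgrnError):
    """A requested gene is absent from the relevant vocabulary."""


class EmptyInput(VcgrnError):
    """An operation received an empty table where data is required."""


class InvalidInput(VcgrnError):
    """Structurally invalid input (e.g. empty gene universe)."""


class UnknownConfigKey(VcgrnError):
    """A configuration file contains a key the package does not define."""


class OrientationAmbiguous(UserWarning):
    """Modulator sign could not be anchored (zero correlation with anchor)."""


class PseudoinverseFallback(UserWarning):
    """Singular ridge system; degrees of freedom computed via pseudoinverse."""
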