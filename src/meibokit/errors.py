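"""Exception hierarchy for the meibography analysis pipeline.

Stage failures during batch processing are caught by the orchestration
layer and recorded in the report status; they are real exceptions only
when the individual operations are called directly.
"""


class MeibokitError(Exception):
    """Base class for all package-specific errors."""


class FlatImageError(MeibokitError):
    """The row-mean intensity profile has no usable peak (unusable acquisition)."""


class NoBoundaryFound(MeibokitError):
    """No eyelid boundary candidate survived filtering/fitting."""


class EmptyMaskError(MeibokitError):
    """A binary mask required to be nonempty was empty."""


class EmptyROIError(MeibokitError):
    """The region-of-interest mask is empty."""


class DegenerateObjectError(MeibokitError):
    """A pixel object is too small/degenerate for moment analysis."""


class InvalidCountsError(MeibokitError):
    """Pixel counts violate the dropout-area formula preconditions."""


class OutsideROIError(MeibokitError):
    """A gland centroid column lies outside the ROI column span."""


class InsufficientReferenceError(MeibokitError):
    """Too few reference profiles to build an irregularity envelope."""


class OutOfRangeError(MeibokitError):
    """A dropout-area percentage outside [0, 100] was passed to grading."""


class DegenerateDataError(MeibokitError):
    """Fewer distinct values than requested classes for threshold fitting."""


class EmptyTableError(MeibokitError):
    """An all-zero confusion table cannot yield an agreement statistic."""


class ParameterError(MeibokitError):
    """Invalid synthetic-generator parameters."""


class UnsupportedFormatError(MeibokitError):
    """Input raster format not supported."""


class EmptyDirectoryError(MeibokitError):
    """A batch directory contained no readable images."""


class NonStarShapedWarning(UserWarning):
    """A polar ray crossed the gland boundary more than once; the
    outermost crossing was used."""
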