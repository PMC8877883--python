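"""Exception hierarchy shared across the package."""


class HetMCETError(Exception):
    """Base class for all package-specific errors."""


class ImageReadError(HetMCETError, IOError):
    """An input raster could not be read or decoded."""


class UnsupportedBitDepthError(HetMCETError, ValueError):
    """Input image is not 8-bit and rescaling was not requested."""


class UndefinedMeanError(HetMCETError, ArithmeticError):
    """A mean estimator was applied to an empty region (or a zero
    denominator arose); the caller treats the candidate threshold as
    invalid rather than aborting the scan."""


class DegenerateInputError(HetMCETError, ValueError):
    """A histogram with fewer than two occupied gray levels cannot be
    bilevel-thresholded."""


class MetricError(HetMCETError, ValueError):
    """An evaluation measure's precondition was violated (e.g. a region
    with no border pixels)."""


class DegeneratePhantomError(HetMCETError, ValueError):
    """Phantom geometry does not intersect the canvas."""
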