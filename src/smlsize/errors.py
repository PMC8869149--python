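"""Exception hierarchy for smlsize."""


class SmlsizeError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(SmlsizeError, ValueError):
    """A model, kernel, or configuration parameter is out of its valid range."""


class DegenerateInputError(SmlsizeError, ValueError):
    """Input carries no usable signal (all-zero profile, too few points, ...)."""


class UnderdeterminedFitError(SmlsizeError, ValueError):
    """Fewer data points than free parameters."""


class FitFailureError(SmlsizeError, RuntimeError):
    """The optimizer produced a non-finite objective or failed outright.

    Carries ``last_iterate`` (parameter dict) when available.
    """

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class NoPeakError(SmlsizeError, ValueError):
    """Profile has no maximum above the baseline; FWHM undefined."""


class BoundaryPeakError(SmlsizeError, ValueError):
    """Profile peak sits at (or above half level at) the window boundary."""


class SingleBinError(SmlsizeError, ValueError):
    """Requested bin width does not resolve the projected span."""


class FormatError(SmlsizeError, ValueError):
    """A file does not conform to the declared dialect."""


class UndersamplingError(SmlsizeError, ValueError):
    """Pixel size too coarse for the PSF width (pixel_size >= 4 * psf_sigma)."""
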