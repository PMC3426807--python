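"""Exception hierarchy for depthbb."""


class DepthBBError(Exception):
    """Base class for all depthbb errors."""


class FormatError(DepthBBError, ValueError):
    """A file violates the expected tabular format (duplicate gene ids,
    negative or non-integer counts, missing required columns)."""


class ConfigurationError(DepthBBError, ValueError):
    """Inputs are individually well formed but inconsistent with each other
    (run column absent from the sample sheet, missing gene lengths,
    invalid simulation configuration)."""


class InsufficientDataError(DepthBBError, ValueError):
    """Too few genes/observations for the requested estimate."""


class DegenerateInputError(DepthBBError, ValueError):
    """Input is structurally valid but carries no information
    (e.g. a library with zero total counts)."""


class FitError(DepthBBError, RuntimeError):
    """A numerical fit failed to converge.

    Carries the binned histogram (``bin_centers``, ``density``) when raised
    by the peak-of-histogram normalization so the user can inspect it.
    """

    def __init__(self, message, bin_centers=None, density=None):
        super().__init__(message)
        self.bin_centers = bin_centers
        self.density = density
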