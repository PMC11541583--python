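"""Exception types shared across the pipelines."""


class SpheroquantError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SpheroquantError):
    """An input file could not be read as the expected format."""


class ValidationError(SpheroquantError, ValueError):
    """A parameter or input violates a precondition."""


class DegenerateHistogramError(SpheroquantError):
    """Automatic thresholding failed because the image has no contrast."""


class NoSpheroidError(SpheroquantError):
    """No region reached the minimum density threshold."""


class PackingError(SpheroquantError):
    """Phantom object placement failed within the retry budget."""


class UndefinedRatioError(SpheroquantError):
    """A control-normalised ratio is undefined (zero denominator)."""
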