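"""Exception hierarchy for the wbatlas pipeline."""


class WbAtlasError(Exception):
    """Base class for all wbatlas errors."""


class FormatError(WbAtlasError):
    """A file or array does not match the expected on-disk format."""


class ParameterError(WbAtlasError, ValueError):
    """An operation was called with an out-of-range parameter."""


class DataError(WbAtlasError):
    """Input data violates a precondition (empty mask, grid mismatch, ...)."""


class SpecError(WbAtlasError):
    """A phantom specification is internally inconsistent."""


class RecipeError(WbAtlasError):
    """A subject recipe produces an invalid (non-invertible) synthesis warp."""


class NormalizationError(WbAtlasError):
    """Blood-pool normalization cannot be performed (non-positive VOI mean)."""


class RegistrationError(WbAtlasError):
    """Registration failed in a way that cannot be reported via flags."""
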