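"""Exception hierarchy for seedspectra.

All library-raised errors derive from :class:`SeedSpectraError` so callers can
catch everything from this package with one clause; most also derive from a
builtin (``ValueError`` / ``IOError``) so generic handling keeps working.
"""


class SeedSpectraError(Exception):
    """Base class for all seedspectra errors."""


class ValidationError(SeedSpectraError, ValueError):
    """An input violates a documented precondition (shape, range, alignment)."""


class CubeFormatError(SeedSpectraError, ValueError):
    """A cube file and its wavelength manifest disagree or are malformed."""


class BandLookupError(SeedSpectraError, KeyError):
    """A requested wavelength is not on the cube's grid."""


class ThresholdError(SeedSpectraError, ValueError):
    """Automatic threshold selection is degenerate (e.g. constant image)."""


class ParameterError(SeedSpectraError, ValueError):
    """A generator or model parameter is out of its valid range."""


class PlacementError(SeedSpectraError, RuntimeError):
    """Seeds could not be placed without overlap within the retry budget."""


class SplitError(SeedSpectraError, ValueError):
    """A train/validation split cannot honour the stratification request."""


class FitError(SeedSpectraError, ValueError):
    """A discriminant model cannot be estimated from the given data."""


class CrossValidationError(SeedSpectraError, ValueError):
    """Leave-one-out cross-validation preconditions are not met."""


class RenderingError(SeedSpectraError, ValueError):
    """A classification image cannot be rendered (e.g. incomplete palette)."""
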