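"""Exception hierarchy.

All package errors derive from :class:`ChromoDecompError` so callers can
catch domain failures without masking programming errors.
"""


class ChromoDecompError(Exception):
    """Base class for all chromodecomp errors."""


class GridMismatchError(ChromoDecompError):
    """Spectral curves do not share a wavelength grid."""


class BandCoverageError(ChromoDecompError):
    """A spectral curve does not cover the requested integration band."""


class DomainError(ChromoDecompError):
    """Input outside the mathematical domain of an operation."""


class InvalidValueError(ChromoDecompError):
    """Non-finite or otherwise invalid numeric input."""


class DegenerateMediumError(ChromoDecompError):
    """Optical medium with no scattering; diffusion reflectance undefined."""


class DegenerateProfileError(ChromoDecompError):
    """Acquisition profile with zero light or zero sensitivity."""


class FitDegenerateError(ChromoDecompError):
    """Rank-deficient design in the color-transform fit."""


class SpaceError(ChromoDecompError):
    """Image is tagged with the wrong color space for an operation."""


class ShapeError(ChromoDecompError):
    """Array shapes incompatible."""


class SizeError(ChromoDecompError):
    """Image/patch geometry incompatible (e.g. image smaller than a patch)."""


class IncompleteSetError(ChromoDecompError):
    """A patch set is missing patches required for recombination."""


class ModelStateError(ChromoDecompError):
    """Operation requires a trained model."""


class DataError(ChromoDecompError):
    """Empty or unusable dataset."""


class NoSignalError(ChromoDecompError):
    """Every pixel of a training batch is masked out."""


class DegenerateScaleError(ChromoDecompError):
    """Min-max scaling of a constant map is undefined."""


class ConfigError(ChromoDecompError):
    """Invalid configuration parameters."""
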