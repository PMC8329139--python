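"""Exception hierarchy for mrtilt.

Every failure mode the estimators can hit maps to a distinct subclass so
callers (and the sweep harness) can record *why* a trial failed instead of
aborting.
"""


class MrTiltError(Exception):
    """Base class for all mrtilt errors."""


class VolumeIOError(MrTiltError):
    """A NIfTI file could not be read or written."""


class DegenerateInputError(MrTiltError):
    """Input carries no usable signal (constant slice, collinear region, ...)."""


class EmptyForegroundError(MrTiltError):
    """A segmentation step produced no foreground pixels."""


class LandmarkNotFoundError(MrTiltError):
    """Nasion/Inion search found no boundary candidates in the search range."""


class DegenerateOrientationError(MrTiltError):
    """Principal axes are undefined (isotropic second moments)."""


class NoEllipticalSliceError(MrTiltError):
    """No axial slice passed the ellipse gate; yaw/roll cannot be estimated."""


class InsufficientDataError(MrTiltError):
    """Too few points/slices for a fit (orthogonal regression needs >= 3 slices)."""


class InvalidTransformError(MrTiltError):
    """The supplied matrix is not a proper rotation."""


class CorrectionImpossibleError(MrTiltError):
    """All three angle estimators failed; nothing to correct."""


class UnsupportedConfigurationError(MrTiltError):
    """Requested configuration is outside the method's validity range."""
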