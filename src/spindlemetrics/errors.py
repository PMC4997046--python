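"""Exception types shared across the package."""


class SpindleMetricsError(Exception):
    """Base class for all package errors."""


class ValidationError(SpindleMetricsError, ValueError):
    """An input violates a documented precondition."""


class GeometryError(SpindleMetricsError, ValueError):
    """Requested geometry does not fit the voxel grid."""


class DegenerateInputError(SpindleMetricsError, ValueError):
    """Input carries no usable signal (e.g. constant-intensity image)."""


class AnisotropyError(SpindleMetricsError, ValueError):
    """Intensity distribution has no well-defined principal axis."""


class MissingPoleError(SpindleMetricsError, ValueError):
    """No masked tubulin voxels on the requested half-spindle side."""


class GenerationError(SpindleMetricsError, RuntimeError):
    """A constrained random generation failed after bounded retries."""
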