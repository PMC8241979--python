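"""Exception hierarchy for the rtfe pipeline.

Every stage raises a subclass of :class:`RtfeError`, so callers can catch
pipeline failures without masking programming errors.
"""


class RtfeError(Exception):
    """Base class for all rtfe errors."""


class InvalidSpecError(RtfeError, ValueError):
    """A phantom / filter / material / boundary-condition spec is invalid."""


class InvalidInputError(RtfeError, ValueError):
    """An operation received values outside its domain."""


class FormatError(RtfeError, IOError):
    """A volume file could not be parsed in any supported format."""


class UnsupportedGeometryError(RtfeError):
    """The voxel FE requires cubic (isotropic) voxels; the input has not."""


class OutOfBoundsError(RtfeError, IndexError):
    """A crop region exceeds the volume extent."""


class InvalidTrimError(RtfeError, ValueError):
    """An axial trim would consume the whole volume."""


class EmptyDistributionError(RtfeError, ValueError):
    """A strain distribution was requested over an empty mask or sample."""


class InvalidTargetError(RtfeError, ValueError):
    """A target distribution cannot be built (zero or negative median)."""


class SolverFailureError(RtfeError, RuntimeError):
    """The CG solver did not converge within its iteration cap."""

    def __init__(self, message, residual_history=None):
        super().__init__(message)
        self.residual_history = list(residual_history or [])


class GenerationFailureError(RtfeError, RuntimeError):
    """A phantom could not satisfy its generation-time contract."""


class ScenarioAlignmentError(RtfeError, ValueError):
    """Two cohort scenarios do not cover the same animals / time points."""
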