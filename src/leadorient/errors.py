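"""Exception hierarchy for lead-orientation detection.

Every failure mode the pipeline can report maps to one exception class so the
CLI can translate them into stable exit codes.
"""


class LeadOrientError(Exception):
    """Base class for all package errors."""


class DimensionalityError(LeadOrientError):
    """Input image is not a 3D scalar volume."""


class InvalidGeometryError(LeadOrientError):
    """Degenerate or missing voxel-to-world transform."""


class EmptySliceError(LeadOrientError):
    """A resampling plane lies entirely outside the CT volume."""


class DegenerateTrajectoryError(LeadOrientError):
    """The two trajectory points coincide."""


class InsufficientArtifactError(LeadOrientError):
    """Too few hyperdense slices to refine the trajectory."""


class ConfigurationError(LeadOrientError):
    """Unknown lead level, profile, or invalid parameter value."""


class NoArtifactError(LeadOrientError):
    """No usable marker artifact found (amplitude below threshold)."""


class NoMarkerError(LeadOrientError):
    """No suprathreshold (metal) pixels in a resampled marker slice."""


class LevelOutOfVolumeError(LeadOrientError):
    """No directional contact level lies inside the CT volume."""


class UnresolvedAmbiguityError(LeadOrientError):
    """All ambiguity-resolution methods are degenerate.

    Carries the two inverse candidate orientations so callers can still
    report them.
    """

    def __init__(self, message: str, candidates: tuple[float, float] | None = None):
        super().__init__(message)
        self.candidates = candidates


class PolarGateRefusal(LeadOrientError):
    """Lead polar angle exceeds the hard imaging-constraint limit."""

    def __init__(self, message: str, polar_deg: float):
        super().__init__(message)
        self.polar_deg = polar_deg
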