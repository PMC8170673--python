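"""Exception types raised across the pipeline."""


class Fus3dError(Exception):
    """Base class for all package-specific errors."""


class InvalidTransformError(Fus3dError, ValueError):
    """Rotation matrix is not orthonormal / proper within tolerance."""


class DegenerateClusterError(Fus3dError, ValueError):
    """Marker cluster is collinear, duplicated, or has fewer than 3 markers."""


class SpeedDomainError(Fus3dError, ValueError):
    """Temperature outside the validity range of the water speed model."""


class MissingPoseError(Fus3dError, ValueError):
    """Ultrasound frame carries no probe pose."""


class DegenerateSampleError(Fus3dError, ValueError):
    """Point sample too small or coplanar for sphere estimation."""


class NoConsensusError(Fus3dError, RuntimeError):
    """MSAC found no hypothesis with enough inliers."""


class EmptyContourError(Fus3dError, ValueError):
    """No digitized points to select a landmark from."""


class EmptySweepError(Fus3dError, ValueError):
    """Ultrasound sweep contains no digitized frames."""


class TooFewConditionsError(Fus3dError, ValueError):
    """Friedman test requires at least 3 conditions."""


class TooFewPointsError(Fus3dError, ValueError):
    """Not enough values for the requested statistic."""


class ParseError(Fus3dError, ValueError):
    """Malformed input file; message carries the offending row."""


class GeometryError(Fus3dError, ValueError):
    """Requested structure not reachable / invalid phantom geometry."""
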