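"""Rigid-body frames and the freehand-ultrasound coordinate chain.

A tracked 2D ultrasound probe produces, per frame, a rigid pose of the
image plane in the motion-capture (world) frame.  Digitized pixel
coordinates (u lateral, v axial depth) are scaled to millimetres, the
axial spacing corrected for the actual speed of sound relative to the
calibration speed, and pushed through image -> probe -> world.  A marker
cluster on the sacrum defines the local pelvic reference frame in which
landmarks are finally expressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateClusterError,
    InvalidTransformError,
    MissingPoseError,
    SpeedDomainError,
)

__all__ = [
    "RigidTransform",
    "ProbeCalibration",
    "UltrasoundFrame",
    "WaterSpeedModel",
    "compose",
    "invert",
    "cluster_frame",
    "speed_of_sound_water",
    "pixel_to_world",
    "express_in_frame",
]

#: strict orthonormality tolerance for accepting a rotation as-is
ORTHO_TOL = 1e-9
#: near-rigid inputs within this tolerance are repaired by polar decomposition
REPAIR_TOL = 1e-6


def _as_rotation(matrix: np.ndarray) -> np.ndarray:
    """Validate (and if mildly perturbed, repair) a 3x3 rotation matrix.

    Deviations from orthonormality up to ``REPAIR_TOL`` are projected onto
    SO(3) via polar decomposition; larger violations or reflections raise
    :class:`InvalidTransformError`.
    """
    R = np.asarray(matrix, dtype=float)
    if R.shape != (3, 3):
        raise InvalidTransformError(f"rotation must be 3x3, got {R.shape}")
    err = np.max(np.abs(R.T @ R - np.eye(3)))
    if err > REPAIR_TOL:
        raise InvalidTransformError(f"rotation not orthonormal (|R'R - I| = {err:.3e})")
    if err > ORTHO_TOL:
        U, _, Vt = np.linalg.svd(R)
        R = U @ Vt
    if np.linalg.det(R) < 0:
        raise InvalidTransformError("rotation has negative determinant (reflection)")
    return R


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion: ``x -> rotation @ x + translation`` (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", _as_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_translation(cls, t) -> "RigidTransform":
        return cls(np.eye(3), t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map one (3,) point or an (n, 3) array through the transform."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def as_matrix(self) -> np.ndarray:
        """Homogeneous 4x4 representation."""
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def is_close(self, other: "RigidTransform", tol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.rotation, other.rotation, atol=tol)
            and np.allclose(self.translation, other.translation, atol=tol)
        )


def compose(first: RigidTransform, second: RigidTransform) -> RigidTransform:
    """Transform equivalent to applying ``first`` then ``second``."""
    return RigidTransform(
        second.rotation @ first.rotation,
        second.rotation @ first.translation + second.translation,
    )


def invert(T: RigidTransform) -> RigidTransform:
    """Inverse rigid motion: ``compose(T, invert(T))`` is the identity."""
    Rt = T.rotation.T
    return RigidTransform(Rt, -Rt @ T.translation)


@dataclass(frozen=True)
class ProbeCalibration:
    """Fixed image-plane-to-probe-cluster transform and pixel scaling.

    ``pixel_spacing_axial`` is valid at ``calibration_speed``; reconstruction
    at a different speed of sound rescales the axial (depth) direction only.
    """

    image_to_probe: RigidTransform
    pixel_spacing_lateral: float  # mm / pixel
    pixel_spacing_axial: float  # mm / pixel at calibration_speed
    calibration_speed: float = 1540.0  # m/s

    def __post_init__(self) -> None:
        if self.pixel_spacing_lateral <= 0 or self.pixel_spacing_axial <= 0:
            raise ValueError("pixel spacings must be positive")
        if not 1300.0 <= self.calibration_speed <= 1700.0:
            raise ValueError("calibration_speed outside plausible range [1300, 1700] m/s")


@dataclass(frozen=True)
class UltrasoundFrame:
    """One tracked image: probe pose in world plus digitized pixels (u, v)."""

    frame_index: int
    probe_pose_world: RigidTransform | None
    digitized_pixels: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        px = np.asarray(self.digitized_pixels, dtype=float).reshape(-1, 2)
        if px.size and px.min() < 0:
            raise ValueError("pixel coordinates must be non-negative")
        object.__setattr__(self, "digitized_pixels", px)

    @property
    def n_pixels(self) -> int:
        return int(self.digitized_pixels.shape[0])


# Simplified quadratic for the speed of sound in (distilled) water,
# c(T) = a0 + a1*T + a2*T^2 with T in Celsius, valid on 10-40 degC.
DEFAULT_WATER_SPEED_COEFFS = (1405.03, 4.624, -3.83e-2)
DEFAULT_WATER_SPEED_RANGE = (10.0, 40.0)


@dataclass(frozen=True)
class WaterSpeedModel:
    """Quadratic temperature model c(T) for the speed of sound in water."""

    coefficients: tuple[float, float, float] = DEFAULT_WATER_SPEED_COEFFS
    valid_range: tuple[float, float] = DEFAULT_WATER_SPEED_RANGE

    def speed(self, temperature: float) -> float:
        """Speed of sound (m/s) at ``temperature`` (degC) within validity."""
        lo, hi = self.valid_range
        if not lo <= temperature <= hi:
            raise SpeedDomainError(
                f"temperature {temperature} degC outside validity range [{lo}, {hi}]"
            )
        a0, a1, a2 = self.coefficients
        return a0 + a1 * temperature + a2 * temperature**2


def speed_of_sound_water(temperature: float, model: WaterSpeedModel | None = None) -> float:
    """Speed of sound in water (m/s) from the quadratic temperature model."""
    return (model or WaterSpeedModel()).speed(temperature)


def cluster_frame(markers: np.ndarray, collinear_tol: float = 1e-8) -> RigidTransform:
    """Local frame of a rigid marker cluster (>= 3 labeled markers, mm).

    Convention (fixed, label-order dependent): origin at the first marker,
    x-axis toward the second, z-axis along the least-squares plane normal
    with sign making the frame right-handed w.r.t. the first three markers,
    y = z x x.  Returns the local-to-world transform.
    """
    M = np.asarray(markers, dtype=float).reshape(-1, 3)
    if M.shape[0] < 3:
        raise DegenerateClusterError("need at least 3 markers")
    origin = M[0]
    x = M[1] - origin
    nx = np.linalg.norm(x)
    if nx < collinear_tol:
        raise DegenerateClusterError("first two markers coincide")
    x = x / nx

    centered = M - M.mean(axis=0)
    # plane normal = singular vector of the smallest singular value
    _, s, Vt = np.linalg.svd(centered, full_matrices=False)
    scale = np.linalg.norm(centered) + collinear_tol
    if s[1] / scale < 1e-6:
        raise DegenerateClusterError("markers are collinear")
    z = Vt[2]
    ref = np.cross(M[1] - origin, M[2] - origin)
    if np.linalg.norm(ref) < collinear_tol:
        raise DegenerateClusterError("first three markers are collinear")
    if np.dot(z, ref) < 0:
        z = -z
    # enforce z orthogonal to the exact x axis, then complete right-handed
    z = z - np.dot(z, x) * x
    z = z / np.linalg.norm(z)
    y = np.cross(z, x)
    R = np.column_stack([x, y, z])
    return RigidTransform(R, origin)


def pixel_to_world(
    frame: UltrasoundFrame,
    cal: ProbeCalibration,
    actual_speed: float | None = None,
) -> np.ndarray:
    """Map digitized (u, v) pixels of one frame to 3D world points (mm).

    Pixels scale to image-plane millimetres as
    ``(u * lateral_spacing, v * axial_spacing * actual_speed / calibration_speed, 0)``
    -- the time-of-flight speed correction rescales depth only -- and then
    pass through image->probe and probe->world.
    """
    if frame.probe_pose_world is None:
        raise MissingPoseError(f"frame {frame.frame_index} has no probe pose")
    if actual_speed is None:
        actual_speed = cal.calibration_speed
    if actual_speed <= 0:
        raise ValueError("actual_speed must be positive")
    px = frame.digitized_pixels
    if px.shape[0] == 0:
        return np.empty((0, 3))
    image_mm = np.zeros((px.shape[0], 3))
    image_mm[:, 0] = px[:, 0] * cal.pixel_spacing_lateral
    image_mm[:, 1] = px[:, 1] * cal.pixel_spacing_axial * (actual_speed / cal.calibration_speed)
    image_to_world = compose(cal.image_to_probe, frame.probe_pose_world)
    return image_to_world.apply(image_mm)


def express_in_frame(points_world: np.ndarray, local: RigidTransform) -> np.ndarray:
    """Re-express world points (mm) in the given local frame."""
    return invert(local).apply(points_world)
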