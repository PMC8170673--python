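"""Synthetic phantom, ultrasound sweeps, laser scans, and cohorts.

Everything the pipeline consumes can be generated here with analytic
ground truth:

* a pelvis-like phantom -- a superellipsoid body with two Gaussian ASIS
  bumps riding on its anterior surface, two spherical femoral heads, and
  a rigid 4-marker sacrum cluster;
* tracked ultrasound sweeps whose digitized pixels back-project exactly
  onto the phantom surface before noise/outliers are injected;
* a simulated laser-scan reference cloud (the ground-truth role);
* a two-session lean/obese test-retest cohort whose torso fat mass (FMT)
  distributions follow the study group descriptives and whose landmark
  error grows linearly with FMT.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh
from scipy import stats

from .errors import GeometryError
from .geometry import ProbeCalibration, RigidTransform, UltrasoundFrame, invert
from .reliability import METHODS, TestRetestDataset

__all__ = [
    "PhantomSpec",
    "Phantom",
    "CohortSpec",
    "generate_phantom",
    "simulate_sweep",
    "simulate_laser_scan",
    "simulate_cohort",
]

# probe: linear array, 39 mm field of view
FIELD_OF_VIEW_MM = 39.0
_N_LATERAL_PX = 512
_PS_LAT = FIELD_OF_VIEW_MM / _N_LATERAL_PX  # mm / pixel
_PS_AX = 0.1  # mm / pixel
_CAL_SPEED = 1540.0  # m/s


def default_calibration() -> ProbeCalibration:
    return ProbeCalibration(
        image_to_probe=RigidTransform.identity(),
        pixel_spacing_lateral=_PS_LAT,
        pixel_spacing_axial=_PS_AX,
        calibration_speed=_CAL_SPEED,
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric pelvis-like phantom (all lengths mm, world frame).

    World axes: x to the subject's left, y anterior, z superior.  The
    ASIS bumps are Gaussian protrusions on the anterior superellipsoid
    surface; the femoral heads are spheres of ``head_radius``.
    """

    body_semiaxes: tuple[float, float, float] = (110.0, 70.0, 80.0)
    body_exponent: float = 2.5
    asis_x: float = 85.0  # left apex at +asis_x, right at -asis_x
    asis_z: float = 30.0
    asis_bump_amplitude: float = 15.0
    asis_bump_width: float = 5.0
    asis_patch_halfwidth: float = 12.0
    head_center_left: tuple[float, float, float] = (55.0, 35.0, -60.0)
    head_radius: float = 24.0
    cluster_markers: tuple = (
        (0.0, -95.0, -30.0),
        (40.0, -95.0, -30.0),
        (0.0, -55.0, -30.0),
        (40.0, -55.0, -30.0),
    )
    mirror: bool = False  # swap left/right geometry
    seed: int = 0

    def __post_init__(self) -> None:
        if self.head_radius <= 0 or self.asis_bump_amplitude <= 0:
            raise GeometryError("radii and bump amplitude must be positive")

    @property
    def head_center_right(self) -> tuple[float, float, float]:
        x, y, z = self.head_center_left
        return (-x, y, z)

    def _signed(self, side: str) -> float:
        s = 1.0 if side == "left" else -1.0
        return -s if self.mirror else s

    def asis_apex(self, side: str) -> np.ndarray:
        s = self._signed(side)
        x0, z0 = s * self.asis_x, self.asis_z
        return np.array([x0, self.anterior_body_y(x0, z0) + self.asis_bump_amplitude, z0])

    def head_center(self, side: str) -> np.ndarray:
        x, y, z = self.head_center_left
        return np.array([self._signed(side) * x, y, z])

    def anterior_body_y(self, x, z):
        """Anterior (y > 0) superellipsoid surface height at (x, z)."""
        a, b, c = self.body_semiaxes
        p = self.body_exponent
        rest = 1.0 - np.abs(np.asarray(x) / a) ** p - np.abs(np.asarray(z) / c) ** p
        if np.any(rest <= 0):
            raise GeometryError("(x, z) outside the anterior body footprint")
        return b * rest ** (1.0 / p)

    def asis_surface_y(self, x, z, side: str):
        """ASIS patch surface (y coordinate): Gaussian protrusion on a
        locally flat anterior plateau at the apex footprint.

        The flat base makes the bump apex the strict anterior maximum of
        the patch, so "most anterior point" and the analytic apex agree
        by construction.
        """
        apex = self.asis_apex(side)
        base = apex[1] - self.asis_bump_amplitude
        w2 = 2.0 * self.asis_bump_width**2
        bump = self.asis_bump_amplitude * np.exp(
            -((np.asarray(x) - apex[0]) ** 2 + (np.asarray(z) - apex[2]) ** 2) / w2
        )
        return base + bump


@dataclass(frozen=True)
class Phantom:
    spec: PhantomSpec
    mesh: trimesh.Trimesh
    cloud: np.ndarray  # (n, 3) surface samples, mm
    landmarks: dict[str, np.ndarray]  # asis_left/right, hjc_left/right
    cluster_markers: np.ndarray  # (4, 3), mm


def _superellipsoid_project(directions: np.ndarray, semiaxes, exponent: float) -> np.ndarray:
    a, b, c = semiaxes
    p = exponent
    scale = (
        np.abs(directions[:, 0] / a) ** p
        + np.abs(directions[:, 1] / b) ** p
        + np.abs(directions[:, 2] / c) ** p
    ) ** (-1.0 / p)
    return directions * scale[:, None]


def _patch_mesh(spec: PhantomSpec, side: str, n: int = 25) -> trimesh.Trimesh:
    apex = spec.asis_apex(side)
    h = spec.asis_patch_halfwidth
    xs = np.linspace(apex[0] - h, apex[0] + h, n)
    zs = np.linspace(apex[2] - h, apex[2] + h, n)
    X, Z = np.meshgrid(xs, zs, indexing="ij")
    Y = spec.asis_surface_y(X, Z, side)
    verts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            k = i * n + j
            faces.append([k, k + 1, k + n])
            faces.append([k + 1, k + n + 1, k + n])
    return trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)


def generate_phantom(spec: PhantomSpec | None = None, n_cloud_points: int = 20000) -> Phantom:
    """Build the phantom mesh, a surface sample cloud, and ground truth.

    The ASIS apices are exact analytic points of the generated surface
    (the patch grids contain them as vertices); the hip joint centers are
    the sphere centers.  Deterministic per ``spec.seed``.
    """
    spec = spec or PhantomSpec()
    # invariant: heads must clear the ASIS sweep surface
    for side in ("left", "right"):
        gap = np.linalg.norm(spec.asis_apex(side) - spec.head_center(side))
        if gap <= spec.head_radius:
            raise GeometryError("femoral head intersects the ASIS sweep surface")

    body = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
    body = trimesh.Trimesh(
        vertices=_superellipsoid_project(body.vertices, spec.body_semiaxes, spec.body_exponent),
        faces=body.faces,
        process=False,
    )
    parts = [body]
    for side in ("left", "right"):
        parts.append(_patch_mesh(spec, side))
        head = trimesh.creation.icosphere(subdivisions=3, radius=spec.head_radius)
        head.apply_translation(spec.head_center(side))
        parts.append(head)
    mesh = trimesh.util.concatenate(parts)

    rng = np.random.default_rng(spec.seed)
    n_body = int(0.6 * n_cloud_points)
    n_patch = int(0.1 * n_cloud_points)
    n_head = (n_cloud_points - n_body - 2 * n_patch) // 2
    dirs = rng.normal(size=(n_body, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    clouds = [_superellipsoid_project(dirs, spec.body_semiaxes, spec.body_exponent)]
    for side in ("left", "right"):
        apex = spec.asis_apex(side)
        h = spec.asis_patch_halfwidth
        # grid sampling (includes the exact apex) plus random fill
        g = int(np.sqrt(n_patch / 2))
        gx = np.linspace(apex[0] - h, apex[0] + h, g if g % 2 else g + 1)
        gz = np.linspace(apex[2] - h, apex[2] + h, g if g % 2 else g + 1)
        X, Z = np.meshgrid(gx, gz, indexing="ij")
        xs = np.r_[X.ravel(), apex[0] + h * (2 * rng.random(n_patch) - 1)]
        zs = np.r_[Z.ravel(), apex[2] + h * (2 * rng.random(n_patch) - 1)]
        clouds.append(np.column_stack([xs, spec.asis_surface_y(xs, zs, side), zs]))
        sdirs = rng.normal(size=(n_head, 3))
        sdirs /= np.linalg.norm(sdirs, axis=1, keepdims=True)
        clouds.append(spec.head_center(side) + spec.head_radius * sdirs)
    cloud = np.vstack(clouds)

    landmarks = {
        "asis_left": spec.asis_apex("left"),
        "asis_right": spec.asis_apex("right"),
        "hjc_left": spec.head_center("left"),
        "hjc_right": spec.head_center("right"),
    }
    return Phantom(spec, mesh, cloud, landmarks, np.asarray(spec.cluster_markers, float))


def _frame_pose(e_u: np.ndarray, e_v: np.ndarray, origin: np.ndarray) -> RigidTransform:
    e_w = np.cross(e_u, e_v)
    return RigidTransform(np.column_stack([e_u, e_v, e_w]), origin)


def _slice_points(phantom: Phantom, structure: str, x_i: float, n_pts: int) -> np.ndarray:
    """Surface points of one image plane (x = x_i) for the given structure."""
    spec = phantom.spec
    kind, side = structure.split("_")
    if kind == "asis":
        apex = spec.asis_apex(side)
        h = spec.asis_patch_halfwidth * 0.8
        zs = np.linspace(apex[2] - h, apex[2] + h, n_pts)
        ys = spec.asis_surface_y(np.full(n_pts, x_i), zs, side)
        return np.column_stack([np.full(n_pts, x_i), ys, zs])
    if kind == "hjc":
        c = spec.head_center(side)
        rho2 = spec.head_radius**2 - (x_i - c[0]) ** 2
        if rho2 <= 0:
            raise GeometryError(f"plane x={x_i} misses the femoral head")
        rho = np.sqrt(rho2)
        phi = np.linspace(-np.deg2rad(50.0), np.deg2rad(50.0), n_pts)
        return np.column_stack(
            [np.full(n_pts, x_i), c[1] + rho * np.cos(phi), c[2] + rho * np.sin(phi)]
        )
    raise GeometryError(f"unknown structure {structure!r}")


def _small_rotation(rng: np.random.Generator, sd_deg: float) -> np.ndarray:
    rv = np.deg2rad(rng.normal(0.0, sd_deg, size=3))
    angle = np.linalg.norm(rv)
    if angle == 0:
        return np.eye(3)
    axis = rv / angle
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def simulate_sweep(
    phantom: Phantom,
    structure: str,
    n_frames: int = 20,
    pixel_noise_mm: float = 0.0,
    pose_noise_mm: float = 0.0,
    pose_noise_deg: float = 0.0,
    outlier_fraction: float = 0.0,
    points_per_frame: int = 15,
    seed: int = 0,
) -> tuple[list[UltrasoundFrame], ProbeCalibration]:
    """Simulate a tracked ultrasound sweep over one structure.

    ``structure`` is ``asis_left|asis_right|hjc_left|hjc_right``.  Frames
    are parallel image planes swept medio-laterally across the structure.
    With all noise parameters at zero the digitized pixels back-project
    exactly onto the phantom surface.  ``pixel_noise_mm`` perturbs the
    digitizations, ``outlier_fraction`` replaces that share of points with
    gross too-deep digitizations, and pose noise perturbs the *stored*
    probe pose (tracking error) while pixels stay consistent with the
    true pose.  Deterministic per ``seed``.
    """
    if not 1 <= n_frames <= 200:
        raise GeometryError("n_frames must lie in [1, 200]")
    spec = phantom.spec
    kind, side = structure.split("_")
    if kind == "asis":
        center = spec.asis_apex(side)
        half_span = spec.asis_patch_halfwidth * 0.7
        depth_ref = center[1]
    elif kind == "hjc":
        center = spec.head_center(side)
        half_span = spec.head_radius * 0.7
        depth_ref = center[1] + spec.head_radius
    else:
        raise GeometryError(f"unknown structure {structure!r}")

    cal = default_calibration()
    rng = np.random.default_rng(seed)
    e_u = np.array([0.0, 0.0, 1.0])  # lateral pixels run along +z
    e_v = np.array([0.0, -1.0, 0.0])  # axial depth points posterior
    frames: list[UltrasoundFrame] = []
    xs = np.linspace(center[0] - half_span, center[0] + half_span, n_frames)
    for i, x_i in enumerate(xs):
        pts = _slice_points(phantom, structure, float(x_i), points_per_frame)
        if np.ptp(pts[:, 2]) > FIELD_OF_VIEW_MM:
            raise GeometryError("structure wider than the probe field of view")
        origin = np.array([x_i, depth_ref + 10.0, center[2] - FIELD_OF_VIEW_MM / 2.0])
        true_pose = _frame_pose(e_u, e_v, origin)
        image_mm = invert(true_pose).apply(pts)
        u = image_mm[:, 0] / cal.pixel_spacing_lateral
        v = image_mm[:, 1] / cal.pixel_spacing_axial
        if pixel_noise_mm > 0:
            u = u + rng.normal(0.0, pixel_noise_mm / cal.pixel_spacing_lateral, u.size)
            v = v + rng.normal(0.0, pixel_noise_mm / cal.pixel_spacing_axial, v.size)
        if outlier_fraction > 0:
            # blunders: spurious shallow echoes (soft-tissue interfaces)
            # digitized 10-30 mm above the bone surface
            hit = rng.random(u.size) < outlier_fraction
            v = v - hit * rng.uniform(10.0, 30.0, u.size) / cal.pixel_spacing_axial
        pose = true_pose
        if pose_noise_mm > 0 or pose_noise_deg > 0:
            dR = _small_rotation(rng, pose_noise_deg)
            dt = rng.normal(0.0, pose_noise_mm, size=3) if pose_noise_mm > 0 else np.zeros(3)
            pose = RigidTransform(dR @ true_pose.rotation, true_pose.translation + dt)
        px = np.column_stack([np.clip(u, 0.0, None), np.clip(v, 0.0, None)])
        frames.append(UltrasoundFrame(frame_index=i, probe_pose_world=pose, digitized_pixels=px))
    return frames, cal


def simulate_laser_scan(
    phantom: Phantom,
    density: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Area-weighted surface samples standing in for the laser scan.

    ``density`` is points per mm^2 of mesh surface.  Sampling is
    prefix-stable: a higher density with the same seed reproduces the
    lower-density points and appends more, so refinement is monotone.
    Default noise is zero (ground-truth role).
    """
    if density <= 0:
        raise ValueError("density must be positive")
    mesh = phantom.mesh
    n = int(np.ceil(density * mesh.area))
    rng = np.random.default_rng(seed)
    areas = mesh.area_faces
    cum = np.cumsum(areas) / areas.sum()
    draws = rng.random((n, 3))
    fidx = np.searchsorted(cum, draws[:, 0])
    tri = mesh.triangles[fidx]
    # uniform barycentric via the square-root trick
    r1 = np.sqrt(draws[:, 1])[:, None]
    r2 = draws[:, 2][:, None]
    pts = (1 - r1) * tri[:, 0] + r1 * (1 - r2) * tri[:, 1] + r1 * r2 * tri[:, 2]
    if noise_sd > 0:
        pts = pts + rng.normal(0.0, noise_sd, size=pts.shape)
    return pts


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass(frozen=True)
class CohortSpec:
    """Two-session lean/obese cohort with FMT-dependent landmark error.

    ``fmt_*`` are (mean, SD) of torso fat mass in % body mass, truncated
    to [0, 100].  Per method, the per-axis test-retest error SD follows
    ``a + b * FMT`` (mm).  Counts are legs; left and right legs of one
    subject share the subject's FMT.  An optional missing-trial mechanism
    drops hip-center rows whose simulated head depth exceeds the probe
    penetration limit.
    """

    n_lean: int = 32
    n_obese: int = 38
    fmt_lean: tuple[float, float] = (14.9, 10.0)
    fmt_obese: tuple[float, float] = (43.3, 7.9)
    error_coeffs: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "MMP": (0.5, 0.20),
            "IPT": (0.5, 0.18),
            "3DFUS": (3.5, 0.12),
            "3DFUS-HJC": (2.0, 0.15),
        }
    )
    anatomy_sd: float = 10.0  # mm, between-subject landmark variation per axis
    inject_missing: bool = False
    depth_model: tuple[float, float, float] = (35.5, 0.6, 5.0)  # d0 + d1*FMT + N(0,d2)
    penetration_limit: float = 65.0  # mm
    seed: int = 0

    def __post_init__(self) -> None:
        for m, (a, b) in self.error_coeffs.items():
            if a < 0:
                raise ValueError(f"error intercept for {m} must be >= 0")
        if self.fmt_lean[1] <= 0 or self.fmt_obese[1] <= 0:
            raise ValueError("FMT SDs must be positive")


# nominal true landmark positions (mm, pelvic frame); mirrored across x
_TRUE_ASIS = np.array([120.0, 80.0, 10.0])
_TRUE_HJC = np.array([55.0, 35.0, -60.0])


def _truncated_normal(rng, mean, sd, size):
    a, b = (0.0 - mean) / sd, (100.0 - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_cohort(spec: CohortSpec | None = None) -> TestRetestDataset:
    """Simulate the two-session test-retest cohort.

    Each leg yields one row per method; both sessions observe the true
    landmark plus independent per-axis Gaussian error with SD
    ``a + b * FMT``.  Deterministic per ``spec.seed``.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for group, n_legs, (mu, sd) in (
        ("lean", spec.n_lean, spec.fmt_lean),
        ("obese", spec.n_obese, spec.fmt_obese),
    ):
        n_subjects = (n_legs + 1) // 2
        fmt_subj = _truncated_normal(rng, mu, sd, n_subjects)
        anat_subj = rng.normal(0.0, spec.anatomy_sd, size=(n_subjects, 3))
        for leg in range(n_legs):
            subj = leg // 2
            side = "left" if leg % 2 == 0 else "right"
            sign = 1.0 if side == "left" else -1.0
            fmt = float(fmt_subj[subj])
            for method in METHODS:
                a, b = spec.error_coeffs[method]
                err_sd = a + b * fmt
                # subject anatomy shifts both landmarks rigidly per side
                true = (
                    (_TRUE_HJC if method == "3DFUS-HJC" else _TRUE_ASIS) + anat_subj[subj]
                ) * np.array([sign, 1.0, 1.0])
                s1 = true + rng.normal(0.0, err_sd, 3)
                s2 = true + rng.normal(0.0, err_sd, 3)
                if spec.inject_missing and method == "3DFUS-HJC":
                    d0, d1, d2 = spec.depth_model
                    depth = d0 + d1 * fmt + rng.normal(0.0, d2)
                    if depth > spec.penetration_limit:
                        s1 = np.full(3, np.nan)
                        s2 = np.full(3, np.nan)
                rows.append({
                    "subject_id": f"{group[0].upper()}{subj:03d}",
                    "side": side,
                    "group": group,
                    "method": method,
                    "fmt": fmt,
                    "ap_test": s1[1], "ml_test": s1[0], "si_test": s1[2],
                    "ap_retest": s2[1], "ml_retest": s2[0], "si_retest": s2[2],
                })
    return TestRetestDataset.from_frame(pd.DataFrame(rows))
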