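"""Robust sphere fitting for hip joint center (HJC) localization.

The femoral head surface is digitized over an ultrasound sweep; pooling
the reconstructed 3D points and fitting a sphere yields the HJC as the
sphere center.  Manual digitization produces gross outliers, so the fit
uses M-estimator Sample Consensus (MSAC): hypotheses are minimal 4-point
algebraic sphere fits and the hypothesis score is the truncated squared
residual sum  sum_i min(r_i^2, threshold^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import DegenerateSampleError, EmptySweepError, NoConsensusError
from .geometry import ProbeCalibration, RigidTransform, UltrasoundFrame, express_in_frame, pixel_to_world

__all__ = [
    "SphereModel",
    "MsacConfig",
    "SphereFitResult",
    "fit_sphere_lsq",
    "msac_sphere",
    "hjc_from_sweep",
]

#: condition-number threshold above which a 4+-point sample counts as coplanar
COPLANAR_COND = 1e8


@dataclass(frozen=True)
class SphereModel:
    center: np.ndarray  # (3,), mm
    radius: float  # mm

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float).reshape(3))
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    def residuals(self, points: np.ndarray) -> np.ndarray:
        """Unsigned radial residuals | ||p - center|| - radius | (mm)."""
        p = np.asarray(points, dtype=float).reshape(-1, 3)
        return np.abs(np.linalg.norm(p - self.center, axis=1) - self.radius)


@dataclass(frozen=True)
class MsacConfig:
    """MSAC loop parameters.

    The inlier threshold reflects the expected digitization noise scale;
    radius bounds encode the plausible femoral-head size and reject
    degenerate giant-sphere hypotheses from near-coplanar samples.
    """

    inlier_threshold: float = 2.0  # mm
    max_iterations: int = 2000
    min_sample_size: int = 4
    confidence: float = 0.99
    seed: int = 0
    radius_bounds: tuple[float, float] = (10.0, 60.0)  # mm
    geometric_refine: bool = False  # Gauss-Newton refinement of the final fit

    def __post_init__(self) -> None:
        if self.inlier_threshold <= 0:
            raise ValueError("inlier_threshold must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not 0 < self.confidence < 1:
            raise ValueError("confidence must be in (0, 1)")
        if not self.radius_bounds[0] < self.radius_bounds[1]:
            raise ValueError("radius_bounds must be increasing")


@dataclass(frozen=True)
class SphereFitResult:
    model: SphereModel
    inlier_mask: np.ndarray  # bool per input point
    msac_cost: float  # mm^2
    rms_inlier_residual: float  # mm
    config: MsacConfig | None = field(default=None, compare=False)

    @property
    def n_inliers(self) -> int:
        return int(np.count_nonzero(self.inlier_mask))

    def to_dict(self) -> dict:
        d = {
            "center_mm": self.model.center.tolist(),
            "radius_mm": float(self.model.radius),
            "msac_cost_mm2": float(self.msac_cost),
            "rms_inlier_residual_mm": float(self.rms_inlier_residual),
            "inlier_indices": np.flatnonzero(self.inlier_mask).tolist(),
        }
        if self.config is not None:
            d["msac_config"] = {
                "inlier_threshold_mm": self.config.inlier_threshold,
                "max_iterations": self.config.max_iterations,
                "confidence": self.config.confidence,
                "seed": self.config.seed,
                "radius_bounds_mm": list(self.config.radius_bounds),
                "geometric_refine": self.config.geometric_refine,
            }
        return d


def fit_sphere_lsq(points: np.ndarray) -> SphereModel:
    """Algebraic least-squares sphere through >= 4 non-coplanar points.

    Linearizes ``|p|^2 = 2 c . p + (r^2 - |c|^2)`` and solves the normal
    problem; exact for noiseless spherical data.
    """
    p = np.asarray(points, dtype=float).reshape(-1, 3)
    if p.shape[0] < 4:
        raise DegenerateSampleError(f"need >= 4 points, got {p.shape[0]}")
    A = np.column_stack([2.0 * p, np.ones(p.shape[0])])
    b = np.einsum("ij,ij->i", p, p)
    if np.linalg.cond(A) > COPLANAR_COND:
        raise DegenerateSampleError("points are (near-)coplanar")
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center, k = sol[:3], sol[3]
    r2 = k + center @ center
    if r2 <= 0:
        raise DegenerateSampleError("degenerate solution with non-positive radius")
    return SphereModel(center, float(np.sqrt(r2)))


def _refine_geometric(model: SphereModel, points: np.ndarray) -> SphereModel:
    """Gauss-Newton minimization of geometric radial residuals."""

    def fun(x):
        c, r = x[:3], x[3]
        return np.linalg.norm(points - c, axis=1) - r

    x0 = np.r_[model.center, model.radius]
    res = least_squares(fun, x0, method="lm")
    return SphereModel(res.x[:3], float(res.x[3]))


def msac_sphere(points: np.ndarray, cfg: MsacConfig | None = None) -> SphereFitResult:
    """MSAC sphere fit: robust center estimate under gross outliers.

    Samples minimal 4-point hypotheses, scores each with the truncated
    squared residual cost, keeps the strictly best (first on ties), stops
    early once the adaptive iteration bound for ``cfg.confidence`` is met,
    and refits on the consensus set with :func:`fit_sphere_lsq`.
    Deterministic for a fixed ``cfg.seed``.
    """
    cfg = cfg or MsacConfig()
    p = np.asarray(points, dtype=float).reshape(-1, 3)
    n = p.shape[0]
    m = cfg.min_sample_size
    if n < m:
        raise DegenerateSampleError(f"need >= {m} points, got {n}")

    rng = np.random.default_rng(cfg.seed)
    th = cfg.inlier_threshold
    th2 = th * th
    best_cost = np.inf
    best_mask: np.ndarray | None = None

    needed = cfg.max_iterations
    i = 0
    while i < min(needed, cfg.max_iterations):
        i += 1
        idx = rng.choice(n, size=m, replace=False)
        try:
            hyp = fit_sphere_lsq(p[idx])
        except DegenerateSampleError:
            continue
        if not cfg.radius_bounds[0] <= hyp.radius <= cfg.radius_bounds[1]:
            continue
        res = hyp.residuals(p)
        cost = float(np.sum(np.minimum(res * res, th2)))
        if cost < best_cost:
            best_cost = cost
            best_mask = res <= th
            # adaptive stopping: enough draws to hit one all-inlier sample
            w = best_mask.mean()
            if w >= 1.0:
                needed = i
            elif w > 0:
                denom = np.log1p(-min(w**m, 1 - 1e-12))
                needed = int(np.ceil(np.log(1 - cfg.confidence) / denom))

    if best_mask is None or best_mask.sum() < m:
        raise NoConsensusError("no sphere hypothesis reached a consensus set")

    try:
        model = fit_sphere_lsq(p[best_mask])
    except DegenerateSampleError:
        raise NoConsensusError("consensus set degenerate for the final refit")
    if cfg.geometric_refine:
        model = _refine_geometric(model, p[best_mask])

    res = model.residuals(p)
    mask = res <= th
    if mask.sum() < m:
        # refit drifted; fall back to the hypothesis consensus set
        mask = best_mask
    cost = float(np.sum(np.minimum(res * res, th2)))
    rms = float(np.sqrt(np.mean(res[mask] ** 2))) if mask.any() else float("nan")
    return SphereFitResult(model=model, inlier_mask=mask, msac_cost=cost,
                           rms_inlier_residual=rms, config=cfg)


def hjc_from_sweep(
    frames: list[UltrasoundFrame],
    cal: ProbeCalibration,
    sacrum: RigidTransform,
    cfg: MsacConfig | None = None,
    actual_speed: float | None = None,
) -> tuple[np.ndarray, SphereFitResult]:
    """Hip joint center (mm, sacrum-local) from one ultrasound sweep.

    Pools the world-frame reconstructions of all digitized frames, fits
    the femoral-head sphere with MSAC, and expresses the center in the
    sacrum-cluster (pelvic) frame.  Sweeps of roughly 10-50 digitized
    frames are expected; outside that range a warning is emitted.
    """
    used = [f for f in frames if f.n_pixels > 0]
    if not used:
        raise EmptySweepError("sweep has no digitized frames")
    if not 10 <= len(used) <= 50:
        warnings.warn(
            f"sweep has {len(used)} digitized frames; expected roughly 10-50",
            stacklevel=2,
        )
    clouds = [pixel_to_world(f, cal, actual_speed) for f in used]
    world = np.vstack(clouds)
    fit = msac_sphere(world, cfg)
    center_local = express_in_frame(fit.model.center, sacrum)
    return center_local, fit
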