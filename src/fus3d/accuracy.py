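"""Point-cloud accuracy of ultrasound bone-surface reconstructions.

A reconstructed (query) cloud is compared against a ground-truth
reference -- a dense laser-scan point cloud or a triangle mesh -- already
expressed in the same marker-cluster frame.  Accuracy is the per-point
minimal Euclidean distance; points beyond 1.5 interquartile ranges
outside the 25th/75th percentiles are flagged as outliers, and summary
statistics are reported over all points with the outlier fraction
alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .errors import TooFewPointsError

__all__ = [
    "AccuracyResult",
    "min_distances",
    "classify_outliers",
    "summarize_accuracy",
    "heatmap_export",
]

IQR_FACTOR = 1.5


@dataclass(frozen=True)
class AccuracyResult:
    distances: np.ndarray  # per query point, mm
    outlier_mask: np.ndarray  # bool per query point
    summary: dict[str, float]  # mean/sd/min/max/median/q1/q3, mm
    outlier_fraction: float  # percent
    excluded_outliers: bool = False

    def to_dict(self) -> dict:
        return {
            "summary_mm": self.summary,
            "outlier_fraction_pct": self.outlier_fraction,
            "n_points": int(self.distances.size),
            "n_outliers": int(np.count_nonzero(self.outlier_mask)),
            "excluded_outliers": self.excluded_outliers,
        }


def _mesh_min_distances(mesh: trimesh.Trimesh, q: np.ndarray) -> np.ndarray:
    """Exact nearest-surface distances via centroid pruning.

    Candidate faces for a query point are all faces whose centroid lies
    within (nearest-centroid distance + the mesh's largest centroid-to-
    vertex radius); the true nearest face is always among them, and the
    exact point-triangle distance decides.
    """
    tris = mesh.triangles
    centroids = tris.mean(axis=1)
    radii = np.linalg.norm(tris - centroids[:, None, :], axis=2).max()
    tree = cKDTree(centroids)
    d_c, _ = tree.query(q, k=1)
    out = np.empty(q.shape[0])
    for i, (p, dc) in enumerate(zip(q, d_c)):
        cand = tree.query_ball_point(p, dc + radii + 1e-9)
        closest = trimesh.triangles.closest_point(
            tris[cand], np.tile(p, (len(cand), 1))
        )
        out[i] = np.linalg.norm(closest - p, axis=1).min()
    return out


def min_distances(query: np.ndarray, reference) -> np.ndarray:
    """Minimal Euclidean distance (mm) from each query point to the reference.

    ``reference`` may be an (m, 3) point cloud (nearest-vertex distance via
    a k-d tree) or a :class:`trimesh.Trimesh` (nearest point on the
    surface).  Output order matches the query order.
    """
    q = np.asarray(query, dtype=float).reshape(-1, 3)
    if q.shape[0] == 0:
        raise TooFewPointsError("query cloud is empty")
    if isinstance(reference, trimesh.Trimesh):
        return _mesh_min_distances(reference, q)
    ref = np.asarray(reference, dtype=float).reshape(-1, 3)
    if ref.shape[0] == 0:
        raise TooFewPointsError("reference cloud is empty")
    dist, _ = cKDTree(ref).query(q, k=1)
    return np.asarray(dist, dtype=float)


def classify_outliers(distances: np.ndarray, factor: float = IQR_FACTOR) -> np.ndarray:
    """Tukey-style outlier mask at ``factor`` x IQR beyond Q1/Q3.

    Quartiles use linear interpolation between order statistics; the
    boundaries are strict, so a zero-IQR sample has no outliers.
    """
    d = np.asarray(distances, dtype=float).ravel()
    if d.size < 4:
        raise TooFewPointsError(f"need >= 4 values, got {d.size}")
    q1, q3 = np.percentile(d, [25.0, 75.0])  # linear interpolation
    iqr = q3 - q1
    return (d < q1 - factor * iqr) | (d > q3 + factor * iqr)


def summarize_accuracy(
    distances: np.ndarray,
    outlier_mask: np.ndarray | None = None,
    exclude_outliers: bool = False,
) -> AccuracyResult:
    """Descriptive statistics of the minimal distances.

    Summaries cover all points by default; the outlier fraction is always
    reported separately.  ``exclude_outliers=True`` restricts the summary
    (not the fraction) to non-flagged points.
    """
    d = np.asarray(distances, dtype=float).ravel()
    mask = classify_outliers(d) if outlier_mask is None else np.asarray(outlier_mask, bool)
    if mask.shape != d.shape:
        raise ValueError("outlier mask length must match distances")
    used = d[~mask] if exclude_outliers else d
    summary = {
        "mean": float(np.mean(used)),
        "sd": float(np.std(used, ddof=1)) if used.size > 1 else 0.0,
        "min": float(np.min(used)),
        "max": float(np.max(used)),
        "median": float(np.median(used)),
        "q1": float(np.percentile(used, 25.0)),
        "q3": float(np.percentile(used, 75.0)),
    }
    frac = 100.0 * float(np.count_nonzero(mask)) / d.size
    return AccuracyResult(d, mask, summary, frac, excluded_outliers=exclude_outliers)


def _ramp_colors(values: np.ndarray, vmin: float, vmax: float) -> np.ndarray:
    """Blue -> red linear ramp (uint8 RGBA); red marks larger distances."""
    if vmax <= vmin:
        t = np.zeros_like(values)
    else:
        t = np.clip((values - vmin) / (vmax - vmin), 0.0, 1.0)
    rgba = np.empty((values.size, 4), dtype=np.uint8)
    rgba[:, 0] = np.round(255 * t)
    rgba[:, 1] = 0
    rgba[:, 2] = np.round(255 * (1.0 - t))
    rgba[:, 3] = 255
    return rgba


def heatmap_export(
    query: np.ndarray,
    distances: np.ndarray,
    path,
    vmin: float = 0.0,
    vmax: float | None = None,
) -> dict:
    """Write a distance heatmap point cloud (ASCII PLY with vertex colors).

    Returns the color-scale metadata that was baked into the file.
    """
    q = np.asarray(query, dtype=float).reshape(-1, 3)
    d = np.asarray(distances, dtype=float).ravel()
    if q.shape[0] != d.size:
        raise ValueError("query and distances lengths differ")
    if vmax is None:
        vmax = float(d.max()) if d.size else 1.0
    colors = _ramp_colors(d, vmin, vmax)
    cloud = trimesh.PointCloud(q, colors=colors)
    cloud.export(str(path), file_type="ply", encoding="ascii")
    return {"vmin_mm": float(vmin), "vmax_mm": float(vmax), "colormap": "blue-red linear"}
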