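"""File I/O: marker/pixel CSVs, point clouds, configs, and reports.

All lengths are millimetres, speeds m/s, temperatures degC; files carry
their units in headers or metadata.  Motion-capture vendor formats are
not parsed -- the documented CSV export schema below is the ingestion
contract:

* markers: ``frame,label,x,y,z``
* digitized pixels: ``frame,u,v``
* landmark records: ``subject_id,group,side,method,session,x_ml,y_ap,z_si``
* cohort: ``subject_id,group,fmt``
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml

from . import __version__
from .errors import ParseError
from .geometry import ProbeCalibration, RigidTransform, cluster_frame
from .reliability import TestRetestDataset

__all__ = [
    "read_markers",
    "marker_cluster_at",
    "read_pixels",
    "read_cloud",
    "write_cloud",
    "read_landmark_records",
    "write_landmark_records",
    "dataset_from_records",
    "load_config",
    "calibration_from_config",
    "write_report",
]


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")


def _check_finite(df: pd.DataFrame, cols: list[str], path) -> None:
    bad = df.index[df[cols].isna().any(axis=1)]
    if len(bad):
        # +2: header line plus 1-based indexing
        raise ParseError(f"{path}: malformed value in row {int(bad[0]) + 2}")


def read_markers(path) -> pd.DataFrame:
    """Marker trajectories from CSV (frame, label, x, y, z; mm)."""
    df = pd.read_csv(path)
    _require_columns(df, ["frame", "label", "x", "y", "z"], path)
    _check_finite(df, ["frame", "x", "y", "z"], path)
    return df


def marker_cluster_at(markers: pd.DataFrame, frame: int, labels: list[str]) -> RigidTransform:
    """Cluster frame from one capture frame, markers ordered by ``labels``."""
    sub = markers[markers["frame"] == frame].set_index("label")
    missing = [lab for lab in labels if lab not in sub.index]
    if missing:
        raise ParseError(f"frame {frame}: missing markers {missing}")
    pts = np.array([sub.loc[lab, ["x", "y", "z"]].to_numpy(dtype=float) for lab in labels])
    return cluster_frame(pts)


def read_pixels(path) -> dict[int, np.ndarray]:
    """Digitized pixels from CSV (frame, u, v) -> {frame: (k, 2) array}."""
    df = pd.read_csv(path)
    _require_columns(df, ["frame", "u", "v"], path)
    _check_finite(df, ["frame", "u", "v"], path)
    return {
        int(f): g[["u", "v"]].to_numpy(dtype=float)
        for f, g in df.groupby("frame", sort=True)
    }


def read_cloud(path) -> np.ndarray:
    """Point cloud from PLY (ASCII or binary) or CSV (x, y, z; mm)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        _require_columns(df, ["x", "y", "z"], path)
        _check_finite(df, ["x", "y", "z"], path)
        return df[["x", "y", "z"]].to_numpy(dtype=float)
    loaded = trimesh.load(str(path))
    return np.asarray(loaded.vertices, dtype=float)


def write_cloud(points: np.ndarray, path, binary: bool = False) -> None:
    """Write a cloud as PLY (ascii default) or CSV depending on suffix."""
    path = Path(path)
    p = np.asarray(points, dtype=float).reshape(-1, 3)
    if path.suffix.lower() == ".csv":
        pd.DataFrame(p, columns=["x", "y", "z"]).to_csv(path, index=False)
        return
    cloud = trimesh.PointCloud(p)
    cloud.export(str(path), file_type="ply", encoding="binary" if binary else "ascii")


_RECORD_COLS = ["subject_id", "group", "side", "method", "session", "x_ml", "y_ap", "z_si"]


def read_landmark_records(path) -> pd.DataFrame:
    """Landmark record table (mm, pelvic frame) from CSV."""
    df = pd.read_csv(path)
    _require_columns(df, _RECORD_COLS, path)
    _check_finite(df, ["x_ml", "y_ap", "z_si"], path)
    return df[_RECORD_COLS]


def write_landmark_records(df: pd.DataFrame, path) -> None:
    _require_columns(df, _RECORD_COLS, path)
    df[_RECORD_COLS].to_csv(path, index=False)


def dataset_from_records(records: pd.DataFrame, cohort: pd.DataFrame) -> TestRetestDataset:
    """Assemble the test-retest dataset from long-format landmark records.

    ``records`` follows the landmark CSV schema (one row per session);
    ``cohort`` maps subject_id to group and fmt (% body mass).  Legs
    missing either session are dropped and counted.
    """
    _require_columns(cohort, ["subject_id", "group", "fmt"], "cohort")
    wide = records.pivot_table(
        index=["subject_id", "side", "method"],
        columns="session",
        values=["x_ml", "y_ap", "z_si"],
        aggfunc="first",
    )
    rows = []
    for (subj, side, method), r in wide.iterrows():
        rows.append({
            "subject_id": subj, "side": side, "method": method,
            "ap_test": r.get(("y_ap", "test"), np.nan),
            "ml_test": r.get(("x_ml", "test"), np.nan),
            "si_test": r.get(("z_si", "test"), np.nan),
            "ap_retest": r.get(("y_ap", "retest"), np.nan),
            "ml_retest": r.get(("x_ml", "retest"), np.nan),
            "si_retest": r.get(("z_si", "retest"), np.nan),
        })
    df = pd.DataFrame(rows).merge(
        cohort[["subject_id", "group", "fmt"]], on="subject_id", how="left"
    )
    return TestRetestDataset.from_frame(df)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def calibration_from_config(cfg: dict) -> ProbeCalibration:
    """Probe calibration from a config block (units: mm, m/s)."""
    block = cfg["calibration"] if "calibration" in cfg else cfg
    T = RigidTransform(
        np.asarray(block.get("image_to_probe_rotation", np.eye(3).tolist()), dtype=float),
        np.asarray(block.get("image_to_probe_translation_mm", [0, 0, 0]), dtype=float),
    )
    return ProbeCalibration(
        image_to_probe=T,
        pixel_spacing_lateral=float(block["pixel_spacing_lateral_mm"]),
        pixel_spacing_axial=float(block["pixel_spacing_axial_mm"]),
        calibration_speed=float(block.get("calibration_speed_m_s", 1540.0)),
    )


def _config_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.bool_):
            return bool(o)
        if hasattr(o, "__dict__"):
            return {k: v for k, v in o.__dict__.items()}
        return super().default(o)


def write_report(results: dict, path, seed: int | None = None, config: dict | None = None) -> dict:
    """Write a machine-readable JSON report with reproducibility metadata."""
    payload = {
        "metadata": {
            "software": f"fus3d {__version__}",
            "seed": seed,
            "config_hash": _config_hash(config or {}),
            "units": {"length": "mm", "speed": "m/s", "temperature": "degC"},
        },
        "results": results,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, cls=_NumpyEncoder)
    return payload
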