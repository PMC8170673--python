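"""Sacrum-cluster pelvic frame and ASIS landmark extraction.

The rigid marker cluster taped to the sacrum stays in place between the
test and retest sessions and therefore defines a shared local pelvic
coordinate system.  All landmark coordinates are reported in this frame
with declared anatomical axis labels.  The anterior superior iliac spine
(ASIS) is taken as the most anterior digitized surface point of a sweep,
mirroring manual selection on the ultrasound images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyContourError
from .geometry import RigidTransform, cluster_frame

__all__ = [
    "DEFAULT_AXIS_LABELS",
    "PelvicFrame",
    "LandmarkRecord",
    "pelvic_frame_from_sacrum",
    "select_asis",
    "pelvic_width",
]

# anatomical labels of the cluster-local axes; positive direction convention:
# anterior, subject's left, and superior are positive
DEFAULT_AXIS_LABELS: dict[str, str] = {
    "x": "med-lat",
    "y": "ant-post",
    "z": "sup-inf",
}

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class PelvicFrame:
    """Local pelvic frame plus the anatomical meaning of its axes."""

    transform: RigidTransform
    axis_labels: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_AXIS_LABELS))

    def __post_init__(self) -> None:
        if sorted(self.axis_labels) != ["x", "y", "z"]:
            raise ValueError("axis_labels must map exactly x, y, z")
        if sorted(self.axis_labels.values()) != ["ant-post", "med-lat", "sup-inf"]:
            raise ValueError("labels must be a permutation of ant-post/med-lat/sup-inf")

    def axis_index(self, label: str) -> int:
        """Column index of the local axis carrying an anatomical label."""
        for axis, lab in self.axis_labels.items():
            if lab == label:
                return _AXIS_INDEX[axis]
        raise KeyError(label)

    @property
    def anterior_axis(self) -> int:
        return self.axis_index("ant-post")


@dataclass(frozen=True)
class LandmarkRecord:
    """One landmark observation in the pelvic frame."""

    subject_id: str
    group: str  # lean | obese
    side: str  # left | right
    method: str  # MMP | IPT | 3DFUS | 3DFUS-HJC
    session: str  # test | retest
    position: np.ndarray  # (3,), mm, pelvic frame

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be left/right, got {self.side!r}")
        if self.session not in ("test", "retest"):
            raise ValueError(f"session must be test/retest, got {self.session!r}")
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float).reshape(3))


def pelvic_frame_from_sacrum(
    markers: np.ndarray,
    axis_labels: dict[str, str] | None = None,
) -> PelvicFrame:
    """Pelvic frame from the sacrum marker cluster.

    Wraps :func:`fus3d.geometry.cluster_frame` (origin at the first marker,
    x toward the second, z normal to the marker plane) and attaches the
    declared anatomical axis labels.
    """
    T = cluster_frame(markers)
    return PelvicFrame(T, dict(axis_labels or DEFAULT_AXIS_LABELS))


def select_asis(points: np.ndarray, anterior_axis: int = 1) -> np.ndarray:
    """Most anterior point of a pooled digitized sweep (pelvic frame, mm).

    Ties on the anterior coordinate resolve to the lowest input index.
    """
    p = np.asarray(points, dtype=float).reshape(-1, 3)
    if p.shape[0] == 0:
        raise EmptyContourError("no digitized points to select the ASIS from")
    return p[int(np.argmax(p[:, anterior_axis]))].copy()


def pelvic_width(asis_left: np.ndarray, asis_right: np.ndarray) -> float:
    """Euclidean distance (mm) between the left and right ASIS."""
    a = np.asarray(asis_left, dtype=float).reshape(3)
    b = np.asarray(asis_right, dtype=float).reshape(3)
    return float(np.linalg.norm(a - b))
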