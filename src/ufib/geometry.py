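"""Streamline geometry primitives.

All geometry lives in one coordinate frame: world millimetres, RAS
orientation.  A streamline is a float64 array of shape ``(n, 3)`` with
``n >= 2`` ordered points and no zero-length segments; a tractogram is a
list of such arrays plus a free-text provenance tag.  Keeping streamlines
as plain arrays (rather than wrapping every polyline in an object) matches
how tractography toolkits treat them and keeps the hot loops vectorised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "Tractogram",
    "ScalarVolume",
    "as_streamline",
    "streamline_length",
    "endpoint_distance",
    "cumulative_arclength",
    "resample_equidistant",
    "endpoint_centroid",
]


def as_streamline(points: np.ndarray) -> np.ndarray:
    """Validate and canonicalise a polyline into a streamline array.

    Consecutive duplicate points (zero-length segments) are removed; the
    result must retain at least two points.

    Parameters
    ----------
    points
        Array-like of shape ``(n, 3)``, world mm.

    Returns
    -------
    float64 array of shape ``(m, 3)`` with ``m >= 2`` and no repeated
    consecutive points.

    Raises
    ------
    ValueError
        If the input is not ``(n, 3)`` or degenerates to fewer than two
        distinct consecutive points.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"streamline must be (n, 3), got shape {pts.shape}")
    if len(pts) >= 2:
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        keep = np.concatenate([[True], seg > 0.0])
        pts = pts[keep]
    if len(pts) < 2:
        raise ValueError("streamline has fewer than 2 distinct points")
    return pts


@dataclass
class Tractogram:
    """A collection of streamlines sharing one world space (RAS mm)."""

    streamlines: list[np.ndarray] = field(default_factory=list)
    space_id: str = "world-ras-mm"

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.streamlines[i]


@dataclass
class ScalarVolume:
    """A 3-D scalar map (one DTI metric) with a voxel-to-world affine."""

    grid: np.ndarray
    affine: np.ndarray
    metric_name: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.grid.ndim != 3:
            raise ValueError("grid must be 3-D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")


def streamline_length(s: np.ndarray) -> float:
    """Arc length: the sum of Euclidean segment lengths, in mm."""
    s = np.asarray(s, dtype=np.float64)
    return float(np.linalg.norm(np.diff(s, axis=0), axis=1).sum())


def endpoint_distance(s: np.ndarray) -> float:
    """Euclidean distance between the first and last point, in mm."""
    s = np.asarray(s, dtype=np.float64)
    return float(np.linalg.norm(s[-1] - s[0]))


def cumulative_arclength(s: np.ndarray) -> np.ndarray:
    """Cumulative arc length at each point, starting at 0."""
    s = np.asarray(s, dtype=np.float64)
    seg = np.linalg.norm(np.diff(s, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_equidistant(s: np.ndarray, n: int) -> np.ndarray:
    """Resample a streamline to exactly ``n`` points equispaced in arc length.

    Piecewise-linear interpolation along the cumulative arc length; the
    first and last points are preserved exactly.

    Raises
    ------
    ValueError
        If ``n < 2``.
    """
    if n < 2:
        raise ValueError(f"node count must be >= 2, got {n}")
    s = np.asarray(s, dtype=np.float64)
    t = cumulative_arclength(s)
    ti = np.linspace(0.0, t[-1], n)
    out = np.empty((n, 3), dtype=np.float64)
    for k in range(3):
        out[:, k] = np.interp(ti, t, s[:, k])
    out[0] = s[0]
    out[-1] = s[-1]
    return out


def endpoint_centroid(streamlines, end: str = "first") -> np.ndarray:
    """Arithmetic mean of one terminal end over a bundle of streamlines.

    ``end`` selects ``"first"`` or ``"last"`` points.  The caller is
    responsible for orientation alignment (see clustering) so that "first"
    means the same anatomical end on every member.
    """
    streamlines = list(streamlines)
    if not streamlines:
        raise ValueError("empty streamline sequence")
    if end not in ("first", "last"):
        raise ValueError(f"end must be 'first' or 'last', got {end!r}")
    idx = 0 if end == "first" else -1
    pts = np.array([np.asarray(s, dtype=np.float64)[idx] for s in streamlines])
    return pts.mean(axis=0)
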