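"""Medial-path (colon centerline) representation and polyline utilities."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core_io import ValidationError

__all__ = ["MedialPath", "resample_polyline", "smooth_polyline", "polyline_arc_length"]


def polyline_arc_length(points: np.ndarray) -> np.ndarray:
    """Cumulative arc length (mm) along a polyline, starting at 0."""
    pts = np.asarray(points, dtype=np.float64)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline at uniform arc-length steps (endpoints kept)."""
    pts = np.asarray(points, dtype=np.float64)
    s = polyline_arc_length(pts)
    total = s[-1]
    if total <= 0:
        return pts[:1].copy()
    n = max(int(np.ceil(total / step)), 1)
    targets = np.linspace(0.0, total, n + 1)
    out = np.empty((len(targets), 3))
    for c in range(3):
        out[:, c] = np.interp(targets, s, pts[:, c])
    return out


def smooth_polyline(points: np.ndarray, window: int, pinned: np.ndarray | None = None) -> np.ndarray:
    """Moving-average smoothing; endpoints and ``pinned`` indices stay fixed."""
    pts = np.asarray(points, dtype=np.float64)
    if window <= 1 or len(pts) <= 2:
        return pts.copy()
    half = window // 2
    out = pts.copy()
    for i in range(1, len(pts) - 1):
        lo, hi = max(0, i - half), min(len(pts), i + half + 1)
        out[i] = pts[lo:hi].mean(axis=0)
    if pinned is not None:
        out[np.asarray(pinned, dtype=int)] = pts[np.asarray(pinned, dtype=int)]
    return out


@dataclass
class MedialPath:
    """Ordered world-coordinate polyline approximating the colon centerline.

    ``boundary_indices`` holds the indices of the five anatomical boundaries
    (cecum start, ascending/transverse, transverse/descending,
    descending/pelvic, pelvic end), so segment ``k`` (1-based, 1 = ascending)
    spans points ``boundary_indices[k-1] .. boundary_indices[k]``.
    """

    points: np.ndarray
    boundary_indices: np.ndarray
    arc_length: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        self.boundary_indices = np.asarray(self.boundary_indices, dtype=int)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValidationError("path points must have shape (n, 3)")
        if len(self.points) >= 2:
            steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
            if np.any(steps == 0):
                raise ValidationError("consecutive path points must be distinct")
        if self.arc_length is None:
            self.arc_length = polyline_arc_length(self.points)
        else:
            self.arc_length = np.asarray(self.arc_length, dtype=np.float64)
        if len(self.boundary_indices) > 0:
            if len(self.boundary_indices) != 5:
                raise ValidationError("boundary_indices must hold the 5 anatomical boundaries")
            if np.any(np.diff(self.boundary_indices) <= 0):
                raise ValidationError("boundary_indices must be strictly increasing")
            if self.boundary_indices[0] != 0 or self.boundary_indices[-1] != len(self.points) - 1:
                raise ValidationError("path must start and end at the first/last boundary")
        self._tree: cKDTree | None = None

    @property
    def total_length(self) -> float:
        return float(self.arc_length[-1])

    def segment_lengths(self) -> dict[int, float]:
        """Arc length (mm) of each of the four colon segments."""
        b = self.boundary_indices
        return {
            k: float(self.arc_length[b[k]] - self.arc_length[b[k - 1]]) for k in range(1, 5)
        }

    def segment_of_index(self, idx: np.ndarray) -> np.ndarray:
        """Segment label (1-4) of path point index(es)."""
        b = self.boundary_indices
        # interior boundaries split the index range; searchsorted with side
        # 'right' puts a boundary point into the lower segment
        return np.clip(np.searchsorted(b[1:4], np.asarray(idx), side="left") + 1, 1, 4)

    def _kdtree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.points)
        return self._tree

    def distance_to(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(distance mm, index of nearest path point) for world point(s)."""
        d, i = self._kdtree().query(np.atleast_2d(points))
        return d, i

    def tangents(self) -> np.ndarray:
        """Unit tangent at each path point (central differences)."""
        t = np.gradient(self.points, axis=0)
        norms = np.linalg.norm(t, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return t / norms
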