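"""Gyrification index (GI) from 2D cortical section contours.

GI is the ratio of the cortical contour's arc length to that of a smooth
outer outline enclosing it; 1 means lissencephalic (smooth), >1 folded. The
"smoothly enclosing" outline is the convex hull of the contour points,
which is parameter-free and makes GI >= 1 for every closed contour. A local
GI profiles folding along the outer outline in sliding arc-length windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import LineString, Point


@dataclass
class Contour:
    """Ordered 2D points; ``closed`` means an implicit first-last segment."""

    points: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("contour points must be an (n, 2) array")
        if len(self.points) < 3:
            raise ValueError("a contour needs at least 3 points")
        diffs = np.diff(self.points, axis=0)
        if (np.linalg.norm(diffs, axis=1) == 0).any():
            raise ValueError("contour has two identical consecutive points")
        if self.closed and np.allclose(self.points[0], self.points[-1]):
            self.points = self.points[:-1]
            if len(self.points) < 3:
                raise ValueError("a closed contour needs at least 3 distinct points")


@dataclass
class GyrificationResult:
    gi: float
    inner_length: float
    outer_length: float
    window_results: list[tuple[tuple[float, float], float]] | None = None


def contour_length(c: Contour) -> float:
    """Sum of Euclidean segment lengths (plus the closing segment if closed)."""
    pts = c.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
    if c.closed:
        seg += float(np.linalg.norm(pts[0] - pts[-1]))
    return float(seg)


def enclosing_outline(c: Contour) -> Contour:
    """Convex hull of the contour points as a closed contour (CCW order)."""
    if not c.closed:
        raise ValueError("enclosing outline requires a closed contour")
    try:
        hull = ConvexHull(c.points)
    except QhullError as exc:
        raise ValueError(f"degenerate contour (collinear points?): {exc}") from exc
    return Contour(points=c.points[hull.vertices], closed=True)


def gyrification_index(c: Contour) -> GyrificationResult:
    """GI = inner contour length / convex-hull outline length (>= 1)."""
    inner = contour_length(c)
    outer = contour_length(enclosing_outline(c))
    return GyrificationResult(gi=inner / outer, inner_length=inner, outer_length=outer)


def _closed_ring(points: np.ndarray) -> LineString:
    return LineString(np.vstack([points, points[:1]]))


def local_gi(c: Contour, window_arc: float, step_arc: float) -> GyrificationResult:
    """Sliding-window GI along the outer outline.

    Each window covers ``window_arc`` of outer-outline arc length, advanced
    by ``step_arc`` (windows wrap around the closed outline). Every inner
    segment is assigned to windows by the nearest-point projection of its
    midpoint onto the outline, and the local GI of a window is the assigned
    inner arc length divided by ``window_arc``.
    """
    outline = enclosing_outline(c)
    outer_len = contour_length(outline)
    if not 0 < window_arc < outer_len:
        raise ValueError("window_arc must be positive and smaller than the outline length")
    if step_arc <= 0:
        raise ValueError("step_arc must be positive")
    ring = _closed_ring(outline.points)
    pts = c.points
    closed_pts = np.vstack([pts, pts[:1]]) if c.closed else pts
    seg_starts = closed_pts[:-1]
    seg_ends = closed_pts[1:]
    mids = 0.5 * (seg_starts + seg_ends)
    seg_lens = np.linalg.norm(seg_ends - seg_starts, axis=1)
    positions = np.array([ring.project(Point(m)) for m in mids])

    # guard against a float-edge duplicate window when step divides the
    # outline length exactly
    starts = np.arange(0.0, outer_len - 1e-9 * max(1.0, outer_len), step_arc)
    windows = []
    for s in starts:
        e = s + window_arc
        if e <= outer_len:
            in_win = (positions >= s) & (positions < e)
        else:  # wrap-around
            in_win = (positions >= s) | (positions < e - outer_len)
        gi = float(seg_lens[in_win].sum() / window_arc)
        windows.append(((float(s), float(e % outer_len if e > outer_len else e)), gi))
    inner = contour_length(c)
    return GyrificationResult(
        gi=inner / outer_len,
        inner_length=inner,
        outer_length=outer_len,
        window_results=windows,
    )
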