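"""Closed 2D cell outlines: resegmentation, long axis, shape metrics.

The whole-cell simulator represents the cell boundary as a closed polygon
with a periodic arc-length coordinate.  Resegmentation interpolates with
periodic Catmull-Rom splines, which (unlike repeated linear interpolation)
does not erode convex regions.  The "microtubule" long axis is the local
maximum of vertex-pair distance found by hill climbing, and the shape
metrics (bend as sin^2 of the axis deflection, tip-local width) classify
cells as straight / bent / bulged.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString

__all__ = [
    "CellOutline2D",
    "ShapeMetrics2D",
    "OutlineSelfIntersectionError",
    "resegment_outline",
    "find_long_axis",
    "shape_metrics",
    "polygon_area",
]

BEND_THRESHOLD = 0.0015
WIDTH_THRESHOLD = 3.45  # um


class OutlineSelfIntersectionError(RuntimeError):
    pass


def polygon_area(x: np.ndarray, y: np.ndarray) -> float:
    """Signed shoelace area (positive for counter-clockwise)."""
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class CellOutline2D:
    """Closed polygonal cell boundary (vertices in um, counter-clockwise)."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.size != self.y.size or self.x.size < 4:
            raise ValueError("outline needs >= 4 (x, y) vertices")
        if polygon_area(self.x, self.y) < 0:
            self.x = self.x[::-1].copy()
            self.y = self.y[::-1].copy()

    @property
    def n_points(self) -> int:
        return self.x.size

    @property
    def seg_lengths(self) -> np.ndarray:
        return np.hypot(
            np.roll(self.x, -1) - self.x, np.roll(self.y, -1) - self.y
        )

    @property
    def arc(self) -> np.ndarray:
        """Periodic cumulative arc length per vertex (arc[0] = 0)."""
        seg = self.seg_lengths
        return np.concatenate([[0.0], np.cumsum(seg[:-1])])

    @property
    def perimeter(self) -> float:
        return float(self.seg_lengths.sum())

    @property
    def area(self) -> float:
        return polygon_area(self.x, self.y)

    def points(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def is_simple(self) -> bool:
        pts = self.points()
        return bool(LineString(np.vstack([pts, pts[:1]])).is_simple)

    def normals(self) -> np.ndarray:
        """Outward unit normals by central differences (CCW polygon)."""
        tx = np.roll(self.x, -1) - np.roll(self.x, 1)
        ty = np.roll(self.y, -1) - np.roll(self.y, 1)
        norm = np.hypot(tx, ty)
        return np.column_stack([ty / norm, -tx / norm])

    def spacing_drift(self) -> float:
        """Max relative deviation of segment lengths from their mean."""
        seg = self.seg_lengths
        mean = seg.mean()
        return float(np.max(np.abs(seg - mean)) / mean)


def _catmull_rom_dense(
    x: np.ndarray, y: np.ndarray, per_segment: int
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the periodic (uniform) Catmull-Rom spline densely."""
    n = x.size
    p0x, p1x = np.roll(x, 1), x
    p2x, p3x = np.roll(x, -1), np.roll(x, -2)
    p0y, p1y = np.roll(y, 1), y
    p2y, p3y = np.roll(y, -1), np.roll(y, -2)
    t = np.linspace(0.0, 1.0, per_segment, endpoint=False)
    t2, t3 = t * t, t * t * t
    b0 = -0.5 * t3 + t2 - 0.5 * t
    b1 = 1.5 * t3 - 2.5 * t2 + 1.0
    b2 = -1.5 * t3 + 2.0 * t2 + 0.5 * t
    b3 = 0.5 * t3 - 0.5 * t2
    dx = (
        np.outer(p0x, b0) + np.outer(p1x, b1) + np.outer(p2x, b2) + np.outer(p3x, b3)
    ).ravel()
    dy = (
        np.outer(p0y, b0) + np.outer(p1y, b1) + np.outer(p2y, b2) + np.outer(p3y, b3)
    ).ravel()
    return dx, dy


def resegment_outline(
    outline: CellOutline2D,
    spacing: float | None = None,
    n_target: int | None = None,
    per_segment: int = 8,
    check_simple: bool = False,
) -> CellOutline2D:
    """Return the outline re-sampled at uniform arc spacing along its
    periodic Catmull-Rom interpolant."""
    dx, dy = _catmull_rom_dense(outline.x, outline.y, per_segment)
    seg = np.hypot(np.diff(dx, append=dx[:1]), np.diff(dy, append=dy[:1]))
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if n_target is None:
        if spacing is None:
            n_target = outline.n_points
        else:
            n_target = max(int(round(total / spacing)), 8)
    s_new = np.linspace(0.0, total, n_target, endpoint=False)
    xx = np.interp(s_new, arc, np.concatenate([dx, dx[:1]]))
    yy = np.interp(s_new, arc, np.concatenate([dy, dy[:1]]))
    new = CellOutline2D(xx, yy)
    if check_simple and not new.is_simple():
        raise OutlineSelfIntersectionError("outline self-intersected")
    return new


# ---------------------------------------------------------------------------
# microtubule long axis


def find_long_axis(
    outline: CellOutline2D,
    start: tuple[int, int] | None = None,
    max_hop: int = 2,
) -> tuple[int, int]:
    """Vertex indices of a local maximum of pairwise distance.

    The "microtubule" line repeatedly moves either endpoint to a nearby
    vertex whenever that increases its length, stopping when no single
    move helps.  For spherocylinder-like shapes this is the global
    maximum.  A warm ``start`` makes per-step updates cheap.
    """
    x, y = outline.x, outline.y
    n = outline.n_points
    if start is None:
        i, j = int(np.argmin(x)), int(np.argmax(x))
    else:
        i, j = start[0] % n, start[1] % n

    def d2(a: int, b: int) -> float:
        return (x[a] - x[b]) ** 2 + (y[a] - y[b]) ** 2

    best = d2(i, j)
    hops = [k for h in range(1, max_hop + 1) for k in (h, -h)]
    improved = True
    while improved:
        improved = False
        for which in (0, 1):
            for h in hops:
                a = (i + h) % n if which == 0 else i
                b = j if which == 0 else (j + h) % n
                cand = d2(a, b)
                if cand > best:
                    i, j, best = a, b, cand
                    improved = True
        if not improved:
            # polish: joint window search escapes vertex-scale plateaus at
            # rounded tips, where single moves are flat to second order
            w = max(3, n // 32)
            ka = (i + np.arange(-w, w + 1)) % n
            kb = (j + np.arange(-w, w + 1)) % n
            dd = (x[ka][:, None] - x[kb][None, :]) ** 2 + (
                y[ka][:, None] - y[kb][None, :]
            ) ** 2
            ai, bj = np.unravel_index(int(np.argmax(dd)), dd.shape)
            if dd[ai, bj] > best * (1.0 + 1e-15):
                i, j, best = int(ka[ai]), int(kb[bj]), float(dd[ai, bj])
                improved = True
    return i, j


# ---------------------------------------------------------------------------
# shape metrics


@dataclass(frozen=True)
class ShapeMetrics2D:
    """Bend, tip width and straight/bent/bulged category of an outline."""

    bend: float
    width: float
    category: str  # "I" straight, "II" bent, "III" bulged
    axis_length: float


def _tip_width(outline: CellOutline2D, tip: int, scan_arc: float) -> float:
    """Tip-local width: scanning out to ``scan_arc`` of boundary on each
    side of the tip, the width at a point on one flank is its distance to
    the nearest point on the opposite flank; the maximum of these local
    cross distances is the measured width.  (The nearest-point pairing
    keeps the measure equal to the tube diameter for bent tubes, while a
    bulge raises it.)"""
    x, y = outline.x, outline.y
    n = outline.n_points
    h = outline.perimeter / n
    kmax = min(int(scan_arc / h), n // 2 - 1)
    if kmax < 2:
        return 0.0
    k = np.arange(1, kmax)
    ia = (tip + k) % n
    ib = (tip - k) % n
    dx = x[ia][:, None] - x[ib][None, :]
    dy = y[ia][:, None] - y[ib][None, :]
    d = np.hypot(dx, dy)
    cross = np.minimum(d.min(axis=1), d.min(axis=0))
    return float(np.max(cross))


def shape_metrics(
    outline: CellOutline2D,
    initial_axis: np.ndarray,
    endpoints: tuple[int, int] | None = None,
    bend_threshold: float = BEND_THRESHOLD,
    width_threshold: float = WIDTH_THRESHOLD,
) -> ShapeMetrics2D:
    """Classify an outline against the initial growth axis.

    ``initial_axis`` is the direction vector of the cell axis at t = 0.
    Bend is sin^2 of the angle between the current long axis and that
    vector; width is the maximal tip-local cross distance scanned to half
    the axis length from each tip.
    """
    if endpoints is None:
        endpoints = find_long_axis(outline)
    i, j = endpoints
    ax = np.array(
        [outline.x[j] - outline.x[i], outline.y[j] - outline.y[i]]
    )
    axis_len = float(np.hypot(*ax))
    v0 = np.asarray(initial_axis, dtype=float)
    cross = ax[0] * v0[1] - ax[1] * v0[0]
    bend = float(
        (cross / (axis_len * np.hypot(*v0))) ** 2
    )
    scan = axis_len / 2.0
    width = max(_tip_width(outline, i, scan), _tip_width(outline, j, scan))
    if bend <= bend_threshold and width <= width_threshold:
        cat = "I"
    elif bend > bend_threshold and width <= width_threshold:
        cat = "II"
    else:
        cat = "III"
    return ShapeMetrics2D(bend=bend, width=width, category=cat, axis_length=axis_len)
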