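"""Planar geometry for oriented (rotated) bounding boxes.

Coordinate convention
---------------------
Image frame, 0-based pixel coordinates: ``x`` is the column index and
increases rightward, ``y`` is the row index and increases downward, the
origin sits at the top-left corner.  Pixel ``(r, c)`` has its center at
``(c + 0.5, r + 0.5)``.

Polar angles are measured counterclockwise in the conventional *y-up*
sense, i.e. on the vector ``(dx, -dy)``: a point directly above the
origin in the image (smaller ``y``) is at 90 degrees, a point directly to
the right is at 0 degrees.  This is the convention under which the
left/right ear classification rule of :mod:`pigtherm.pairing` reproduces
correct pig anatomy (calibrated by the generator-based tests).

Points are plain length-2 sequences ``(x, y)``; functions return
``numpy`` arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum
from typing import NamedTuple, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon

__all__ = [
    "EarSide",
    "PolarPoint",
    "Line2D",
    "OrientedBox",
    "GeometryError",
    "DegenerateBoxError",
    "ParallelLinesError",
    "canonicalize",
    "box_from_center",
    "boxes_equal",
    "center",
    "center_distance",
    "nearest_vertex_pair",
    "extreme_vertices",
    "line_through",
    "line_intersection",
    "polar_angle",
    "rotated_iou",
    "rasterize",
    "rasterize_mask",
    "shoelace_area",
    "unit_vector",
]

#: |sin| of the angle between two lines below which they are treated as
#: parallel (no unique intersection point).
PARALLEL_TOL = 1e-6


class GeometryError(ValueError):
    """Base class for geometric failures."""


class DegenerateBoxError(GeometryError):
    """Vertex set does not form a valid convex quadrilateral."""


class ParallelLinesError(GeometryError):
    """Two lines are parallel (or nearly so); no unique intersection."""


class EarSide(IntEnum):
    """Detector class of an ear-root box: 0 = left ear, 1 = right ear."""

    LEFT = 0
    RIGHT = 1


class PolarPoint(NamedTuple):
    """A point in polar coordinates: radius in pixels, angle in degrees [0, 360)."""

    radius: float
    angle: float


def unit_vector(angle_deg: float) -> np.ndarray:
    """Unit vector at `angle_deg` (y-up degrees) expressed in image (y-down) coordinates."""
    a = math.radians(angle_deg)
    return np.array([math.cos(a), -math.sin(a)])


def shoelace_area(vertices: np.ndarray) -> float:
    """Unsigned polygon area by the shoelace formula."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def canonicalize(vertices: Sequence[Sequence[float]]) -> np.ndarray:
    """Reorder four vertices into the canonical cyclic order.

    The canonical cycle has positive shoelace orientation in image
    coordinates (counterclockwise in the y-down frame) and starts at the
    vertex with the smallest ``(y, x)``.  Idempotent; the point set is
    unchanged.

    Raises
    ------
    DegenerateBoxError
        If the points are not four distinct vertices of a strictly convex
        quadrilateral.
    """
    v = np.asarray(vertices, dtype=float)
    if v.shape != (4, 2):
        raise DegenerateBoxError(f"expected 4 vertices of shape (4, 2), got {v.shape}")
    if not np.all(np.isfinite(v)):
        raise DegenerateBoxError("vertices must be finite")
    centroid = v.mean(axis=0)
    rel = v - centroid
    order = np.argsort(np.arctan2(rel[:, 1], rel[:, 0]), kind="stable")
    v = v[order]
    # convexity / non-degeneracy: all turns in the same (positive) direction
    edges = np.roll(v, -1, axis=0) - v
    cross = edges[:, 0] * np.roll(edges, -1, axis=0)[:, 1] - edges[:, 1] * np.roll(edges, -1, axis=0)[:, 0]
    if np.any(cross <= 1e-9):
        raise DegenerateBoxError("vertices are collinear, duplicated, or not convex")
    start = np.lexsort((v[:, 0], v[:, 1]))[0]
    return np.roll(v, -start, axis=0)


@dataclass(frozen=True, eq=False)
class OrientedBox:
    """One ear-root region: four vertices (canonical order), class label, confidence.

    Vertices are canonicalized on construction, so two boxes covering the
    same quadrilateral compare equal vertex-by-vertex regardless of the
    order the caller supplied.
    """

    vertices: np.ndarray
    label: EarSide | None = None
    confidence: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "vertices", canonicalize(self.vertices))
        if self.label is not None:
            object.__setattr__(self, "label", EarSide(self.label))
        if self.confidence is not None:
            c = float(self.confidence)
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"confidence must be in [0, 1], got {c}")
            object.__setattr__(self, "confidence", c)

    @property
    def center(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    @property
    def area(self) -> float:
        return shoelace_area(self.vertices)

    def translated(self, offset: Sequence[float]) -> "OrientedBox":
        return OrientedBox(self.vertices + np.asarray(offset, dtype=float),
                           self.label, self.confidence)

    def mirrored_x(self, axis_x: float) -> "OrientedBox":
        """Reflect about the vertical line x = axis_x (label preserved as-is)."""
        v = self.vertices.copy()
        v[:, 0] = 2.0 * axis_x - v[:, 0]
        return OrientedBox(v, self.label, self.confidence)

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


def box_from_center(center_xy: Sequence[float], length: float, width: float,
                    axis_angle_deg: float, label: EarSide | None = None,
                    confidence: float | None = None) -> OrientedBox:
    """Rectangle with long axis along `axis_angle_deg` (y-up degrees)."""
    c = np.asarray(center_xy, dtype=float)
    u = unit_vector(axis_angle_deg)
    n = unit_vector(axis_angle_deg + 90.0)
    half_l, half_w = 0.5 * length, 0.5 * width
    verts = [c + s * half_l * u + t * half_w * n for s, t in ((1, 1), (1, -1), (-1, -1), (-1, 1))]
    return OrientedBox(np.array(verts), label, confidence)


def boxes_equal(a: OrientedBox, b: OrientedBox, tol: float = 1e-6) -> bool:
    """Geometric identity of two boxes (canonical vertices within `tol`)."""
    return bool(np.allclose(a.vertices, b.vertices, atol=tol))


def center(box: OrientedBox) -> np.ndarray:
    """Arithmetic mean of the four vertices."""
    return box.center


def center_distance(a: OrientedBox, b: OrientedBox) -> float:
    """Euclidean distance between box centers, in pixels."""
    return float(np.linalg.norm(a.center - b.center))


def nearest_vertex_pair(a: OrientedBox, b: OrientedBox) -> tuple[np.ndarray, np.ndarray]:
    """The closest pair of vertices (one from each box) over all 16 combinations.

    Ties are broken by canonical vertex index: lowest index in ``a`` first,
    then lowest in ``b``.
    """
    diff = a.vertices[:, None, :] - b.vertices[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    i, j = np.unravel_index(np.argmin(d2), d2.shape)  # argmin takes first on ties
    return a.vertices[i].copy(), b.vertices[j].copy()


def extreme_vertices(box: OrientedBox, base: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Vertices of `box` nearest to and farthest from `base` (ties by canonical index)."""
    p = np.asarray(base, dtype=float)
    d2 = np.sum((box.vertices - p) ** 2, axis=1)
    return box.vertices[int(np.argmin(d2))].copy(), box.vertices[int(np.argmax(d2))].copy()


@dataclass(frozen=True)
class Line2D:
    """Implicit line a*x + b*y + c = 0, normalized so a**2 + b**2 = 1.

    Unlike the point-slope form, this representation handles vertical
    lines.  The sign is fixed (a > 0, or a == 0 and b > 0) so that a line
    has a unique representation.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        norm = math.hypot(self.a, self.b)
        if norm < 1e-12:
            raise GeometryError("line coefficients (a, b) must not both be zero")
        a, b, c = self.a / norm, self.b / norm, self.c / norm
        if a < 0 or (a == 0 and b < 0):
            a, b, c = -a, -b, -c
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "c", c)

    def signed_distance(self, p: Sequence[float]) -> float:
        x, y = p
        return self.a * x + self.b * y + self.c


def line_through(p: Sequence[float], q: Sequence[float]) -> Line2D:
    """The unique line containing distinct points `p` and `q`."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    d = q - p
    if np.linalg.norm(d) < 1e-12:
        raise GeometryError("cannot construct a line through two identical points")
    a, b = d[1], -d[0]  # normal is the edge direction rotated 90 degrees
    c = -(a * p[0] + b * p[1])
    return Line2D(a, b, c)


def line_intersection(l1: Line2D, l2: Line2D) -> np.ndarray:
    """Intersection point of two non-parallel lines.

    Raises
    ------
    ParallelLinesError
        If |sin| of the angle between the lines is below ``PARALLEL_TOL``.
    """
    denom = l1.a * l2.b - l2.a * l1.b  # = sin(angle) for unit normals
    if abs(denom) < PARALLEL_TOL:
        raise ParallelLinesError("lines are parallel or nearly parallel")
    x = (l1.b * l2.c - l2.b * l1.c) / denom
    y = (l2.a * l1.c - l1.a * l2.c) / denom
    return np.array([x, y])


def polar_angle(p: Sequence[float], origin: Sequence[float]) -> PolarPoint:
    """Polar coordinates of `p` about `origin` (angle y-up counterclockwise, degrees)."""
    p = np.asarray(p, dtype=float)
    o = np.asarray(origin, dtype=float)
    v = p - o
    r = float(np.linalg.norm(v))
    if r < 1e-12:
        raise GeometryError("point coincides with the polar origin")
    ang = math.degrees(math.atan2(o[1] - p[1], p[0] - o[0])) % 360.0
    if ang == 360.0:
        ang = 0.0
    return PolarPoint(r, ang)


def rotated_iou(a: OrientedBox, b: OrientedBox) -> float:
    """Intersection-over-union of two oriented boxes via convex polygon clipping."""
    pa, pb = a.polygon(), b.polygon()
    inter = pa.intersection(pb).area
    union = pa.area + pb.area - inter
    if union <= 0:
        return 0.0
    return float(inter / union)


def rasterize_mask(box: OrientedBox, frame_shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers lie inside or on the boundary of `box`.

    `frame_shape` is ``(rows, cols)``.  A box entirely outside the frame
    yields an all-False mask.
    """
    rows, cols = int(frame_shape[0]), int(frame_shape[1])
    mask = np.zeros((rows, cols), dtype=bool)
    v = box.vertices
    r0 = max(0, int(math.floor(v[:, 1].min() - 0.5)))
    r1 = min(rows - 1, int(math.ceil(v[:, 1].max() - 0.5)))
    c0 = max(0, int(math.floor(v[:, 0].min() - 0.5)))
    c1 = min(cols - 1, int(math.ceil(v[:, 0].max() - 0.5)))
    if r0 > r1 or c0 > c1:
        return mask
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    xs = cc.ravel() + 0.5
    ys = rr.ravel() + 0.5
    inside = shapely.intersects_xy(box.polygon(), xs, ys)  # boundary-inclusive
    mask[rr.ravel()[inside], cc.ravel()[inside]] = True
    return mask


def rasterize(box: OrientedBox, frame_shape: tuple[int, int]) -> np.ndarray:
    """Pixel indices covered by `box`, as an (N, 2) array of (row, col).

    Membership is the pixel-center-inside test of :func:`rasterize_mask`;
    indices come out in row-major order.
    """
    mask = rasterize_mask(box, frame_shape)
    return np.argwhere(mask)
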