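"""Summary statistics of persistence diagrams.

A diagram with hundreds of thousands of points cannot be compared pairwise
(bottleneck or Wasserstein distances are far too expensive at this scale),
so each diagram is reduced to interpretable scalars: the point count, the
average lifetime, the area under the accumulative persistence function, and
shape descriptors (centroid, area, perimeter, filamentarity) of six summary
polygons — the regions under the first three persistence landscapes and the
99%, 95% and 90% convex peels of the point cloud.

Coordinate conventions: landscapes live in the rotated plane
``(t, y) = ((d + b) / 2, (d - b) / 2)``; convex peels stay in the raw
(birth, death) plane; the accumulative persistence function is a step
function of the midlife ``m = (d + b) / 2`` accumulating lifetimes
``d - b``.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import MultiPolygon, Polygon

from .persistence import PersistenceDiagram

__all__ = [
    "EmptyDiagramError",
    "DegenerateCloudError",
    "LandscapeFunction",
    "PolygonSummary",
    "count_points",
    "average_lifetime",
    "apf",
    "apf_area",
    "landscape",
    "landscape_polygon",
    "peel_polygon",
    "convex_peel",
    "polygon_summary",
]


class EmptyDiagramError(ValueError):
    """Statistic undefined on an empty diagram."""


class DegenerateCloudError(ValueError):
    """Convex peel needs at least 3 non-collinear points."""


@dataclass(frozen=True)
class PolygonSummary:
    """Shape descriptors of a summary polygon.

    ``filamentarity F = (P^2 - 4 pi A) / (P^2 + 4 pi A)`` is 0 for a disk
    and approaches 1 for thread-like shapes; the isoperimetric inequality
    keeps it in [0, 1].  A degenerate summary (empty landscape, collinear
    cloud) reports all-zero descriptors with ``degenerate=True`` so that
    downstream feature vectors keep a fixed length.
    """

    Cx: float
    Cy: float
    area: float
    perimeter: float
    filamentarity: float
    degenerate: bool = False

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.Cx, self.Cy, self.area, self.perimeter, self.filamentarity)


@dataclass(frozen=True)
class LandscapeFunction:
    """The k-th persistence landscape as a piecewise-linear function.

    ``breakpoints`` is an (m, 2) array of (t, value) knots, zero outside
    their range; slopes between knots are in {-1, 0, +1}.
    """

    k: int
    breakpoints: np.ndarray

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=np.float64)
        if len(self.breakpoints) == 0:
            return np.zeros_like(t)
        return np.interp(t, self.breakpoints[:, 0], self.breakpoints[:, 1], left=0.0, right=0.0)

    @property
    def is_zero(self) -> bool:
        return len(self.breakpoints) == 0 or bool(np.all(self.breakpoints[:, 1] <= 0))


def count_points(diagram: PersistenceDiagram) -> int:
    """Number of (birth, death) pairs in the diagram."""
    return len(diagram)


def average_lifetime(diagram: PersistenceDiagram) -> float:
    """Mean of death - birth over all pairs."""
    if len(diagram) == 0:
        raise EmptyDiagramError("average lifetime of an empty diagram")
    return float(diagram.lifetimes.mean())


def apf(diagram: PersistenceDiagram) -> tuple[np.ndarray, np.ndarray]:
    """Accumulative persistence function as (jump locations, step values).

    ``APF(t) = sum_i (d_i - b_i) 1{(d_i + b_i)/2 <= t}`` — lifetimes
    accumulated in order of midlife.  Returns the sorted midlives and the
    cumulative sums, i.e. the value of the step function at and after each
    jump.  Non-decreasing and right-continuous; the terminal value is the
    total lifetime.
    """
    if len(diagram) == 0:
        raise EmptyDiagramError("APF of an empty diagram")
    mid = (diagram.births + diagram.deaths) / 2.0
    life = diagram.lifetimes
    order = np.argsort(mid, kind="stable")
    return mid[order], np.cumsum(life[order])


def apf_area(diagram: PersistenceDiagram, field_range: tuple[float, float]) -> float:
    """Integral of the accumulative persistence function over ``field_range``.

    The integration domain is the value range of the standardized field the
    diagram came from, so that areas are comparable across images.
    """
    lo, hi = float(field_range[0]), float(field_range[1])
    if hi < lo:
        raise ValueError("field_range must satisfy lo <= hi")
    if len(diagram) == 0:
        raise EmptyDiagramError("APF of an empty diagram")
    mid = (diagram.births + diagram.deaths) / 2.0
    life = diagram.lifetimes
    # each lifetime contributes from its jump (clipped to lo) up to hi
    weight = np.clip(hi - np.maximum(mid, lo), 0.0, None)
    return float(np.sum(life * weight))


def _tent_key(pair: tuple[float, float]) -> tuple[float, float]:
    b, d = pair
    return (b, -d)


def landscape(diagram: PersistenceDiagram, k: int) -> LandscapeFunction:
    """Exact k-th persistence landscape by the sequential sweep algorithm.

    Each pair (b, d) erects a tent peaking at ``((b+d)/2, (d-b)/2)``; the
    k-th landscape is the k-th largest tent value at every t.  The sweep
    constructs lambda_1 from the (b asc, d desc)-sorted pairs, re-inserting
    the truncated remainders of overtaken tents for the next level, and
    repeats k times.  Zero function if the diagram has fewer than k points.
    """
    if k < 1:
        raise ValueError("landscape index k must be >= 1")
    pool = sorted(((float(b), float(d)) for b, d in diagram.pairs), key=_tent_key)
    pool = [p for p in pool if p[1] > p[0]]
    level = 0
    while pool:
        level += 1
        knots, pool = _sweep_one_landscape(pool)
        if level == k:
            return LandscapeFunction(k, np.asarray(knots))
    return LandscapeFunction(k, np.empty((0, 2)))


def _sweep_one_landscape(pool: list[tuple[float, float]]):
    """One pass of the landscape sweep: returns (knots of lambda, leftover pool)."""
    pool = list(pool)
    b, d = pool.pop(0)
    knots = [(b, 0.0), ((b + d) / 2.0, (d - b) / 2.0)]
    while True:
        # next tent reaching beyond the current death d
        nxt = None
        for i, (b2, d2) in enumerate(pool):
            if d2 > d:
                nxt = i
                break
        if nxt is None:
            # every remaining tent dies by d: they belong to deeper levels
            knots.append((d, 0.0))
            break
        b2, d2 = pool.pop(nxt)
        if b2 > d:
            knots.append((d, 0.0))
        if b2 >= d:
            knots.append((b2, 0.0))
        else:
            # tents cross at t = (b2 + d) / 2; the overlap (b2, d) waits
            # for the next landscape level
            knots.append(((b2 + d) / 2.0, (d - b2) / 2.0))
            bisect.insort(pool, (b2, d), key=_tent_key)
        knots.append(((b2 + d2) / 2.0, (d2 - b2) / 2.0))
        b, d = b2, d2
    return _dedup_knots(knots), pool


def _dedup_knots(knots: list[tuple[float, float]]) -> list[tuple[float, float]]:
    out = [knots[0]]
    for t, v in knots[1:]:
        if t == out[-1][0] and v == out[-1][1]:
            continue
        out.append((t, v))
    return out


def _landscape_lobes(fn: LandscapeFunction) -> list[Polygon]:
    """Closed polygons between the landscape and the t-axis, one per lobe."""
    lobes: list[Polygon] = []
    current: list[tuple[float, float]] = []
    pts = fn.breakpoints
    for i, (t, v) in enumerate(pts):
        current.append((float(t), float(v)))
        closes = v == 0.0 and len(current) > 1
        if closes or i == len(pts) - 1:
            if len(current) >= 3 and any(p[1] > 0 for p in current):
                if current[-1][1] != 0.0:
                    current.append((current[-1][0], 0.0))
                if current[0][1] != 0.0:
                    current.insert(0, (current[0][0], 0.0))
                poly = Polygon(current)
                if poly.area > 0:
                    lobes.append(poly)
            current = [(float(t), float(v))] if v == 0.0 else []
    return lobes


def landscape_polygon(diagram: PersistenceDiagram, k: int) -> PolygonSummary:
    """Descriptors of the region under the k-th landscape.

    The polygon is bounded above by lambda_k and below by the t-axis over
    its support.  Disconnected support is treated as a multipolygon: area
    and perimeter are additive over lobes and the centroid is area-weighted.
    An identically-zero landscape yields the all-zero degenerate summary.
    """
    fn = landscape(diagram, k)
    lobes = _landscape_lobes(fn) if not fn.is_zero else []
    if not lobes:
        return PolygonSummary(0.0, 0.0, 0.0, 0.0, 0.0, degenerate=True)
    return polygon_summary(MultiPolygon(lobes) if len(lobes) > 1 else lobes[0])


def peel_polygon(diagram: PersistenceDiagram, proportion: float) -> Polygon:
    """The convex-peel hull polygon itself, in (birth, death) axes.

    Raises :class:`DegenerateCloudError` if the cloud (or what remains of
    it after peeling) has fewer than 3 non-collinear points.
    """
    if not 0.0 < proportion <= 1.0:
        raise ValueError("proportion must lie in (0, 1]")
    pts = np.asarray(diagram.pairs, dtype=np.float64).copy()
    keep_at_least = math.ceil(proportion * len(pts))
    try:
        hull = ConvexHull(pts)
    except (QhullError, ValueError) as exc:
        raise DegenerateCloudError("need >= 3 non-collinear points") from exc
    while len(pts) - len(hull.vertices) >= keep_at_least:
        pts = np.delete(pts, hull.vertices, axis=0)
        try:
            hull = ConvexHull(pts)
        except (QhullError, ValueError) as exc:
            # remaining interior points are collinear: nothing left to peel
            raise DegenerateCloudError("peeled cloud became collinear") from exc
    return Polygon(pts[hull.vertices])


def convex_peel(diagram: PersistenceDiagram, proportion: float) -> PolygonSummary:
    """Convex-hull peel of the diagram point cloud in (birth, death) axes.

    Convex hulls are successively peeled away while at least
    ``ceil(proportion * n)`` points would remain; the summary polygon is
    the convex hull of the final retained set.  This trims outliers without
    letting the dense diagonal mass dominate the shape.
    """
    try:
        return polygon_summary(peel_polygon(diagram, proportion))
    except DegenerateCloudError:
        if not 0.0 < proportion <= 1.0:
            raise
        # fewer than 3 points or all collinear from the start: re-raise;
        # a cloud that degenerates mid-peel reports the degenerate summary
        try:
            ConvexHull(np.asarray(diagram.pairs, dtype=np.float64))
        except (QhullError, ValueError) as exc:
            raise DegenerateCloudError("need >= 3 non-collinear points") from exc
        return PolygonSummary(0.0, 0.0, 0.0, 0.0, 0.0, degenerate=True)


def polygon_summary(polygon: Polygon | MultiPolygon) -> PolygonSummary:
    """Centroid, area, perimeter and filamentarity of a polygon.

    Area by the shoelace formula, perimeter as total boundary length and
    the area-weighted polygon centroid (all via shapely).  A zero-area
    polygon gets filamentarity 1 (its thread-like limit) and the degenerate
    flag.
    """
    area = polygon.area
    perimeter = polygon.length
    if area == 0.0:
        return PolygonSummary(0.0, 0.0, 0.0, perimeter, 1.0, degenerate=True)
    c = polygon.centroid
    f = (perimeter**2 - 4 * math.pi * area) / (perimeter**2 + 4 * math.pi * area)
    return PolygonSummary(float(c.x), float(c.y), float(area), float(perimeter), float(f))
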