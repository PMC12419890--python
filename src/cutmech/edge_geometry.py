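"""Estimate cutting-edge radius and wedge angle from a digitized tip cross-section.

The measurement definitions mirror how blade tips are characterized from
milled-section micrographs: two lines are fitted along the straight flanks of
the cutting edge; the wedge angle is the interior angle between them; and the
edge radius is the radius of the smallest circle tangent to both flank lines
that still fits entirely within the material cross-section.

The contour is an ordered polyline in pixel coordinates with a known physical
scale.  Flank identification is automated deterministically: a vertex is
"straight" when the summed turning angle across a 5-point window stays below a
threshold (default 2 degrees); the two longest straight runs are the flanks,
each fitted by total least squares.  The smallest bitangent contained circle
is found by monotone bisection on the radius (centres lie on the interior
angle bisector, so tangency fixes the centre for each radius).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString, Point, Polygon

from .errors import (
    DegenerateGeometryError,
    EstimationFailureError,
    InvalidInputError,
    NoFlanksError,
)

__all__ = [
    "CrossSectionContour",
    "FlankFitConfig",
    "FlankLines",
    "EdgeGeometryEstimate",
    "fit_flank_lines",
    "wedge_angle",
    "edge_radius",
    "estimate_edge_geometry",
    "circle_fits",
]


@dataclass
class CrossSectionContour:
    """Ordered planar points (px) of a milled tip cross-section.

    The polyline runs from one flank end, around the tip, to the other flank
    end (open), or closes on itself.  ``scale`` converts pixels to metres.
    """

    points: np.ndarray  # (N, 2), px
    scale: float  # m per px
    specimen_id: str = ""
    cut_location: float | None = None  # normalized height on the tooth, 0-1

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise InvalidInputError("points must be an (N, 2) array")
        if self.points.shape[0] < 20:
            raise InvalidInputError("contour needs at least 20 points")
        if self.scale <= 0:
            raise InvalidInputError("scale must be > 0")
        if self.cut_location is not None and not 0 <= self.cut_location <= 1:
            raise InvalidInputError("cut_location must lie in [0, 1]")
        if not LineString(self.points).is_simple:
            raise InvalidInputError("contour polyline must be non-self-intersecting")


@dataclass(frozen=True)
class FlankFitConfig:
    """Deterministic criteria for the automated flank-line fit."""

    curvature_window_px: float = 10.0  # arc length per curvature window
    max_window_turning_deg: float = 2.0  # summed turning below this = straight
    min_run_length: int = 10  # vertices per admissible straight run
    min_flank_angle_deg: float = 1.0  # below this the flanks are "parallel"
    bisection_tol_px: float = 0.05  # radius bisection tolerance
    containment_tol_px: float = 0.01  # slack in the circle-in-polygon test


@dataclass(frozen=True)
class FlankLines:
    """Two TLS flank lines (point + unit direction, oriented away from the apex)."""

    point1: np.ndarray
    direction1: np.ndarray
    point2: np.ndarray
    direction2: np.ndarray
    apex: np.ndarray
    fit_residual_px: float  # rms orthogonal distance of run points to lines


@dataclass(frozen=True)
class EdgeGeometryEstimate:
    """Edge radius (m) and wedge angle (deg) of one cross-section."""

    edge_radius: float
    wedge_angle: float
    flank_lines: FlankLines
    fit_residual: float  # m

    def __post_init__(self) -> None:
        if self.edge_radius < 0:
            raise InvalidInputError("edge_radius must be >= 0")
        if not 0 < self.wedge_angle < 180:
            raise InvalidInputError("wedge_angle must lie in (0, 180)")


def _tls_line(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Total least squares line: centroid, unit direction, rms residual."""
    centroid = points.mean(axis=0)
    _, s, vt = np.linalg.svd(points - centroid, full_matrices=False)
    direction = vt[0]
    resid = s[1] / math.sqrt(len(points)) if len(points) > 1 else 0.0
    return centroid, direction, float(resid)


def _straight_runs(points: np.ndarray, config: FlankFitConfig) -> list[slice]:
    """Maximal runs of vertices whose windowed turning stays below threshold."""
    seg = np.diff(points, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    if np.any(seg_len == 0):
        keep = np.r_[True, seg_len > 0]
        points = points[keep]
        seg = np.diff(points, axis=0)
        seg_len = np.linalg.norm(seg, axis=1)
    heading = np.arctan2(seg[:, 1], seg[:, 0])
    turning = np.abs(np.angle(np.exp(1j * np.diff(heading))))  # at interior vertices
    # Sum turning across a window of fixed arc length: a gentle tip arc turns
    # by window/R radians per window, so it is flagged curved for any radius
    # up to curvature_window_px / max_window_turning (about 280 px at the
    # defaults), while digitization-scale wiggle on a flank stays below it.
    spacing = float(np.median(seg_len))
    w = max(int(round(config.curvature_window_px / spacing)) - 2, 1)
    kernel = np.ones(w)
    summed = np.convolve(turning, kernel, mode="same")
    straight = summed < math.radians(config.max_window_turning_deg)

    runs: list[slice] = []
    start = None
    for i, flag in enumerate(straight):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append(slice(start + 1, i + 1))  # vertex indices
            start = None
    if start is not None:
        runs.append(slice(start + 1, len(straight) + 1))
    return [r for r in runs if r.stop - r.start >= config.min_run_length]


def fit_flank_lines(
    contour: CrossSectionContour, config: FlankFitConfig = FlankFitConfig()
) -> FlankLines:
    """Fit the two straight flank lines and locate their intersection (apex).

    Raises :class:`NoFlanksError` if fewer than two straight runs are found
    and :class:`DegenerateGeometryError` if the flanks are nearly parallel.
    """
    pts = contour.points
    runs = _straight_runs(pts, config)
    if len(runs) < 2:
        raise NoFlanksError(
            f"contour {contour.specimen_id!r}: found {len(runs)} straight run(s), "
            "need 2 flanks"
        )
    runs = sorted(runs, key=lambda r: r.stop - r.start, reverse=True)[:2]
    runs = sorted(runs, key=lambda r: r.start)  # keep contour order
    c1, d1, res1 = _tls_line(pts[runs[0]])
    c2, d2, res2 = _tls_line(pts[runs[1]])

    cross = d1[0] * d2[1] - d1[1] * d2[0]
    angle_between = math.degrees(math.asin(min(1.0, abs(cross))))
    if angle_between < config.min_flank_angle_deg:
        raise DegenerateGeometryError(
            f"contour {contour.specimen_id!r}: flank lines are within "
            f"{config.min_flank_angle_deg} degrees of parallel"
        )
    # Intersection: c1 + t1*d1 = c2 + t2*d2.
    A = np.column_stack([d1, -d2])
    t = np.linalg.solve(A, c2 - c1)
    apex = c1 + t[0] * d1
    # Orient directions from the apex toward each run's centroid.
    if np.dot(d1, c1 - apex) < 0:
        d1 = -d1
    if np.dot(d2, c2 - apex) < 0:
        d2 = -d2
    resid = math.hypot(res1, res2) / math.sqrt(2)
    return FlankLines(
        point1=c1, direction1=d1, point2=c2, direction2=d2, apex=apex,
        fit_residual_px=resid,
    )


def wedge_angle(
    contour: CrossSectionContour, config: FlankFitConfig = FlankFitConfig()
) -> float:
    """Interior angle (degrees) between the two flank lines."""
    flanks = fit_flank_lines(contour, config)
    cosang = float(np.clip(np.dot(flanks.direction1, flanks.direction2), -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def _min_boundary_distance(center: np.ndarray, closed_pts: np.ndarray) -> float:
    """Minimum distance from a point to a closed polygonal boundary (vectorized)."""
    a = closed_pts[:-1]
    b = closed_pts[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom[denom == 0] = 1.0
    t = np.clip(np.einsum("ij,ij->i", center - a, ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return float(np.min(np.linalg.norm(center - proj, axis=1)))


def circle_fits(
    r_px: float,
    apex: np.ndarray,
    bisector: np.ndarray,
    half_angle_rad: float,
    closed_pts: np.ndarray,
    polygon: Polygon,
    tol_px: float = 0.01,
) -> bool:
    """Containment predicate: does the bitangent circle of radius r fit?

    The centre sits on the interior bisector at distance ``r/sin(half_angle)``
    from the apex (tangency to both flank lines); the circle fits when the
    centre is inside the cross-section polygon and its distance to every
    boundary segment is at least ``r - tol_px``.  Containment is monotone in
    r for wedge-plus-tangent-arc tips, which is what makes bisection valid.
    """
    center = apex + (r_px / math.sin(half_angle_rad)) * bisector
    if not polygon.contains(Point(center)):
        return False
    return _min_boundary_distance(center, closed_pts) >= r_px - tol_px


def _close(points: np.ndarray) -> np.ndarray:
    if np.allclose(points[0], points[-1]):
        return points
    return np.vstack([points, points[0]])


def edge_radius(
    contour: CrossSectionContour, config: FlankFitConfig = FlankFitConfig()
) -> float:
    """Smallest bitangent circle radius (m) that fits within the cross-section.

    Solved by bracketing on a log-spaced radius grid followed by bisection to
    ``bisection_tol_px``.  The open contour is closed by the straight segment
    joining its endpoints (the bounding cut edge).
    """
    flanks = fit_flank_lines(contour, config)
    u1, u2 = flanks.direction1, flanks.direction2
    bisector = u1 + u2
    norm = np.linalg.norm(bisector)
    if norm == 0:
        raise DegenerateGeometryError("flank directions are anti-parallel")
    bisector = bisector / norm
    cosang = float(np.clip(np.dot(u1, u2), -1.0, 1.0))
    half_angle = 0.5 * math.acos(cosang)

    closed_pts = _close(contour.points)
    polygon = Polygon(closed_pts)
    if not polygon.is_valid:
        polygon = polygon.buffer(0)

    extent = float(np.max(np.linalg.norm(contour.points - flanks.apex, axis=1)))

    def fits(r: float) -> bool:
        return circle_fits(
            r, flanks.apex, bisector, half_angle, closed_pts, polygon,
            tol_px=config.containment_tol_px,
        )

    lo = 0.0
    hi = None
    for r in np.geomspace(max(config.bisection_tol_px, 0.25), extent, 64):
        if fits(float(r)):
            hi = float(r)
            break
        lo = float(r)
    if hi is None:
        raise EstimationFailureError(
            f"contour {contour.specimen_id!r}: no contained bitangent circle up "
            f"to the contour extent ({extent:.1f} px)"
        )
    while hi - lo > config.bisection_tol_px:
        mid = 0.5 * (lo + hi)
        if fits(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi) * contour.scale


def estimate_edge_geometry(
    contour: CrossSectionContour, config: FlankFitConfig = FlankFitConfig()
) -> EdgeGeometryEstimate:
    """Full estimate: edge radius, wedge angle, flank lines and fit residual."""
    flanks = fit_flank_lines(contour, config)
    cosang = float(np.clip(np.dot(flanks.direction1, flanks.direction2), -1.0, 1.0))
    angle = math.degrees(math.acos(cosang))
    radius = edge_radius(contour, config)
    return EdgeGeometryEstimate(
        edge_radius=radius,
        wedge_angle=angle,
        flank_lines=flanks,
        fit_residual=flanks.fit_residual_px * contour.scale,
    )
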