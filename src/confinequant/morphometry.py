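"""Shape and dynamics metrics for cell and nuclear contours.

This module measures traced outlines of cells and nuclei: best-fit ellipses
by exact polygon second moments, area/perimeter/roundness/aspect-ratio,
protrusion length and base width from annotated polylines, per-track shape
dynamics (perimeter variance, aspect-ratio extrema, trailing displacement),
and event-aligned time courses.

Conventions
-----------
* Contour vertices are ``(x, y)`` pixel coordinates, 0-based, x rightward,
  y downward, pixel centers at integer coordinates.
* Vertex order is normalized to positive signed (shoelace) area, referred
  to throughout as counterclockwise.
* Roundness is the best-fit-ellipse convention ``4*Area / (pi * major**2)``
  (1 for a disc); circularity ``4*pi*A/P**2`` is deliberately not used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon as _ShPolygon


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Contour:
    """A traced closed outline in pixel coordinates.

    Parameters
    ----------
    vertices : (N, 2) array
        Ordered ``(x, y)`` vertex coordinates in pixels, N >= 3 for a
        closed contour. The polygon must be simple (non-self-intersecting).
    pixel_size_um : float
        Physical size of one pixel in micrometers.
    closed : bool
        Closed polygon (True) or open polyline (False). Shape metrics
        require a closed contour.
    frame : int or None
        Time index when the contour belongs to a tracked object.
    """

    vertices: np.ndarray
    pixel_size_um: float = 1.0
    closed: bool = True
    frame: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("vertices must be an (N, 2) array of (x, y)")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.closed:
            # drop an explicitly repeated closing vertex
            if v.shape[0] >= 2 and np.allclose(v[0], v[-1]):
                v = v[:-1]
            if v.shape[0] < 3:
                raise ValueError("a closed contour needs at least 3 vertices")
            poly = _ShPolygon(v)
            if not poly.is_valid:
                raise ValueError("contour is not a simple polygon")
            # normalize orientation to positive signed area
            if _signed_area(v) < 0:
                v = v[::-1].copy()
        else:
            if v.shape[0] < 2:
                raise ValueError("a polyline needs at least 2 points")
        self.vertices = v

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])


@dataclass
class EllipseFit:
    """Best-fit ellipse of a polygon by normalized second central moments."""

    centroid: tuple[float, float]
    major_axis: float  # full length, px
    minor_axis: float  # full length, px
    orientation: float  # radians in [-pi/2, pi/2)

    def __post_init__(self) -> None:
        if not (self.major_axis >= self.minor_axis > 0):
            raise ValueError("require major_axis >= minor_axis > 0")

    @property
    def aspect_ratio(self) -> float:
        return self.major_axis / self.minor_axis


@dataclass
class ShapeMetrics:
    """Scalar shape descriptors of one contour."""

    area_px2: float
    area_um2: float
    perimeter_px: float
    perimeter_um: float
    roundness: float
    aspect_ratio: float
    ellipse: EllipseFit


@dataclass
class ProtrusionMeasurement:
    """Length and base width of one annotated protrusion."""

    length_um: float
    base_width_um: float
    width_to_length: float
    frame: int | None = None


@dataclass
class TrackedObject:
    """Time-indexed contours and/or centroids of one tracked cell or nucleus.

    Frames must be strictly increasing with a uniform spacing of
    ``dt_min`` minutes. Centroids are derived from contours when absent.
    """

    id: str
    frames: np.ndarray
    dt_min: float
    contours: list[Contour] | None = None
    centroids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 1 or len(self.frames) < 2:
            raise ValueError("need at least 2 frames")
        d = np.diff(self.frames)
        if not np.all(d > 0):
            raise ValueError("frames must be strictly increasing")
        if not np.all(d == d[0]):
            raise ValueError("frame spacing must be uniform")
        if self.dt_min <= 0:
            raise ValueError("dt_min must be positive")
        if self.contours is not None and len(self.contours) != len(self.frames):
            raise ValueError("one contour per frame required")
        if self.centroids is None:
            if self.contours is None:
                raise ValueError("provide contours or centroids")
            self.centroids = np.array(
                [polygon_centroid(c.vertices) for c in self.contours]
            )
        else:
            self.centroids = np.asarray(self.centroids, dtype=float)
            if self.centroids.shape != (len(self.frames), 2):
                raise ValueError("centroids must be (n_frames, 2)")


@dataclass
class ShapeDynamics:
    """Per-track dynamics summary.

    ``trailing_displacement_um[i]`` is the straight-line centroid
    displacement between frame ``i`` and the frame ``window_min`` minutes
    earlier; NaN where the trailing window is not yet available.
    """

    perimeter_variance_um2: float
    min_aspect: float
    max_aspect: float
    trailing_displacement_um: np.ndarray
    perimeters_um: np.ndarray = field(repr=False, default=None)
    aspect_ratios: np.ndarray = field(repr=False, default=None)


@dataclass
class AlignedSeries:
    """Event-aligned matrix of per-object series; lag 0 is the event frame."""

    lags: np.ndarray
    matrix: np.ndarray  # (n_objects, n_lags), NaN-padded
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray  # values available per lag


# ---------------------------------------------------------------------------
# exact polygon moments
# ---------------------------------------------------------------------------

def _signed_area(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    return 0.5 * float(np.sum(x * y1 - x1 * y))


def polygon_area(v: np.ndarray) -> float:
    """Unsigned shoelace area of a polygon, px^2."""
    return abs(_signed_area(np.asarray(v, dtype=float)))


def polygon_perimeter(v: np.ndarray, closed: bool = True) -> float:
    v = np.asarray(v, dtype=float)
    seg = np.diff(v, axis=0)
    p = float(np.sum(np.hypot(seg[:, 0], seg[:, 1])))
    if closed:
        p += float(np.hypot(*(v[0] - v[-1])))
    return p


def polygon_centroid(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    x, y = v[:, 0], v[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a = 0.5 * np.sum(cross)
    if abs(a) < 1e-12:
        raise ValueError("degenerate polygon: zero area")
    cx = np.sum((x + x1) * cross) / (6.0 * a)
    cy = np.sum((y + y1) * cross) / (6.0 * a)
    return np.array([cx, cy])


def _central_second_moments(v: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact normalized second central moments (covariance) of the
    polygon interior, via Green's-theorem closed forms."""
    x, y = v[:, 0], v[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a = 0.5 * np.sum(cross)
    if abs(a) < 1e-12:
        raise ValueError("degenerate polygon: zero area")
    cx = np.sum((x + x1) * cross) / (6.0 * a)
    cy = np.sum((y + y1) * cross) / (6.0 * a)
    ixx = np.sum((x * x + x * x1 + x1 * x1) * cross) / 12.0
    iyy = np.sum((y * y + y * y1 + y1 * y1) * cross) / 12.0
    ixy = np.sum((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross) / 24.0
    cov = np.array(
        [
            [ixx / a - cx * cx, ixy / a - cx * cy],
            [ixy / a - cx * cy, iyy / a - cy * cy],
        ]
    )
    return cov, abs(float(a))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def fit_ellipse(contour: Contour) -> EllipseFit:
    """Fit the moment-equivalent ellipse of a closed contour.

    The ellipse shares the polygon's centroid and normalized second
    central moments; axes are then rescaled uniformly so the ellipse area
    equals the polygon area (the convention of common image-analysis
    tools). Raises ``ValueError`` for degenerate (collinear) contours.
    """
    if not contour.closed:
        raise ValueError("fit_ellipse requires a closed contour")
    v = contour.vertices
    cov, area = _central_second_moments(v)
    lam, vec = np.linalg.eigh(cov)  # ascending
    if lam[0] <= 0:
        raise ValueError("degenerate contour: collinear vertices")
    # for an exact ellipse the eigenvalues are (semiaxis/2)^2
    semi_minor = 2.0 * np.sqrt(lam[0])
    semi_major = 2.0 * np.sqrt(lam[1])
    scale = np.sqrt(area / (np.pi * semi_major * semi_minor))
    semi_major *= scale
    semi_minor *= scale
    vx, vy = vec[:, 1]
    theta = float(np.arctan2(vy, vx))
    # wrap to [-pi/2, pi/2)
    theta = (theta + np.pi / 2) % np.pi - np.pi / 2
    cx, cy = polygon_centroid(v)
    return EllipseFit(
        centroid=(float(cx), float(cy)),
        major_axis=float(2 * semi_major),
        minor_axis=float(2 * semi_minor),
        orientation=theta,
    )


def contour_metrics(contour: Contour) -> ShapeMetrics:
    """Area, perimeter, roundness and aspect ratio of a closed contour.

    Area is the shoelace formula, perimeter the closed polyline length,
    roundness ``4*A/(pi*major^2)`` and aspect ratio major/minor of the
    best-fit ellipse. Physical values use ``contour.pixel_size_um``.
    """
    ell = fit_ellipse(contour)
    a_px2 = polygon_area(contour.vertices)
    p_px = polygon_perimeter(contour.vertices)
    s = contour.pixel_size_um
    roundness = 4.0 * a_px2 / (np.pi * ell.major_axis**2)
    return ShapeMetrics(
        area_px2=a_px2,
        area_um2=a_px2 * s * s,
        perimeter_px=p_px,
        perimeter_um=p_px * s,
        roundness=float(roundness),
        aspect_ratio=ell.aspect_ratio,
        ellipse=ell,
    )


def protrusion_metrics(
    protrusion_path: np.ndarray,
    base_segment: np.ndarray,
    pixel_size_um: float,
    frame: int | None = None,
) -> ProtrusionMeasurement:
    """Length and base width of an annotated protrusion.

    ``protrusion_path`` is an (N>=2, 2) polyline in pixels traced along
    the protrusion; ``base_segment`` is a 2-point segment across its base
    (endpoints on the cell contour). Length is polyline arc length and
    width the base-segment length, both scaled by ``pixel_size_um``.
    """
    path = np.asarray(protrusion_path, dtype=float)
    base = np.asarray(base_segment, dtype=float)
    if path.ndim != 2 or path.shape[0] < 2:
        raise ValueError("protrusion path needs at least 2 points")
    if base.shape != (2, 2):
        raise ValueError("base_segment must be two (x, y) points")
    length = polygon_perimeter(path, closed=False) * pixel_size_um
    if length <= 0:
        raise ValueError("zero-length protrusion path")
    width = float(np.hypot(*(base[1] - base[0]))) * pixel_size_um
    if width <= 0:
        raise ValueError("zero-length base segment")
    return ProtrusionMeasurement(
        length_um=length,
        base_width_um=width,
        width_to_length=width / length,
        frame=frame,
    )


def track_shape_dynamics(
    track: TrackedObject, window_min: float = 5.0
) -> ShapeDynamics:
    """Perimeter variance, aspect-ratio extrema, and trailing displacement.

    Perimeter variance is the population (divide-by-N) variance of the
    per-frame perimeter in um^2. Trailing displacement at frame ``i`` is
    the straight-line centroid displacement between ``t`` and
    ``t - window_min`` (net displacement, not path length), NaN over the
    first window. Requires at least 5 frames and a window that is an
    integer multiple of the frame interval.
    """
    n = len(track.frames)
    if n < 5:
        raise ValueError(f"track has {n} frames; at least 5 are required")
    k_f = window_min / track.dt_min
    k = int(round(k_f))
    if abs(k_f - k) > 1e-9 or k < 1:
        raise ValueError("window_min must be a positive multiple of dt_min")
    if track.contours is not None:
        s = np.array([c.pixel_size_um for c in track.contours])
        perims = np.array(
            [polygon_perimeter(c.vertices) for c in track.contours]
        ) * s
        aspects = np.array(
            [fit_ellipse(c).aspect_ratio for c in track.contours]
        )
        px = track.contours[0].pixel_size_um
    else:
        raise ValueError("shape dynamics require per-frame contours")
    disp = np.full(n, np.nan)
    if k < n:
        d = track.centroids[k:] - track.centroids[:-k]
        disp[k:] = np.hypot(d[:, 0], d[:, 1]) * px
    return ShapeDynamics(
        perimeter_variance_um2=float(np.var(perims)),  # population variance
        min_aspect=float(aspects.min()),
        max_aspect=float(aspects.max()),
        trailing_displacement_um=disp,
        perimeters_um=perims,
        aspect_ratios=aspects,
    )


def align_on_event(
    series: list[np.ndarray], event_frame: list[int]
) -> AlignedSeries:
    """Align per-object time series on a per-object event index.

    Lag 0 corresponds to each object's event frame; ragged ends are
    NaN-padded. Mean and SD (population) are computed per lag over the
    values available at that lag.
    """
    if len(series) != len(event_frame):
        raise ValueError("one event index per series required")
    series = [np.asarray(s, dtype=float) for s in series]
    for s, e in zip(series, event_frame):
        if s.ndim != 1:
            raise ValueError("each series must be 1-D")
        if not (0 <= e < len(s)):
            raise ValueError(
                f"event index {e} outside series of length {len(s)}"
            )
    before = max(event_frame)
    after = max(len(s) - e - 1 for s, e in zip(series, event_frame))
    lags = np.arange(-before, after + 1)
    mat = np.full((len(series), len(lags)), np.nan)
    for i, (s, e) in enumerate(zip(series, event_frame)):
        start = before - e
        mat[i, start : start + len(s)] = s
    n = np.sum(~np.isnan(mat), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(mat, axis=0)
        sd = np.nanstd(mat, axis=0)
    return AlignedSeries(lags=lags, matrix=mat, mean=mean, sd=sd, n=n)
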