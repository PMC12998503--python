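"""Band, line and region intensity measurements with reference normalization.

Covers the intensity quantifications used around migrating cells: mean
intensity in a band of stated thickness traced just inside (or outside, or
straddling) a cell or nuclear contour, optionally restricted to an
annotated front arc; thick-line intensity profiles; region-vs-region
enrichment ratios; and normalization of per-object measures to a
reference population (e.g. neighboring somatic cells) or ROI mean.

Bands are constructed by Euclidean distance transform from the rasterized
polygon boundary — every pixel whose distance to the boundary on the
requested side is at most the band thickness — rather than by polygon
erosion, which can break topology on concave contours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.draw import polygon2mask

from .image import MultiChannelImage
from .morphometry import Contour


@dataclass
class BandMeasure:
    """Mean intensity over a contour-following band."""

    mean_intensity: float
    band_thickness_px: float
    side: str  # inner | outer | centered
    n_pixels: int

    def __post_init__(self) -> None:
        if self.n_pixels <= 0:
            raise ValueError("band contains no pixels")
        if self.band_thickness_px < 1:
            raise ValueError("band thickness must be >= 1 px")


@dataclass
class LineProfile:
    """Intensity along a path, averaged across a perpendicular thickness."""

    positions: np.ndarray  # px along the path, strictly increasing
    intensities: np.ndarray
    thickness_px: int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.positions) != len(self.intensities):
            raise ValueError("positions and intensities differ in length")
        if len(self.positions) >= 2 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")


@dataclass
class NormalizedValues:
    """Per-object values divided by a reference mean."""

    ratios: np.ndarray
    reference_mean: float
    reference_mode: str  # "population" (array of measures) or "roi_mean"


# ---------------------------------------------------------------------------
# band construction
# ---------------------------------------------------------------------------

def contour_mask(contour: Contour, shape: tuple[int, int]) -> np.ndarray:
    """Boolean raster of the polygon interior (pixel centers inside)."""
    v = contour.vertices
    return polygon2mask(shape, np.column_stack([v[:, 1], v[:, 0]]))


def band_mask(
    contour: Contour,
    shape: tuple[int, int],
    thickness_px: float,
    side: str = "inner",
) -> np.ndarray:
    """Pixels within ``thickness_px`` of the contour on the chosen side.

    ``inner`` takes interior pixels with distance-to-exterior <= thickness,
    ``outer`` the mirror image, ``centered`` half the thickness each way.
    """
    if side not in ("inner", "outer", "centered"):
        raise ValueError("side must be inner, outer or centered")
    mask = contour_mask(contour, shape)
    dist_in = ndimage.distance_transform_edt(mask)
    dist_out = ndimage.distance_transform_edt(~mask)
    if side == "inner":
        return mask & (dist_in <= thickness_px)
    if side == "outer":
        return (~mask) & (dist_out <= thickness_px)
    half = thickness_px / 2.0
    return (mask & (dist_in <= half)) | ((~mask) & (dist_out <= half))


def resample_contour(
    contour: Contour, step_px: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Densely resample a closed contour.

    Returns (points, frac_index) where ``frac_index`` is the fractional
    vertex index of each resampled point, used to restrict band pixels to
    an annotated arc.
    """
    v = contour.vertices
    n = len(v)
    pts, idx = [], []
    for i in range(n):
        a, b = v[i], v[(i + 1) % n]
        seg = np.hypot(*(b - a))
        k = max(1, int(np.ceil(seg / step_px)))
        t = np.arange(k) / k
        pts.append(a[None] + t[:, None] * (b - a)[None])
        idx.append(i + t)
    return np.concatenate(pts), np.concatenate(idx)


def _arc_contains(frac_index: np.ndarray, arc: tuple[float, float], n: int) -> np.ndarray:
    """Membership of fractional vertex indices in the arc start..end (CCW, wrapping)."""
    start, end = float(arc[0]) % n, float(arc[1]) % n
    if start <= end:
        return (frac_index >= start) & (frac_index <= end)
    return (frac_index >= start) | (frac_index <= end)


def band_intensity(
    image: MultiChannelImage,
    channel: int | str,
    contour: Contour,
    thickness_px: float = 20,
    side: str = "inner",
    arc: tuple[float, float] | None = None,
) -> BandMeasure:
    """Mean intensity in a band of ``thickness_px`` along a contour.

    ``arc=(i0, i1)`` restricts the band to pixels whose nearest contour
    point lies on the counterclockwise arc from vertex index i0 to i1
    (fractional indices allowed) — used to measure a "cell front" versus
    the rest of the cortex. Raises ``ValueError`` when the band is empty
    (contour too small for the requested thickness/side).
    """
    img = image.channel(channel)
    mask = band_mask(contour, img.shape, thickness_px, side)
    if arc is not None:
        ys, xs = np.nonzero(mask)
        if len(ys) == 0:
            raise ValueError("band is empty for this contour/thickness")
        pts, frac = resample_contour(contour)
        tree = cKDTree(pts)
        _, nearest = tree.query(np.column_stack([xs, ys]))
        keep = _arc_contains(frac[nearest], arc, contour.n_vertices)
        sel = np.zeros_like(mask)
        sel[ys[keep], xs[keep]] = True
        mask = sel
    n = int(mask.sum())
    if n == 0:
        raise ValueError("band is empty for this contour/thickness")
    return BandMeasure(
        mean_intensity=float(img[mask].mean()),
        band_thickness_px=thickness_px,
        side=side,
        n_pixels=n,
    )


def front_body_ratio(
    image: MultiChannelImage,
    channel: int | str,
    contour: Contour,
    front_arc: tuple[float, float],
    thickness_px: float = 20,
    side: str = "inner",
) -> float:
    """Front-to-body cortical intensity ratio for one annotated front arc.

    The band is partitioned exactly: every band pixel belongs to the
    front (its nearest contour point lies on ``front_arc``) or to the
    body (the strict complement), so the two means share no pixels.
    """
    img = image.channel(channel)
    mask = band_mask(contour, img.shape, thickness_px, side)
    ys, xs = np.nonzero(mask)
    if len(ys) == 0:
        raise ValueError("band is empty for this contour/thickness")
    pts, frac = resample_contour(contour)
    _, nearest = cKDTree(pts).query(np.column_stack([xs, ys]))
    in_front = _arc_contains(frac[nearest], front_arc, contour.n_vertices)
    if not in_front.any() or in_front.all():
        raise ValueError("front arc covers none or all of the band")
    vals = img[ys, xs]
    body_mean = float(vals[~in_front].mean())
    if body_mean == 0:
        raise ValueError("body band mean is zero")
    return float(vals[in_front].mean()) / body_mean


# ---------------------------------------------------------------------------
# normalization, profiles, regions
# ---------------------------------------------------------------------------

def normalize_to_reference(
    values: np.ndarray,
    reference_values: np.ndarray | float,
) -> NormalizedValues:
    """Divide per-object measures by a reference mean.

    ``reference_values`` may be an array of per-object reference measures
    (e.g. somatic-cell band intensities, averaged) or a single ROI mean.
    """
    values = np.atleast_1d(np.asarray(values, dtype=float))
    if np.isscalar(reference_values) or np.ndim(reference_values) == 0:
        ref_mean = float(reference_values)
        mode = "roi_mean"
    else:
        ref = np.asarray(reference_values, dtype=float)
        ref_mean = float(ref.mean())
        mode = "population"
    if ref_mean <= 0:
        raise ValueError("reference mean must be positive")
    return NormalizedValues(
        ratios=values / ref_mean, reference_mean=ref_mean, reference_mode=mode
    )


def line_profile(
    image: MultiChannelImage,
    channel: int | str,
    path: np.ndarray,
    thickness_px: int = 10,
    spacing_px: float = 1.0,
) -> LineProfile:
    """Thick-line intensity profile along a polyline path.

    The path is resampled at ``spacing_px`` intervals; at each position
    the intensity is averaged over ``thickness_px`` samples spaced 1 px
    along the local perpendicular (bilinear interpolation).
    """
    img = image.channel(channel)
    path = np.asarray(path, dtype=float)
    if path.ndim != 2 or path.shape[0] < 2:
        raise ValueError("path needs at least 2 points")
    seg = np.diff(path, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    s_cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = s_cum[-1]
    if total < spacing_px:
        raise ValueError("path shorter than one sample spacing")
    s = np.arange(0.0, total + 1e-9, spacing_px)
    x = np.interp(s, s_cum, path[:, 0])
    y = np.interp(s, s_cum, path[:, 1])
    tx, ty = np.gradient(x), np.gradient(y)
    norm = np.hypot(tx, ty)
    norm[norm == 0] = 1.0
    # unit normals perpendicular to the local tangent
    nx, ny = -ty / norm, tx / norm
    offsets = np.arange(thickness_px, dtype=float) - (thickness_px - 1) / 2.0
    xs = x[None, :] + offsets[:, None] * nx[None, :]
    ys = y[None, :] + offsets[:, None] * ny[None, :]
    vals = ndimage.map_coordinates(
        img, np.stack([ys, xs]), order=1, mode="nearest"
    )
    return LineProfile(
        positions=s, intensities=vals.mean(axis=0), thickness_px=thickness_px
    )


def region_enrichment(
    image: MultiChannelImage,
    channel: int | str,
    roi1: np.ndarray,
    roi2: np.ndarray,
) -> float:
    """Ratio mean(roi1)/mean(roi2) over two equal-size, disjoint ROI masks.

    Mirrors the tissue-level enrichment measurement in which a region
    containing cells of interest is divided by an adjacent region without
    them, using ROIs of the same size.
    """
    img = image.channel(channel)
    roi1 = np.asarray(roi1, dtype=bool)
    roi2 = np.asarray(roi2, dtype=bool)
    if roi1.shape != img.shape or roi2.shape != img.shape:
        raise ValueError("ROI masks must match the image shape")
    if np.any(roi1 & roi2):
        raise ValueError("ROIs overlap")
    n1, n2 = int(roi1.sum()), int(roi2.sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("empty ROI")
    if n1 != n2:
        raise ValueError(f"ROIs must be equal in size (got {n1} vs {n2} px)")
    m2 = float(img[roi2].mean())
    if m2 == 0:
        raise ValueError("reference ROI mean is zero")
    return float(img[roi1].mean()) / m2
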