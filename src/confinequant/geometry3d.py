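"""Embryo-surface geometry: convex hull of somatic positions and PGC depths.

The embryo surface is approximated per timepoint by the convex hull of
all tracked somatic cell positions; the depth of each primordial germ
cell (PGC) is its closest Euclidean distance to that triangulated
surface. Distances are exact point-to-triangle minima handling the face,
edge and vertex cases; interior and exterior points both receive their
positive distance to the surface (exterior points are additionally
flagged, since noisy tracking can place a cell outside the hull).

Hulls are recomputed independently per timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

DEFAULT_CUTOFF_UM = 100.0


@dataclass
class PointCloudFrame:
    """Labeled 3-D cell positions (um) at one timepoint."""

    time: int
    somatic_xyz: np.ndarray
    pgc_xyz: np.ndarray
    pgc_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.somatic_xyz = np.asarray(self.somatic_xyz, dtype=float)
        self.pgc_xyz = np.asarray(self.pgc_xyz, dtype=float).reshape(-1, 3)
        if self.somatic_xyz.ndim != 2 or self.somatic_xyz.shape[1] != 3:
            raise ValueError("somatic_xyz must be (N, 3)")
        if self.somatic_xyz.shape[0] < 4:
            raise ValueError("need at least 4 somatic points")
        if not (np.all(np.isfinite(self.somatic_xyz)) and np.all(np.isfinite(self.pgc_xyz))):
            raise ValueError("coordinates must be finite")
        if not self.pgc_ids:
            self.pgc_ids = list(range(len(self.pgc_xyz)))
        if len(self.pgc_ids) != len(self.pgc_xyz):
            raise ValueError("one id per PGC required")


@dataclass
class HullSurface:
    """Closed triangulated convex surface."""

    vertices: np.ndarray  # (M, 3) hull vertex coordinates
    faces: np.ndarray  # (F, 3) indices into the *original* point array
    points: np.ndarray  # original input points
    equations: np.ndarray  # (F, 4) outward plane equations n.x + d <= 0 inside
    volume: float
    area: float

    @property
    def n_faces(self) -> int:
        return len(self.faces)


@dataclass
class SurfaceDistanceResult:
    """Closest distance from one PGC to the hull surface."""

    pgc_id: object
    distance_um: float
    nearest_face: int
    within_cutoff: bool
    outside_hull: bool
    time: int | None = None


def build_hull_surface(somatic_xyz: np.ndarray) -> HullSurface:
    """Triangulated convex hull of somatic cell positions.

    Raises ``ValueError`` for coplanar or otherwise degenerate input.
    """
    pts = np.asarray(somatic_xyz, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 4:
        raise ValueError("need at least 4 points in 3-D")
    try:
        hull = ConvexHull(pts)
    except QhullError as e:
        raise ValueError(f"degenerate (coplanar?) point set: {e}") from None
    return HullSurface(
        vertices=pts[hull.vertices],
        faces=hull.simplices.copy(),
        points=pts,
        equations=hull.equations.copy(),
        volume=float(hull.volume),
        area=float(hull.area),
    )


def _point_triangle_distances(p: np.ndarray, a, b, c) -> np.ndarray:
    """Exact distance from point ``p`` to each triangle (a[i], b[i], c[i]).

    Projects onto the triangle plane; when the projection's barycentric
    coordinates leave the triangle, the minimum over the three edge
    segments is used (which covers the vertex cases too).
    """
    ab = b - a
    ac = c - a
    ap = p[None, :] - a
    n = np.cross(ab, ac)
    nn = np.einsum("ij,ij->i", n, n)
    nn = np.where(nn == 0, 1.0, nn)  # degenerate facets fall through to edges
    t = np.einsum("ij,ij->i", ap, n) / nn
    proj = p[None, :] - t[:, None] * n
    # barycentric coordinates of the projection
    d00 = np.einsum("ij,ij->i", ab, ab)
    d01 = np.einsum("ij,ij->i", ab, ac)
    d11 = np.einsum("ij,ij->i", ac, ac)
    pv = proj - a
    d20 = np.einsum("ij,ij->i", pv, ab)
    d21 = np.einsum("ij,ij->i", pv, ac)
    denom = d00 * d11 - d01 * d01
    denom = np.where(np.abs(denom) < 1e-300, 1.0, denom)
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    inside = (v >= 0) & (w >= 0) & (v + w <= 1)
    plane_dist = np.linalg.norm(p[None, :] - proj, axis=1)

    def seg_dist(s0, s1):
        d = s1 - s0
        dd = np.einsum("ij,ij->i", d, d)
        dd = np.where(dd == 0, 1.0, dd)
        tt = np.clip(np.einsum("ij,ij->i", p[None, :] - s0, d) / dd, 0.0, 1.0)
        closest = s0 + tt[:, None] * d
        return np.linalg.norm(p[None, :] - closest, axis=1)

    edge_dist = np.minimum.reduce([seg_dist(a, b), seg_dist(b, c), seg_dist(a, c)])
    return np.where(inside, plane_dist, edge_dist)


def distance_to_surface(
    hull: HullSurface,
    pgc_xyz: np.ndarray,
    cutoff_um: float = DEFAULT_CUTOFF_UM,
    pgc_ids: list | None = None,
    time: int | None = None,
) -> list[SurfaceDistanceResult]:
    """Closest distance from each PGC to the triangulated hull surface.

    Returns one result per query point (an empty list for an empty
    query), with the nearest facet index, the 100-um display-cutoff flag,
    and whether the point lies outside the hull.
    """
    pts = np.asarray(pgc_xyz, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        return []
    if pgc_ids is None:
        pgc_ids = list(range(len(pts)))
    a = hull.points[hull.faces[:, 0]]
    b = hull.points[hull.faces[:, 1]]
    c = hull.points[hull.faces[:, 2]]
    out = []
    for pid, p in zip(pgc_ids, pts):
        d = _point_triangle_distances(p, a, b, c)
        j = int(np.argmin(d))
        # outside if beyond any outward face plane
        signed = hull.equations[:, :3] @ p + hull.equations[:, 3]
        out.append(
            SurfaceDistanceResult(
                pgc_id=pid,
                distance_um=float(d[j]),
                nearest_face=j,
                within_cutoff=bool(d[j] <= cutoff_um),
                outside_hull=bool(signed.max() > 1e-9),
                time=time,
            )
        )
    return out


def surface_distance_table(
    frames: list[PointCloudFrame], cutoff_um: float = DEFAULT_CUTOFF_UM
) -> pd.DataFrame:
    """Per-frame hull construction and PGC depths, long format.

    Columns: time, pgc_id, distance_um, within_cutoff, outside_hull —
    ready for heatmap plotting over time and track id.
    """
    rows = []
    for fr in frames:
        hull = build_hull_surface(fr.somatic_xyz)
        for r in distance_to_surface(
            hull, fr.pgc_xyz, cutoff_um=cutoff_um, pgc_ids=fr.pgc_ids, time=fr.time
        ):
            rows.append(
                {
                    "time": fr.time,
                    "pgc_id": r.pgc_id,
                    "distance_um": r.distance_um,
                    "within_cutoff": r.within_cutoff,
                    "outside_hull": r.outside_hull,
                }
            )
    return pd.DataFrame(rows)


def read_tracks_csv(path) -> list[PointCloudFrame]:
    """Read tracked positions (time, id, class, x, y, z in um) into frames.

    The ``class`` column distinguishes ``somatic`` from ``pgc`` rows
    (case-insensitive), matching typical manual-tracking exports.
    """
    df = pd.read_csv(path)
    required = {"time", "id", "class", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"tracks CSV missing columns: {sorted(missing)}")
    cls = df["class"].astype(str).str.lower()
    frames = []
    for t, grp in df.assign(_cls=cls).groupby("time"):
        som = grp[grp["_cls"] == "somatic"][["x", "y", "z"]].to_numpy()
        pg = grp[grp["_cls"] == "pgc"]
        frames.append(
            PointCloudFrame(
                time=int(t),
                somatic_xyz=som,
                pgc_xyz=pg[["x", "y", "z"]].to_numpy(),
                pgc_ids=pg["id"].tolist(),
            )
        )
    return frames
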