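"""Seeded synthetic fixtures with ground truth for every pipeline stage.

Each generator draws from a single NumPy ``default_rng`` seeded once per
scene, with sub-draws in a fixed documented order, so a fixed seed yields
byte-identical arrays. Intensities are non-negative floats in memory; the
TIFF writers quantize to 16-bit on export.

Generators and the features they emulate:

* :func:`make_cell_scene` — cells with a cortical actin band, a
  front-enriched arc, a nucleus, and a front protrusion, over one or more
  timepoints.
* :func:`make_bm_scene` — a basement-membrane stripe of controlled FWHM
  with optional zero-intensity gaps covering a stated fraction of its
  length.
* :func:`make_dextran_scene` — a bright intercellular-space network
  between dark cell bodies with an exactly known positive-pixel fraction.
* :func:`make_force_curve` — Hertz-model AFM force curves with optional
  pre-contact baseline and additive Gaussian noise.
* :func:`make_embryo_pointcloud` — somatic positions jittered on a
  spherical shell with interior PGCs at requested depths.
* :func:`make_foci_scene` — nuclei with planted focus counts and
  envelope invaginations.

Noise is plain additive Gaussian (clipped at zero); no distributional
model of real camera noise is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .afm_hertz import DEFAULT_MU, DEFAULT_R_M, ForceCurve, hertz_force
from .geometry3d import PointCloudFrame
from .image import MultiChannelImage, write_json, write_tiff
from .intensity import band_mask, resample_contour, _arc_contains
from .morphometry import Contour


@dataclass
class SceneSpec:
    """Common raster parameters shared by the image generators."""

    seed: int
    image_shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.5
    noise_sd: float = 2.0
    background_level: float = 20.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """Ground truth attached to a generated scene.

    ``contours``/``labels`` pair one label with each generated object
    outline; ``scalar_truth`` holds named scalar truths (documented per
    generator); ``extras`` holds structured truth such as masks,
    polylines, and per-object records.
    """

    contours: list[Contour] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)
    scalar_truth: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.contours) != len(self.labels):
            raise ValueError("every contour needs exactly one label")


def _finalize(channels: dict, spec: SceneSpec, rng: np.random.Generator) -> MultiChannelImage:
    """Add background and noise (per channel, in dict order) and clip at 0."""
    names = list(channels)
    data = np.stack([channels[k] for k in names]).astype(float)
    data += spec.background_level
    if spec.noise_sd > 0:
        for i in range(len(names)):
            data[i] += rng.normal(0.0, spec.noise_sd, size=data[i].shape)
    np.clip(data, 0.0, None, out=data)
    return MultiChannelImage(
        data=data, pixel_size_um=spec.pixel_size_um, channel_names=names
    )


def _ellipse_polygon(
    center: np.ndarray,
    semi_x: float,
    semi_y: float,
    orientation: float = 0.0,
    n: int = 128,
) -> np.ndarray:
    t = 2 * np.pi * np.arange(n) / n
    x = semi_x * np.cos(t)
    y = semi_y * np.sin(t)
    ct, st = np.cos(orientation), np.sin(orientation)
    return np.column_stack(
        [center[0] + ct * x - st * y, center[1] + st * x + ct * y]
    )


# ---------------------------------------------------------------------------
# cell scenes
# ---------------------------------------------------------------------------

def make_cell_scene(
    spec: SceneSpec,
    n_cells: int = 3,
    body_axes_um: tuple[float, float] = (12.0, 8.0),
    protrusion_length_um: float = 6.0,
    front_enrichment: float = 1.5,
    n_timepoints: int = 1,
    band_thickness_px: float = 6.0,
    membrane_thickness_px: float = 3.0,
    nucleus_fraction: float = 0.5,
    amplitude: float = 100.0,
    front_half_angle: float = np.pi / 4,
) -> tuple[list[MultiChannelImage], GroundTruth]:
    """Cells with cortical actin, a front-enriched arc, nuclei, protrusions.

    ``body_axes_um`` are the full major/minor axis lengths of the cell
    body ellipse. The actin band has uniform amplitude along the cortex
    times ``front_enrichment`` over the front arc (the vertices within
    ``front_half_angle`` of the front direction); enrichment 1 renders a
    statistically uniform cortex. Channels: membrane, actin, nucleus.

    Draw order from the scene RNG: cell centers/orientations (placement
    retries included), per-cell drift, then per-frame per-channel noise.

    Ground truth (per timepoint, in ``extras['cells'][t]``): body and
    nucleus contours, protrusion polyline, front arc as fractional vertex
    indices. ``scalar_truth``: front_enrichment, body_axes_um,
    aspect_ratio, protrusion_length_um, band amplitude.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if front_enrichment < 1:
        raise ValueError("front_enrichment must be >= 1")
    rng = spec.rng()
    h, w = spec.image_shape
    px = spec.pixel_size_um
    semi_a = body_axes_um[0] / 2 / px
    semi_b = body_axes_um[1] / 2 / px
    prot_px = protrusion_length_um / px
    margin = semi_a + prot_px + 4
    min_sep = 2 * semi_a + 6
    if 2 * margin >= min(h, w):
        raise ValueError(
            f"cells of semi-axis {semi_a:.0f} px (+{prot_px:.0f} px protrusion) "
            f"do not fit a {h}x{w} image"
        )
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n_cells:
        tries += 1
        if tries > 500:
            raise ValueError(
                f"could not place {n_cells} non-overlapping cells after 500 "
                f"tries; feasible density here is about "
                f"{max(1, len(centers))} cells for a {h}x{w} image"
            )
        c = np.array(
            [rng.uniform(margin, w - margin), rng.uniform(margin, h - margin)]
        )
        if all(np.hypot(*(c - o)) >= min_sep for o in centers):
            centers.append(c)
    orientations = rng.uniform(0, 2 * np.pi, size=n_cells)
    drifts = rng.normal(0.0, 1.0, size=(n_cells, 2))  # px per frame

    n_vert = 128
    t_param = 2 * np.pi * np.arange(n_vert) / n_vert
    ang = np.minimum(t_param, 2 * np.pi - t_param)  # distance to parameter 0
    front_idx = np.nonzero(ang <= front_half_angle)[0]
    # contiguous arc around vertex 0, expressed wrap-around
    arc = (float(front_idx[front_idx > n_vert // 2].min()), float(front_idx[front_idx <= n_vert // 2].max()))

    images: list[MultiChannelImage] = []
    per_frame: list[list[dict]] = []
    contours: list[Contour] = []
    labels: list[str] = []
    for tp in range(n_timepoints):
        membrane = np.zeros((h, w))
        actin = np.zeros((h, w))
        nucleus = np.zeros((h, w))
        cells_t = []
        for ci in range(n_cells):
            center = centers[ci] + tp * drifts[ci]
            body = Contour(
                _ellipse_polygon(center, semi_a, semi_b, orientations[ci], n_vert),
                pixel_size_um=px,
                frame=tp,
            )
            nuc = Contour(
                _ellipse_polygon(
                    center,
                    semi_a * nucleus_fraction,
                    semi_b * nucleus_fraction,
                    orientations[ci],
                    n_vert,
                ),
                pixel_size_um=px,
                frame=tp,
            )
            mem_band = band_mask(body, (h, w), membrane_thickness_px, "inner")
            membrane[mem_band] += amplitude
            act_band = band_mask(body, (h, w), band_thickness_px, "inner")
            ys, xs = np.nonzero(act_band)
            pts, frac = resample_contour(body)
            _, nearest = cKDTree(pts).query(np.column_stack([xs, ys]))
            in_front = _arc_contains(frac[nearest], arc, n_vert)
            vals = np.full(len(ys), amplitude)
            vals[in_front] *= front_enrichment
            actin[ys, xs] += vals
            nuc_mask = band_mask(nuc, (h, w), max(semi_a, semi_b), "inner")
            nucleus[nuc_mask] += amplitude
            # protrusion: polyline from the front vertex outward
            ct, st = np.cos(orientations[ci]), np.sin(orientations[ci])
            front_pt = center + semi_a * np.array([ct, st])
            tip = front_pt + prot_px * np.array([ct, st])
            n_s = max(2, int(np.ceil(prot_px)) * 2)
            line = front_pt[None] + np.linspace(0, 1, n_s)[:, None] * (tip - front_pt)[None]
            ix = np.clip(np.round(line[:, 0]).astype(int), 0, w - 1)
            iy = np.clip(np.round(line[:, 1]).astype(int), 0, h - 1)
            membrane[iy, ix] = np.maximum(membrane[iy, ix], 0.8 * amplitude)
            cells_t.append(
                {
                    "body": body,
                    "nucleus": nuc,
                    "protrusion": np.vstack([front_pt, tip]),
                    "front_arc": arc,
                    "center": center,
                }
            )
            contours += [body, nuc]
            labels += [f"t{tp}_cell{ci}_body", f"t{tp}_cell{ci}_nucleus"]
        per_frame.append(cells_t)
        images.append(
            _finalize(
                {"membrane": membrane, "actin": actin, "nucleus": nucleus},
                spec,
                rng,
            )
        )
    truth = GroundTruth(
        contours=contours,
        labels=labels,
        scalar_truth={
            "front_enrichment": front_enrichment,
            "body_axes_um": tuple(body_axes_um),
            "aspect_ratio": body_axes_um[0] / body_axes_um[1],
            "protrusion_length_um": protrusion_length_um,
            "band_amplitude": amplitude,
            "band_thickness_px": band_thickness_px,
        },
        extras={"cells": per_frame},
    )
    return images, truth


# ---------------------------------------------------------------------------
# basement-membrane scenes
# ---------------------------------------------------------------------------

def make_bm_scene(
    spec: SceneSpec,
    thickness_um: float = 3.0,
    gap_fraction: float = 0.0,
    gap_length_um: float = 5.0,
    amplitude: float = 100.0,
) -> tuple[MultiChannelImage, GroundTruth]:
    """A horizontal membrane stripe with a Gaussian cross-section.

    The stripe's cross-section FWHM equals ``thickness_um``; gaps of
    ``gap_length_um`` are placed at random non-overlapping positions so
    their total covers ``gap_fraction`` of the stripe length, and the
    stripe intensity is zeroed there. Draw order: stripe row jitter, then
    gap positions, then noise.

    ``scalar_truth``: thickness_um, fwhm_px, row, gap_fraction (actual),
    amplitude. ``extras``: per-column boolean ``gap_columns``.
    """
    if not (0 <= gap_fraction <= 1):
        raise ValueError("gap_fraction must lie in [0, 1]")
    px = spec.pixel_size_um
    if thickness_um < 2 * px:
        raise ValueError(
            f"thickness {thickness_um} um is below 2 px "
            f"({2 * px} um): unresolvable"
        )
    rng = spec.rng()
    h, w = spec.image_shape
    fwhm_px = thickness_um / px
    sigma = fwhm_px / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    row = h / 2 + rng.uniform(-h / 8, h / 8)
    y = np.arange(h, dtype=float)
    profile = amplitude * np.exp(-((y - row) ** 2) / (2 * sigma**2))
    band = np.tile(profile[:, None], (1, w))
    gap_cols = np.zeros(w, dtype=bool)
    if gap_fraction > 0:
        gap_len = max(1, int(round(gap_length_um / px)))
        n_gaps = max(1, int(round(gap_fraction * w / gap_len)))
        tries = 0
        placed = 0
        while placed < n_gaps and tries < 1000:
            tries += 1
            start = int(rng.integers(0, w - gap_len + 1))
            if not gap_cols[start : start + gap_len].any():
                gap_cols[start : start + gap_len] = True
                placed += 1
        band[:, gap_cols] = 0.0
    image = _finalize({"bm": band}, spec, rng)
    truth = GroundTruth(
        scalar_truth={
            "thickness_um": thickness_um,
            "fwhm_px": fwhm_px,
            "row": row,
            "gap_fraction": float(gap_cols.mean()),
            "amplitude": amplitude,
        },
        extras={"gap_columns": gap_cols},
    )
    return image, truth


# ---------------------------------------------------------------------------
# dextran (intercellular space) scenes
# ---------------------------------------------------------------------------

def make_dextran_scene(
    spec: SceneSpec,
    gap_width_um: float = 2.0,
    target_fraction: float = 0.30,
    amplitude: float = 200.0,
) -> tuple[MultiChannelImage, GroundTruth]:
    """A bright intercellular-space network between dark cell bodies.

    Cell bodies are Voronoi regions of random seed points; the space
    network is the set of pixels nearest to a region boundary. The
    boundary-distance threshold is chosen as the ``target_fraction``
    quantile of the distance field, so the truth mask fraction matches
    the target almost exactly while the typical channel width stays near
    ``gap_width_um``. Draw order: seed points, then noise.

    ``scalar_truth``: fraction (exact mask fraction), gap_width_um
    (request), achieved_width_um (2 x chosen threshold), n_seeds.
    ``extras``: the exact boolean ``gap_mask``.
    """
    if not (0 < target_fraction < 0.9):
        raise ValueError("target_fraction must lie in (0, 0.9)")
    px = spec.pixel_size_um
    w_px = gap_width_um / px
    if w_px < 1:
        raise ValueError("gap width below one pixel is not renderable")
    rng = spec.rng()
    h, w = spec.image_shape
    # Poisson-Voronoi edge length per unit area is 2*sqrt(lambda), so the
    # covered fraction at half-width w/2 is roughly w * 2 * sqrt(lambda)
    lam = (target_fraction / (2.0 * w_px)) ** 2
    n_seeds = int(round(lam * h * w))
    if n_seeds < 4:
        raise ValueError(
            f"infeasible combination: fraction {target_fraction} at width "
            f"{gap_width_um} um needs fewer than 4 cells in a {h}x{w} image"
        )
    seeds = np.column_stack(
        [rng.uniform(0, w, n_seeds), rng.uniform(0, h, n_seeds)]
    )
    yy, xx = np.mgrid[0:h, 0:w]
    grid = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    d, _ = cKDTree(seeds).query(grid, k=2)
    # distance to the local Voronoi boundary along the bisector
    edge_dist = ((d[:, 1] - d[:, 0]) / 2.0).reshape(h, w)
    thr = float(np.quantile(edge_dist, target_fraction))
    mask = edge_dist <= thr
    img = np.where(mask, amplitude, 0.0)
    image = _finalize({"dextran": img}, spec, rng)
    truth = GroundTruth(
        scalar_truth={
            "fraction": float(mask.mean()),
            "gap_width_um": gap_width_um,
            "achieved_width_um": 2.0 * thr * px,
            "n_seeds": n_seeds,
        },
        extras={"gap_mask": mask},
    )
    return image, truth


# ---------------------------------------------------------------------------
# AFM force curves
# ---------------------------------------------------------------------------

def make_force_curve(
    E_pa: float,
    C: float = 0.0,
    mu: float = DEFAULT_MU,
    R_um: float = DEFAULT_R_M * 1e6,
    delta_max_nm: float = 250.0,
    n_points: int = 100,
    noise_sd: float = 0.0,
    seed: int = 0,
    precontact_nm: float = 0.0,
) -> tuple[ForceCurve, dict]:
    """A Hertz-model force curve with optional pre-contact baseline.

    Samples F(delta) = (4/3) E/(1-mu^2) sqrt(R) delta^(3/2) + C on a
    uniform separation grid from ``-precontact_nm`` (where the force is
    the bare offset C) to ``delta_max_nm``, plus additive Gaussian noise
    of ``noise_sd`` newtons. Truth records E, C and the index of the
    contact sample (separation exactly zero when the grid hits it).
    """
    if E_pa <= 0:
        raise ValueError("E must be positive")
    if n_points < 20:
        raise ValueError("need at least 20 points")
    rng = np.random.default_rng(seed)
    R = R_um * 1e-6
    total_nm = precontact_nm + delta_max_nm
    step = total_nm * 1e-9 / (n_points - 1)
    # snap the grid so the contact point (separation 0) is an exact sample
    contact_index = int(round(precontact_nm * 1e-9 / step))
    sep = (np.arange(n_points) - contact_index) * step
    indent = np.clip(sep, 0.0, None)
    force = hertz_force(indent, E_pa, mu=mu, R=R, C=C)
    if noise_sd > 0:
        force = force + rng.normal(0.0, noise_sd, size=n_points)
    curve = ForceCurve(separation=sep, force=force, R=R, mu=mu)
    return curve, {"E": E_pa, "C": C, "contact_index": contact_index}


# ---------------------------------------------------------------------------
# embryo point clouds
# ---------------------------------------------------------------------------

def make_embryo_pointcloud(
    seed: int,
    n_somatic: int = 300,
    n_pgc: int = 5,
    radius_um: float = 100.0,
    pgc_depths_um: list | None = None,
    jitter_um: float = 1.0,
    n_timepoints: int = 1,
) -> tuple[list[PointCloudFrame], GroundTruth]:
    """Somatic cells jittered on a spherical shell; PGCs at known depths.

    Somatic points lie at radius ``radius_um`` + Gaussian radial jitter;
    each PGC sits at ``radius - depth`` along a random inward direction.
    Frames beyond the first apply a small rigid rotation to all points
    (the truth depths are unchanged). Draw order: somatic directions,
    radial jitter, PGC directions, per-frame rotation axes.

    ``scalar_truth``: depths_um (per PGC), radius_um, jitter_um.
    """
    if pgc_depths_um is None:
        pgc_depths_um = list(np.linspace(5, radius_um / 2, n_pgc))
    if len(pgc_depths_um) != n_pgc:
        raise ValueError("one depth per PGC required")
    if any(d >= radius_um for d in pgc_depths_um):
        raise ValueError("PGC depths must be smaller than the shell radius")
    if any(d < 0 for d in pgc_depths_um):
        raise ValueError("PGC depths must be non-negative")
    if n_somatic < 4:
        raise ValueError("need at least 4 somatic points")
    rng = np.random.default_rng(seed)
    u = rng.normal(size=(n_somatic, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    radii = radius_um + rng.normal(0.0, jitter_um, size=n_somatic)
    somatic = u * radii[:, None]
    pdir = rng.normal(size=(n_pgc, 3))
    pdir /= np.linalg.norm(pdir, axis=1, keepdims=True)
    pgc = pdir * (radius_um - np.asarray(pgc_depths_um))[:, None]
    frames = []
    for tp in range(n_timepoints):
        if tp == 0:
            rot = np.eye(3)
        else:
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = 0.05 * tp
            K = np.array(
                [
                    [0, -axis[2], axis[1]],
                    [axis[2], 0, -axis[0]],
                    [-axis[1], axis[0], 0],
                ]
            )
            rot = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K
        frames.append(
            PointCloudFrame(
                time=tp,
                somatic_xyz=somatic @ rot.T,
                pgc_xyz=pgc @ rot.T,
                pgc_ids=list(range(n_pgc)),
            )
        )
    truth = GroundTruth(
        scalar_truth={
            "depths_um": list(map(float, pgc_depths_um)),
            "radius_um": radius_um,
            "jitter_um": jitter_um,
        }
    )
    return frames, truth


# ---------------------------------------------------------------------------
# foci / invagination scenes
# ---------------------------------------------------------------------------

def make_foci_scene(
    spec: SceneSpec,
    foci_per_nucleus: list[int] = (5,),
    invaginations_per_nucleus: list[int] | None = None,
    nucleus_radius_um: float = 6.0,
    focus_sigma_px: float = 1.5,
    focus_amplitude: float = 150.0,
    min_separation_px: float = 5.0,
    notch_depth_frac: float = 0.18,
    notch_width_rad: float = 0.25,
    amplitude: float = 100.0,
) -> tuple[MultiChannelImage, GroundTruth]:
    """Nuclei with planted focus counts and envelope invaginations.

    Nuclei are laid out on a grid; each gets a DAPI-like filled channel,
    an envelope ring channel, and Gaussian foci planted at rejection-
    sampled positions at least ``min_separation_px`` apart (an error is
    raised when a count cannot be placed). Invaginations are inward
    radial notches of depth ``notch_depth_frac`` x radius at equally
    spaced angles (randomly rotated per nucleus). Draw order: per-nucleus
    notch phase, then focus positions, then noise.

    Channels: dapi, foci, envelope. ``extras``: labeled ``nuclear_masks``
    raster, per-nucleus ``foci_xy``. ``scalar_truth``: foci_per_nucleus,
    invaginations_per_nucleus.
    """
    foci_per_nucleus = list(foci_per_nucleus)
    n_nuclei = len(foci_per_nucleus)
    if n_nuclei == 0:
        raise ValueError("at least one nucleus required")
    if invaginations_per_nucleus is None:
        invaginations_per_nucleus = [0] * n_nuclei
    if len(invaginations_per_nucleus) != n_nuclei:
        raise ValueError("one invagination count per nucleus required")
    rng = spec.rng()
    h, w = spec.image_shape
    px = spec.pixel_size_um
    r_px = nucleus_radius_um / px
    spacing = 3.2 * r_px
    per_row = max(1, int((w - spacing) // spacing))
    if per_row * max(1, int((h - spacing) // spacing)) < n_nuclei:
        raise ValueError(f"{n_nuclei} nuclei do not fit a {h}x{w} image")
    dapi = np.zeros((h, w))
    foci_ch = np.zeros((h, w))
    envelope = np.zeros((h, w))
    labels_img = np.zeros((h, w), dtype=np.int32)
    contours: list[Contour] = []
    labels: list[str] = []
    foci_xy: list[np.ndarray] = []
    n_vert = 256
    for i, (n_foci, n_inv) in enumerate(
        zip(foci_per_nucleus, invaginations_per_nucleus)
    ):
        gx, gy = i % per_row, i // per_row
        center = np.array([spacing * (gx + 1), spacing * (gy + 1)])
        theta = 2 * np.pi * np.arange(n_vert) / n_vert
        r = np.full(n_vert, r_px)
        phase = rng.uniform(0, 2 * np.pi)
        if n_inv > 0:
            for k in range(n_inv):
                th_k = phase + 2 * np.pi * k / n_inv
                dth = np.angle(np.exp(1j * (theta - th_k)))
                r -= notch_depth_frac * r_px * np.exp(
                    -(dth**2) / (2 * notch_width_rad**2)
                )
        poly = np.column_stack(
            [center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)]
        )
        contour = Contour(poly, pixel_size_um=px)
        contours.append(contour)
        labels.append(f"nucleus{i}")
        from .intensity import contour_mask  # local import avoids a cycle

        mask = contour_mask(contour, (h, w))
        dapi[mask] += amplitude
        labels_img[mask] = i + 1
        dist_in = ndimage.distance_transform_edt(mask)
        dist_out = ndimage.distance_transform_edt(~mask)
        ring = (mask & (dist_in <= 1.5)) | ((~mask) & (dist_out <= 1.5))
        envelope[ring] += amplitude
        # plant foci by rejection sampling inside the eroded nucleus
        inner = mask & (dist_in > 3 * focus_sigma_px)
        iy, ix = np.nonzero(inner)
        if n_foci > 0 and len(iy) == 0:
            raise ValueError(f"nucleus {i} too small to hold foci")
        placed: list[np.ndarray] = []
        tries = 0
        while len(placed) < n_foci:
            tries += 1
            if tries > 500 * max(1, n_foci):
                raise ValueError(
                    f"nucleus {i}: could not place {n_foci} foci at "
                    f"separation >= {min_separation_px} px (overcrowded)"
                )
            j = int(rng.integers(0, len(iy)))
            p = np.array([ix[j], iy[j]], dtype=float)
            if all(
                np.hypot(*(p - q)) >= max(3.0, min_separation_px)
                for q in placed
            ):
                placed.append(p)
        pts = np.asarray(placed, dtype=float).reshape(-1, 2)
        foci_xy.append(pts)
        for fx, fy in pts:
            y0, y1 = int(fy - 4 * focus_sigma_px), int(fy + 4 * focus_sigma_px) + 1
            x0, x1 = int(fx - 4 * focus_sigma_px), int(fx + 4 * focus_sigma_px) + 1
            yy, xx = np.mgrid[max(0, y0) : min(h, y1), max(0, x0) : min(w, x1)]
            foci_ch[yy, xx] += focus_amplitude * np.exp(
                -((xx - fx) ** 2 + (yy - fy) ** 2) / (2 * focus_sigma_px**2)
            )
    image = _finalize(
        {"dapi": dapi, "foci": foci_ch, "envelope": envelope}, spec, rng
    )
    truth = GroundTruth(
        contours=contours,
        labels=labels,
        scalar_truth={
            "foci_per_nucleus": foci_per_nucleus,
            "invaginations_per_nucleus": list(invaginations_per_nucleus),
        },
        extras={"nuclear_masks": labels_img, "foci_xy": foci_xy},
    )
    return image, truth


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def write_scene(
    image: MultiChannelImage,
    truth: GroundTruth,
    out_dir: str | Path,
    stem: str = "scene",
) -> None:
    """Write a scene as 16-bit TIFF plus a sidecar JSON ground-truth file.

    Raster truth (masks) goes to companion TIFFs; contours, labels and
    scalar truth to ``<stem>_truth.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_tiff(image, out_dir / f"{stem}.tif")
    payload = {
        "labels": truth.labels,
        "contours": [c.vertices.tolist() for c in truth.contours],
        "pixel_size_um": image.pixel_size_um,
        "scalar_truth": truth.scalar_truth,
    }
    import tifffile

    for key, val in truth.extras.items():
        if isinstance(val, np.ndarray) and val.ndim == 2:
            tifffile.imwrite(
                out_dir / f"{stem}_{key}.tif", val.astype(np.uint16)
            )
            payload[f"{key}_file"] = f"{stem}_{key}.tif"
    write_json(payload, out_dir / f"{stem}_truth.json")
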