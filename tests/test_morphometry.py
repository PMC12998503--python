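"""Contour morphometrics: ellipse fits, shape metrics, track dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.draw import polygon2mask

from confinequant.morphometry import (
    Contour,
    TrackedObject,
    align_on_event,
    contour_metrics,
    fit_ellipse,
    polygon_area,
    polygon_perimeter,
    protrusion_metrics,
    track_shape_dynamics,
)

from conftest import circle_contour, ellipse_contour, square_contour


def random_convex_contour(rng, n_pts=12, scale=60.0, center=(150.0, 150.0)):
    """Convex hull of random points, as a closed contour."""
    from scipy.spatial import ConvexHull

    pts = center + rng.normal(size=(n_pts, 2)) * scale / 2
    hull = ConvexHull(pts)
    return Contour(pts[hull.vertices])


def rasterized_moment_ellipse(contour, shape=(320, 320)):
    """Independent oracle: axes from pixel second moments of the filled mask."""
    v = contour.vertices
    mask = polygon2mask(shape, np.column_stack([v[:, 1], v[:, 0]]))
    ys, xs = np.nonzero(mask)
    cov = np.cov(np.stack([xs, ys]), bias=True)
    lam = np.linalg.eigvalsh(cov)
    area = mask.sum()
    semi_minor, semi_major = 2 * np.sqrt(lam[0]), 2 * np.sqrt(lam[1])
    scale = np.sqrt(area / (np.pi * semi_major * semi_minor))
    return 2 * semi_major * scale, 2 * semi_minor * scale


class TestContour:
    def test_requires_three_vertices(self):
        with pytest.raises(ValueError):
            Contour(np.array([[0, 0], [1, 1]]))

    def test_rejects_self_intersection(self):
        bowtie = np.array([[0, 0], [2, 2], [2, 0], [0, 2]], dtype=float)
        with pytest.raises(ValueError):
            Contour(bowtie)

    def test_orientation_normalized(self):
        cw = np.array([[0, 0], [0, 2], [2, 2], [2, 0]], dtype=float)
        c = Contour(cw)
        x, y = c.vertices[:, 0], c.vertices[:, 1]
        signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        assert signed > 0


class TestFitEllipse:
    def test_circle_axes(self):
        fit = fit_ellipse(circle_contour(radius=20))
        assert fit.major_axis == pytest.approx(40, abs=0.5)
        assert fit.minor_axis == pytest.approx(40, abs=0.5)

    def test_axis_aligned_ellipse(self):
        fit = fit_ellipse(ellipse_contour(40, 20))
        assert fit.major_axis == pytest.approx(80, abs=0.5)
        assert fit.minor_axis == pytest.approx(40, abs=0.5)
        assert abs(fit.orientation) < 0.01

    def test_rotated_ellipse_orientation(self):
        fit0 = fit_ellipse(ellipse_contour(40, 20))
        fit30 = fit_ellipse(ellipse_contour(40, 20, angle=np.pi / 6))
        assert fit30.major_axis == pytest.approx(fit0.major_axis, rel=1e-6)
        assert fit30.minor_axis == pytest.approx(fit0.minor_axis, rel=1e-6)
        assert fit30.orientation == pytest.approx(np.pi / 6, abs=0.01)

    def test_degenerate_contour_raises(self):
        with pytest.raises(ValueError):
            # simple but zero-area: a sliver along a line
            fit_ellipse(Contour(np.array([[0, 0], [10, 0], [5, 1e-14]])))

    def test_rasterized_moment_oracle(self, rng):
        """Moment fit matches an independent pixel-moment oracle on 50
        random convex polygons within 1%."""
        for _ in range(50):
            c = random_convex_contour(rng)
            fit = fit_ellipse(c)
            major_o, minor_o = rasterized_moment_ellipse(c)
            assert fit.major_axis == pytest.approx(major_o, rel=0.01)
            assert fit.minor_axis == pytest.approx(minor_o, rel=0.01)


class TestContourMetrics:
    def test_circle(self):
        m = contour_metrics(circle_contour(radius=20))
        assert m.roundness == pytest.approx(1.0, abs=0.02)
        assert m.aspect_ratio == pytest.approx(1.0, abs=0.02)

    def test_two_to_one_ellipse(self):
        # for an ellipse, roundness = 4*pi*a*b / (pi*(2a)^2) = b/a
        m = contour_metrics(ellipse_contour(40, 20))
        assert m.roundness == pytest.approx(0.5, abs=0.02)
        assert m.aspect_ratio == pytest.approx(2.0, abs=0.02)

    def test_unit_square(self):
        m = contour_metrics(square_contour(1.0))
        assert m.area_px2 == pytest.approx(1.0)
        assert m.perimeter_px == pytest.approx(4.0)
        assert m.aspect_ratio == pytest.approx(1.0, abs=1e-9)

    def test_pixel_size_scaling(self):
        m1 = contour_metrics(circle_contour(radius=20, pixel_size_um=1.0))
        m2 = contour_metrics(circle_contour(radius=20, pixel_size_um=0.5))
        assert m2.perimeter_um == pytest.approx(m1.perimeter_um / 2)
        assert m2.area_um2 == pytest.approx(m1.area_um2 / 4)
        assert m2.roundness == pytest.approx(m1.roundness)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        angle=st.floats(0, 2 * np.pi),
        tx=st.floats(-50, 50),
        ty=st.floats(-50, 50),
    )
    def test_rigid_motion_invariance(self, angle, tx, ty):
        """Area, perimeter, roundness, aspect invariant under rigid motion."""
        base = ellipse_contour(35, 18, n=500)
        ct, st_ = np.cos(angle), np.sin(angle)
        R = np.array([[ct, -st_], [st_, ct]])
        moved = Contour(base.vertices @ R.T + [tx, ty])
        m0, m1 = contour_metrics(base), contour_metrics(moved)
        assert m1.area_px2 == pytest.approx(m0.area_px2, rel=0.005)
        assert m1.perimeter_px == pytest.approx(m0.perimeter_px, rel=0.005)
        assert m1.roundness == pytest.approx(m0.roundness, rel=0.005)
        assert m1.aspect_ratio == pytest.approx(m0.aspect_ratio, rel=0.005)


class TestProtrusions:
    def test_pythagorean_length(self):
        m = protrusion_metrics(
            np.array([[0, 0], [3, 4]]), np.array([[0, 0], [0, 1]]), 1.0
        )
        assert m.length_um == pytest.approx(5.0)

    def test_base_width_scaling(self):
        m = protrusion_metrics(
            np.array([[0, 0], [10, 0]]), np.array([[0, 0], [0, 6]]), 0.5
        )
        assert m.base_width_um == pytest.approx(3.0)

    def test_width_to_length_ratio(self):
        m = protrusion_metrics(
            np.array([[0, 0], [0, 10]]), np.array([[0, 0], [2, 0]]), 1.0
        )
        assert m.width_to_length == pytest.approx(0.2)

    def test_zero_length_path_raises(self):
        with pytest.raises(ValueError):
            protrusion_metrics(
                np.array([[1, 1], [1, 1]]), np.array([[0, 0], [0, 1]]), 1.0
            )


def _square_track(sides, step=(0.0, 0.0), dt_min=1.0):
    contours = [
        square_contour(
            s, center=(10 + i * step[0], 10 + i * step[1]), frame=i
        )
        for i, s in enumerate(sides)
    ]
    return TrackedObject(
        id="t", frames=np.arange(len(sides)), dt_min=dt_min, contours=contours
    )


class TestTrackDynamics:
    def test_static_track_zero_variance(self):
        track = _square_track([3.0] * 6)
        d = track_shape_dynamics(track, window_min=5)
        assert d.perimeter_variance_um2 == 0.0
        assert d.min_aspect == d.max_aspect

    def test_population_variance_hand_value(self):
        # perimeters 10,12,14,10,12,14 -> population variance 8/3
        track = _square_track([2.5, 3.0, 3.5, 2.5, 3.0, 3.5])
        d = track_shape_dynamics(track, window_min=5)
        assert d.perimeter_variance_um2 == pytest.approx(8 / 3)

    def test_trailing_displacement(self):
        # centroid advances (0.6, 0.8) px per frame; over 5 frames -> 5 px
        track = _square_track([3.0] * 6, step=(0.6, 0.8))
        d = track_shape_dynamics(track, window_min=5)
        assert np.isnan(d.trailing_displacement_um[:5]).all()
        assert d.trailing_displacement_um[5] == pytest.approx(5.0)

    def test_short_track_raises(self):
        with pytest.raises(ValueError, match="5"):
            track_shape_dynamics(_square_track([3.0] * 4))

    def test_window_must_divide(self):
        with pytest.raises(ValueError):
            track_shape_dynamics(_square_track([3.0] * 6, dt_min=2.0), window_min=5)


class TestAlignOnEvent:
    def test_identical_series_zero_sd(self):
        s = np.array([1.0, 2.0, 3.0, 4.0])
        a = align_on_event([s, s], [2, 2])
        assert np.all(a.sd[a.n == 2] == 0)

    def test_relative_shift(self):
        s1 = np.arange(6.0)
        s2 = np.arange(6.0)
        a = align_on_event([s1, s2], [2, 4])
        # at lag 0 both series show their event value
        lag0 = np.where(a.lags == 0)[0][0]
        assert a.matrix[0, lag0] == 2.0
        assert a.matrix[1, lag0] == 4.0

    def test_hand_computed_means(self):
        s1 = np.array([1.0, 2.0, 3.0])
        s2 = np.array([10.0, 20.0, 30.0])
        s3 = np.array([5.0, 6.0, 7.0])
        a = align_on_event([s1, s2, s3], [1, 1, 1])
        assert a.lags.tolist() == [-1, 0, 1]
        np.testing.assert_allclose(a.mean, [16 / 3, 28 / 3, 40 / 3])

    def test_event_outside_raises(self):
        with pytest.raises(ValueError):
            align_on_event([np.arange(3.0)], [5])


def test_polygon_helpers_exact():
    sq = square_contour(2.0).vertices
    assert polygon_area(sq) == pytest.approx(4.0)
    assert polygon_perimeter(sq) == pytest.approx(8.0)
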