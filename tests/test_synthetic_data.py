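"""Synthetic-scene generators: determinism, noise scaling, ground truth."""

import numpy as np
import pytest

from confinequant.image import read_tiff
from confinequant.morphometry import contour_metrics
from confinequant.synthetic_data import (
    GroundTruth,
    SceneSpec,
    make_bm_scene,
    make_cell_scene,
    make_dextran_scene,
    make_embryo_pointcloud,
    make_foci_scene,
    make_force_curve,
    write_scene,
)


class TestSceneSpec:
    def test_rejects_negative_noise(self):
        with pytest.raises(ValueError):
            SceneSpec(seed=0, noise_sd=-1.0)

    def test_rejects_nonpositive_pixel(self):
        with pytest.raises(ValueError):
            SceneSpec(seed=0, pixel_size_um=0.0)


class TestDeterminism:
    """Same seed, byte-identical output, for every generator."""

    def test_cell_scene(self):
        spec = SceneSpec(seed=42)
        a, _ = make_cell_scene(spec, n_timepoints=2)
        b, _ = make_cell_scene(spec, n_timepoints=2)
        for ia, ib in zip(a, b):
            assert ia.data.tobytes() == ib.data.tobytes()

    def test_bm_scene(self):
        a, _ = make_bm_scene(SceneSpec(seed=7), gap_fraction=0.3)
        b, _ = make_bm_scene(SceneSpec(seed=7), gap_fraction=0.3)
        assert a.data.tobytes() == b.data.tobytes()

    def test_dextran_scene(self):
        a, ta = make_dextran_scene(SceneSpec(seed=7))
        b, tb = make_dextran_scene(SceneSpec(seed=7))
        assert a.data.tobytes() == b.data.tobytes()
        assert np.array_equal(ta.extras["gap_mask"], tb.extras["gap_mask"])

    def test_force_curve(self):
        a, _ = make_force_curve(1000.0, noise_sd=1e-11, seed=5)
        b, _ = make_force_curve(1000.0, noise_sd=1e-11, seed=5)
        assert a.force.tobytes() == b.force.tobytes()

    def test_pointcloud(self):
        a, _ = make_embryo_pointcloud(seed=9, n_pgc=2, pgc_depths_um=[5, 10])
        b, _ = make_embryo_pointcloud(seed=9, n_pgc=2, pgc_depths_um=[5, 10])
        assert a[0].somatic_xyz.tobytes() == b[0].somatic_xyz.tobytes()
        assert a[0].pgc_xyz.tobytes() == b[0].pgc_xyz.tobytes()

    def test_foci_scene(self):
        spec = SceneSpec(seed=3, image_shape=(320, 320), pixel_size_um=0.25)
        a, _ = make_foci_scene(spec, foci_per_nucleus=[4, 2])
        b, _ = make_foci_scene(spec, foci_per_nucleus=[4, 2])
        assert a.data.tobytes() == b.data.tobytes()


def test_background_noise_sd_matches_spec():
    """Sample SD of a flat background region within 10% of noise_sd."""
    spec = SceneSpec(seed=1, image_shape=(300, 300), pixel_size_um=0.25,
                     noise_sd=3.0, background_level=50.0)
    img, truth = make_bm_scene(spec, thickness_um=2.0)
    row = int(truth.scalar_truth["row"])
    # a corner far from the membrane stripe
    corner = img.channel("bm")[:100, :150] if row > 150 else \
        img.channel("bm")[200:, :150]
    assert corner.size >= 10_000
    assert np.std(corner) == pytest.approx(3.0, rel=0.10)


class TestCellScene:
    def test_circle_truth_roundness(self):
        spec = SceneSpec(seed=2, noise_sd=0.0)
        _, truth = make_cell_scene(spec, n_cells=1, body_axes_um=(10.0, 10.0))
        m = contour_metrics(truth.extras["cells"][0][0]["body"])
        assert m.roundness == pytest.approx(1.0, abs=0.02)
        assert m.aspect_ratio == pytest.approx(1.0, abs=0.02)

    def test_truth_aspect_recovery(self):
        spec = SceneSpec(seed=3, noise_sd=0.0)
        _, truth = make_cell_scene(spec, n_cells=2, body_axes_um=(15.0, 9.0))
        for cell in truth.extras["cells"][0]:
            m = contour_metrics(cell["body"])
            assert m.aspect_ratio == pytest.approx(15 / 9, rel=0.03)

    def test_one_truth_entry_per_object(self):
        spec = SceneSpec(seed=4)
        imgs, truth = make_cell_scene(spec, n_cells=3, n_timepoints=2)
        assert len(imgs) == 2
        assert len(truth.contours) == len(truth.labels) == 3 * 2 * 2
        assert len(set(truth.labels)) == len(truth.labels)

    def test_placement_failure_message(self):
        spec = SceneSpec(seed=5, image_shape=(96, 96))
        with pytest.raises(ValueError, match="do not fit|feasible"):
            make_cell_scene(spec, n_cells=30, body_axes_um=(20.0, 20.0))

    def test_protrusion_truth_length(self):
        spec = SceneSpec(seed=6, noise_sd=0.0)
        _, truth = make_cell_scene(spec, n_cells=1, protrusion_length_um=6.0)
        line = truth.extras["cells"][0][0]["protrusion"]
        length = np.hypot(*(line[1] - line[0])) * spec.pixel_size_um
        assert length == pytest.approx(6.0, rel=1e-6)


class TestBMScene:
    def test_thickness_below_resolution_raises(self):
        spec = SceneSpec(seed=0, pixel_size_um=0.5)
        with pytest.raises(ValueError, match="unresolvable"):
            make_bm_scene(spec, thickness_um=0.8)

    def test_rendered_fwhm_matches(self):
        """3 um at 0.25 um/px renders a 12 px FWHM cross-section."""
        spec = SceneSpec(seed=1, image_shape=(200, 200), pixel_size_um=0.25,
                         noise_sd=0.0, background_level=0.0)
        img, truth = make_bm_scene(spec, thickness_um=3.0)
        col = img.channel("bm")[:, 100]
        above = np.nonzero(col >= col.max() / 2)[0]
        width = above[-1] - above[0] + 1  # integer-sampled FWHM
        assert width == pytest.approx(12, abs=0.5)

    def test_gap_fraction_recorded(self):
        spec = SceneSpec(seed=2, image_shape=(128, 400), pixel_size_um=0.25)
        _, truth = make_bm_scene(spec, thickness_um=2.0, gap_fraction=0.5)
        assert truth.scalar_truth["gap_fraction"] == pytest.approx(0.5, abs=0.05)
        cols = truth.extras["gap_columns"]
        assert cols.mean() == truth.scalar_truth["gap_fraction"]

    def test_continuous_membrane_flat_along(self):
        spec = SceneSpec(seed=3, image_shape=(128, 256), pixel_size_um=0.25,
                         noise_sd=0.0)
        img, truth = make_bm_scene(spec, thickness_um=3.0, gap_fraction=0.0)
        row = img.channel("bm")[int(round(truth.scalar_truth["row"])), :]
        assert np.ptp(row) < 1e-6 * max(1.0, row.max())


class TestDextranScene:
    def test_truth_fraction_near_target(self):
        for f in (0.1, 0.3):
            _, truth = make_dextran_scene(SceneSpec(seed=4), target_fraction=f)
            assert truth.scalar_truth["fraction"] == pytest.approx(f, abs=0.02)

    def test_two_level_threshold_recovers_mask(self):
        spec = SceneSpec(seed=5, noise_sd=0.0, background_level=10.0)
        img, truth = make_dextran_scene(spec, target_fraction=0.3)
        mask = img.channel("dextran") > 10.0 + 100.0  # halfway level
        np.testing.assert_array_equal(mask, truth.extras["gap_mask"])

    def test_infeasible_fraction_raises(self):
        with pytest.raises(ValueError):
            make_dextran_scene(SceneSpec(seed=6), target_fraction=0.95)


class TestForceCurveGen:
    def test_offset_at_zero_indentation(self):
        curve, truth = make_force_curve(1000.0, C=3e-10, noise_sd=0.0)
        i = truth["contact_index"]
        assert curve.force[i] == 3e-10

    def test_printed_formula_value(self):
        curve, _ = make_force_curve(1000.0, C=0.0, noise_sd=0.0,
                                    delta_max_nm=250.0, n_points=50)
        assert curve.force[-1] == pytest.approx(3.61e-10, rel=2e-3)

    def test_doubling_E_doubles_force(self):
        c1, _ = make_force_curve(1000.0, noise_sd=0.0)
        c2, _ = make_force_curve(2000.0, noise_sd=0.0)
        np.testing.assert_allclose(c2.force, 2 * c1.force, rtol=1e-12)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            make_force_curve(1000.0, n_points=10)


class TestFociSceneGen:
    def test_half_positive_by_rule(self):
        from confinequant.nuclear_integrity import classify_foci

        spec = SceneSpec(seed=8, image_shape=(320, 320), pixel_size_um=0.25)
        _, truth = make_foci_scene(spec, foci_per_nucleus=[12, 3])
        cls = classify_foci(truth.scalar_truth["foci_per_nucleus"], "gammaH2AX")
        assert cls.percent_positive == 50.0

    def test_overcrowded_raises(self):
        spec = SceneSpec(seed=9, image_shape=(128, 128), pixel_size_um=0.5)
        with pytest.raises(ValueError, match="overcrowd"):
            make_foci_scene(spec, foci_per_nucleus=[80], nucleus_radius_um=5.0)

    def test_labeled_masks_match_contours(self):
        spec = SceneSpec(seed=10, image_shape=(320, 320), pixel_size_um=0.25)
        _, truth = make_foci_scene(spec, foci_per_nucleus=[1, 2, 3])
        masks = truth.extras["nuclear_masks"]
        assert sorted(np.unique(masks)) == [0, 1, 2, 3]


def test_ground_truth_label_pairing():
    with pytest.raises(ValueError):
        GroundTruth(contours=[], labels=["orphan"])


def test_write_scene_roundtrip(tmp_path):
    spec = SceneSpec(seed=11, image_shape=(128, 128))
    img, truth = make_dextran_scene(spec, target_fraction=0.2)
    write_scene(img, truth, tmp_path, stem="dex")
    assert (tmp_path / "dex.tif").exists()
    assert (tmp_path / "dex_truth.json").exists()
    assert (tmp_path / "dex_gap_mask.tif").exists()
    back = read_tiff(tmp_path / "dex.tif")
    assert back.pixel_size_um == img.pixel_size_um
    assert back.shape == img.shape
    # 16-bit quantization: within rounding of the float original
    assert np.max(np.abs(back.data - np.clip(np.round(img.data), 0, 65535))) == 0
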