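import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.draw import ellipse as draw_ellipse

from bypassflow import morphometry as mo
from bypassflow.synthimage import MonolayerSpec, generate_monolayer


def ellipse_image(shape, centers, radii, angle=0.0, value=1.0):
    img = np.zeros(shape)
    for (r, c) in centers:
        rr, cc = draw_ellipse(r, c, radii[0], radii[1], shape=shape,
                              rotation=angle)
        img[rr, cc] = value
    return img


class TestSegmentNuclei:
    def test_recovers_cell_count(self, monolayer_100):
        spec, image, truth = monolayer_100
        labels = mo.segment_nuclei(image[0], spec.pixel_size)
        assert labels.max() == pytest.approx(100, abs=5)

    def test_blank_image_gives_zero_labels(self):
        assert mo.segment_nuclei(np.zeros((64, 64)), 0.3).max() == 0

    def test_overlapping_pair_split_by_watershed(self):
        img = ellipse_image((120, 120), [(60, 45), (60, 78)], (18, 22))
        labels = mo.segment_nuclei(img, pixel_size=1.0, min_size_um2=30,
                                   h_um=3.0, distance_sigma=1.0)
        assert labels.max() == 2

    def test_debris_filtered_by_size(self):
        img = ellipse_image((100, 100), [(50, 50)], (15, 15))
        img[10, 10] = 1.0  # single-pixel speck
        labels = mo.segment_nuclei(img, pixel_size=1.0, min_size_um2=30)
        assert labels.max() == 1


class TestSegmentCells:
    def test_boundary_displacement_under_2px(self, monolayer_100):
        spec, image, truth = monolayer_100
        nuclei = mo.segment_nuclei(image[0], spec.pixel_size)
        cells = mo.segment_cells(nuclei, image[1])
        from skimage.segmentation import find_boundaries
        from scipy import ndimage as ndi
        dist = ndi.distance_transform_edt(~find_boundaries(truth.label_map))
        assert dist[find_boundaries(cells)].mean() < 2.0

    def test_uniform_guidance_gives_geometric_voronoi(self):
        nuclei = np.zeros((80, 80), dtype=np.int32)
        nuclei[20, 20] = 1
        nuclei[60, 60] = 2
        cells = mo.segment_cells(nuclei, np.ones((80, 80)))
        # each pixel belongs to the nearer seed (up to the 1-px ridge)
        rr, cc = np.mgrid[0:80, 0:80]
        d1 = np.hypot(rr - 20, cc - 20)
        d2 = np.hypot(rr - 60, cc - 60)
        expected = np.where(d1 <= d2, 1, 2)
        agree = (cells == expected) | (np.abs(d1 - d2) < 3)
        assert agree.mean() > 0.98

    def test_single_nucleus_fills_image(self):
        nuclei = np.zeros((40, 40), dtype=np.int32)
        nuclei[20, 20] = 1
        cells = mo.segment_cells(nuclei, np.zeros((40, 40)))
        assert (cells == 1).all()

    def test_zero_nuclei_zero_cells(self):
        assert mo.segment_cells(np.zeros((10, 10), dtype=int),
                                np.ones((10, 10))).max() == 0


class TestShapeFeatures:
    def test_disk_is_round(self):
        img = np.zeros((100, 100), dtype=int)
        rr, cc = draw_ellipse(50, 50, 30, 30)
        img[rr, cc] = 1
        rec = mo.shape_features(img, 1.0).iloc[0]
        assert rec.eccentricity < 0.05 and rec.axis_ratio < 1.05

    def test_two_to_one_ellipse(self):
        img = np.zeros((120, 160), dtype=int)
        rr, cc = draw_ellipse(60, 80, 25, 50)
        img[rr, cc] = 1
        rec = mo.shape_features(img, 1.0).iloc[0]
        assert rec.axis_ratio == pytest.approx(2.0, abs=0.05)
        assert rec.eccentricity == pytest.approx(np.sqrt(1 - 0.25),
                                                 abs=0.01)

    def test_orientation_recovery_vs_truth(self, monolayer_100):
        spec, image, truth = monolayer_100
        nuclei = mo.segment_nuclei(image[0], spec.pixel_size)
        cells = mo.segment_cells(nuclei, image[1])
        sf = mo.shape_features(cells, spec.pixel_size)
        mapping = mo.match_labels(cells, truth.label_map)
        tc = truth.cells.set_index("cell_id")
        errs = [float(mo.alignment_angle(r.orientation_deg,
                                         tc.loc[mapping[r.cell_id],
                                                "orientation_deg"]))
                for _, r in sf.iterrows()
                if not r.excluded and not r.on_border
                and r.cell_id in mapping]
        assert len(errs) > 30
        assert np.median(errs) < 3.0

    def test_eccentricity_ratio_identity(self, monolayer_100):
        spec, image, truth = monolayer_100
        nuclei = mo.segment_nuclei(image[0], spec.pixel_size)
        sf = mo.shape_features(mo.segment_cells(nuclei, image[1]),
                               spec.pixel_size)
        ok = sf[~sf.excluded]
        np.testing.assert_allclose(
            ok.eccentricity, np.sqrt(1 - 1 / ok.axis_ratio ** 2),
            atol=1e-9)

    def test_translation_and_rotation_equivariance(self):
        img = np.zeros((140, 140), dtype=int)
        rr, cc = draw_ellipse(60, 60, 20, 40, rotation=0.4)
        img[rr, cc] = 1
        base = mo.shape_features(img, 1.0).iloc[0]
        shifted = np.roll(img, (15, -10), axis=(0, 1))
        s = mo.shape_features(shifted, 1.0).iloc[0]
        assert s.axis_ratio == pytest.approx(base.axis_ratio, abs=1e-6)
        rotated = np.rot90(img)
        r = mo.shape_features(rotated, 1.0).iloc[0]
        assert r.axis_ratio == pytest.approx(base.axis_ratio, abs=0.02)
        assert float(mo.alignment_angle(r.orientation_deg,
                                        base.orientation_deg)) == \
            pytest.approx(90.0, abs=1.0)


class TestAlignmentAngle:
    @pytest.mark.parametrize("o, f, expected", [
        (0, 0, 0), (120, 0, 60), (-30, 0, 30), (90, 0, 90),
        (179, 0, 1), (-90, 90, 0)])
    def test_examples(self, o, f, expected):
        assert float(mo.alignment_angle(o, f)) == pytest.approx(expected)

    @given(o=st.floats(-1000, 1000), f=st.floats(-1000, 1000))
    @settings(max_examples=100, deadline=None)
    def test_range_and_axis_symmetry(self, o, f):
        a = float(mo.alignment_angle(o, f))
        assert 0.0 <= a <= 90.0
        assert float(mo.alignment_angle(o + 180, f)) == pytest.approx(
            a, abs=1e-6)
        assert float(mo.alignment_angle(f, o)) == pytest.approx(a, abs=1e-6)


class TestExtractProfile:
    def test_schema_fixed_and_stable(self, monolayer_100):
        spec, image, truth = monolayer_100
        nuclei = mo.segment_nuclei(image[0], spec.pixel_size)
        cells = mo.segment_cells(nuclei, image[1])
        prof1 = mo.extract_profile(cells, image, spec.pixel_size)
        prof2 = mo.extract_profile(cells, image, spec.pixel_size)
        expected = mo.profile_feature_names(("nuclei", "vecadherin",
                                             "factin"))
        assert list(prof1.columns) == ["cell_id", "on_border"] + expected
        pd.testing.assert_frame_equal(prof1, prof2)

    def test_uniform_cell_flat_radial_profile(self):
        labels = np.zeros((81, 81), dtype=int)
        rr, cc = draw_ellipse(40, 40, 35, 35)
        labels[rr, cc] = 1
        chans = np.ones((2, 81, 81))
        prof = mo.extract_profile(labels, chans, 1.0,
                                  channel_names=("a", "b"),
                                  exclude_border=False)
        rings = prof[[f"radial_a_ring{k}" for k in range(4)]].iloc[0]
        # ring fractions proportional to ring areas: (2k+1)/16
        expected = np.array([1, 3, 5, 7]) / 16
        np.testing.assert_allclose(rings, expected, atol=0.02)

    def test_identical_channels_perfect_colocalization(self):
        rng = np.random.default_rng(0)
        labels = np.zeros((40, 40), dtype=int)
        labels[5:35, 5:35] = 1
        ch = rng.random((40, 40))
        prof = mo.extract_profile(labels, np.stack([ch, ch]), 1.0,
                                  channel_names=("a", "b"),
                                  exclude_border=False)
        assert prof["coloc_a_b_corr"].iloc[0] == pytest.approx(1.0,
                                                               abs=1e-6)

    def test_border_cells_excluded_by_default(self, monolayer_100):
        spec, image, truth = monolayer_100
        nuclei = mo.segment_nuclei(image[0], spec.pixel_size)
        cells = mo.segment_cells(nuclei, image[1])
        prof = mo.extract_profile(cells, image, spec.pixel_size)
        assert not prof["on_border"].any()

    def test_requires_two_channels(self):
        with pytest.raises(ValueError):
            mo.extract_profile(np.ones((10, 10), dtype=int),
                               np.ones((1, 10, 10)), 1.0)


class TestSummarizeGroups:
    def test_null_replicates_rarely_significant(self):
        rng = np.random.default_rng(0)
        n_sig = 0
        for rep in range(100):
            df = pd.DataFrame({
                "group": np.repeat(["a", "b", "c"], 200),
                "x": rng.standard_normal(600)})
            s = mo.summarize_groups(df, "group", ["x"])
            if s["anova_p"].iloc[0] < 0.05:
                n_sig += 1
        assert n_sig <= 10

    def test_large_offset_detected(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "group": np.repeat(["a", "b"], 100),
            "x": np.concatenate([rng.standard_normal(100),
                                 5 + rng.standard_normal(100)])})
        s = mo.summarize_groups(df, "group", ["x"])
        assert s["anova_p"].iloc[0] < 1e-6

    def test_constant_sample_iqr_and_degenerate_flag(self):
        df = pd.DataFrame({"group": ["a"] * 3 + ["b"] * 3,
                           "x": [2.0] * 6})
        s = mo.summarize_groups(df, "group", ["x"])
        assert (s["q1"] == 2.0).all() and (s["q3"] == 2.0).all()
        assert s["degenerate"].all()

    def test_requires_two_groups_of_two(self):
        df = pd.DataFrame({"group": ["a", "a", "b"], "x": [1, 2, 3]})
        with pytest.raises(ValueError):
            mo.summarize_groups(df, "group", ["x"])
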