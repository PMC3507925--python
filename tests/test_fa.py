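import numpy as np
import pandas as pd
import pytest

from spreadquant.core import LabelImage
from spreadquant.fa import (FAScene, camera_background, cellular_background,
                            detect_cell_outline, detect_fas, measure_scene,
                            normalized_fa_intensity, standardize_condition,
                            subtract_camera_background)
from spreadquant.simulate import FASimParams, simulate_fa_scene

from conftest import disk_mask


def constructed_scene(n_fas=3, fa_area_side=10, fa_intensity=150.0,
                      cyto=50.0, outside=10.0, shape=(200, 200),
                      cell_radius=80.0):
    """Scene with rectangular FAs and exactly known intensity arithmetic."""
    rr, cc = np.mgrid[:shape[0], :shape[1]]
    centre = ((shape[0] - 1) / 2, (shape[1] - 1) / 2)
    cell = np.hypot(rr - centre[0], cc - centre[1]) <= cell_radius
    img = np.full(shape, outside)
    img[cell] = outside + cyto
    grid = np.zeros(shape, np.int32)
    for i in range(n_fas):
        r0 = int(centre[0] - 40 + 25 * i)
        c0 = int(centre[1] - 5)
        grid[r0:r0 + fa_area_side, c0:c0 + fa_area_side] = i + 1
        img[grid == i + 1] = outside + fa_intensity
    return img, cell, LabelImage(grid)


class TestCellOutline:
    def test_uniform_bright_disk_recovered(self):
        mask = disk_mask(40, pad=20)
        img = mask.astype(float) * 100
        out = detect_cell_outline(img, threshold=50)
        np.testing.assert_array_equal(out, mask)

    def test_holes_are_filled_and_largest_component_kept(self):
        img = np.zeros((100, 100))
        img[20:60, 20:60] = 100
        img[35:45, 35:45] = 0      # hole
        img[80:85, 80:85] = 100    # smaller second component
        out = detect_cell_outline(img, threshold=50)
        assert out[40, 40]          # hole filled
        assert not out[82, 82]      # smaller component dropped

    def test_all_dark_image_rejected(self):
        with pytest.raises(ValueError):
            detect_cell_outline(np.zeros((50, 50)), threshold=10)

    def test_generator_cell_recovered_at_high_snr(self):
        params = FASimParams(seed=4, noise_sd=10.0)  # punctum SNR 15
        scene, truth = simulate_fa_scene(params)
        out = detect_cell_outline(scene.primary_channel)
        jaccard = (out & truth.cell_mask).sum() / (out | truth.cell_mask).sum()
        assert jaccard >= 0.9


class TestDetectFAs:
    def test_planted_puncta_counted_and_nuclear_spots_excluded(self):
        params = FASimParams(seed=7, n_puncta=12, n_nuclear_spots=3)
        scene, truth = simulate_fa_scene(params)
        labels = detect_fas(scene.primary_channel, truth.cell_mask,
                            scene.exclusion_regions)
        assert len(labels.label_ids) == 12

    def test_no_puncta_gives_empty_labelling(self):
        params = FASimParams(seed=1, n_puncta=0)
        scene, truth = simulate_fa_scene(params)
        labels = detect_fas(scene.primary_channel, truth.cell_mask,
                            scene.exclusion_regions)
        assert labels.label_ids == frozenset()

    def test_all_detections_inside_cell_and_outside_exclusions(self):
        params = FASimParams(seed=3, n_puncta=10, n_nuclear_spots=2,
                             noise_sd=10.0)
        scene, truth = simulate_fa_scene(params)
        labels = detect_fas(scene.primary_channel, truth.cell_mask,
                            scene.exclusion_regions)
        fa_px = labels.grid > 0
        assert not (fa_px & ~truth.cell_mask).any()
        rr, cc = np.mgrid[:fa_px.shape[0], :fa_px.shape[1]]
        for r0, c0, rad in scene.exclusion_regions:
            inside = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad ** 2
            assert not (fa_px & inside).any()

    def test_punctum_straddling_cell_edge_excluded(self):
        img, cell, _ = constructed_scene(n_fas=0)
        rr, cc = np.mgrid[:200, :200]
        centre_edge = (99.5 + 80, 99.5)  # on the cell boundary
        punctum = np.hypot(rr - centre_edge[0], cc - centre_edge[1]) <= 3
        img[punctum] = 300
        labels = detect_fas(img, cell, [])
        assert labels.label_ids == frozenset()


class TestBackgroundArithmetic:
    def test_uniform_outside_value_recovered(self):
        img, cell, _ = constructed_scene(outside=10.0)
        assert camera_background(img, cell) == pytest.approx(10.0, abs=1e-12)

    def test_bimodal_outside_averages(self):
        img = np.zeros((50, 50))
        img[:25] = 8.0
        img[25:] = 12.0
        cell = np.zeros((50, 50), bool)
        assert camera_background(img, cell) == pytest.approx(10.0)

    def test_random_outside_field_matches_direct_mean(self, rng):
        cell = disk_mask(25, pad=24)
        img = rng.uniform(0, 30, cell.shape)
        assert camera_background(img, cell) == pytest.approx(
            img[~cell].mean(), abs=1e-12)

    def test_too_few_outside_pixels_rejected(self):
        img = np.zeros((10, 10))
        cell = np.ones((10, 10), bool)
        with pytest.raises(ValueError):
            camera_background(img, cell)

    def test_camera_subtraction_clamps_at_zero(self):
        out = subtract_camera_background(np.array([[5.0, 20.0]]), 10.0)
        np.testing.assert_array_equal(out, [[0.0, 10.0]])

    def test_cellular_background_excludes_fa_pixels(self):
        img, cell, fa = constructed_scene(fa_intensity=200.0, cyto=50.0,
                                          outside=0.0)
        assert cellular_background(img, cell, fa) == pytest.approx(50.0)

    def test_cellular_background_without_fas_is_whole_cell_mean(self, rng):
        cell = disk_mask(30, pad=19)
        img = rng.uniform(0, 100, cell.shape)
        assert cellular_background(img, cell) == pytest.approx(
            img[cell].mean(), abs=1e-12)


class TestNormalizedIntensity:
    def test_closed_form_construction_returns_900(self):
        # 3 FAs x 100 px at corrected intensity 150, cellular background 50
        img, cell, fa = constructed_scene(n_fas=3, fa_area_side=10,
                                          fa_intensity=150.0, cyto=50.0,
                                          outside=10.0)
        cam = camera_background(img, cell)
        corrected = subtract_camera_background(img, cam)
        bg = cellular_background(corrected, cell, fa)
        assert normalized_fa_intensity(corrected, fa, bg) == pytest.approx(
            900.0, rel=1e-9)

    def test_no_fas_gives_zero(self):
        img, cell, _ = constructed_scene(n_fas=0)
        empty = LabelImage(np.zeros(img.shape, np.int32))
        assert normalized_fa_intensity(img, empty, 50.0) == 0.0

    def test_gain_and_offset_invariance(self):
        img, cell, fa = constructed_scene()
        def normalized(image):
            cam = camera_background(image, cell)
            corr = subtract_camera_background(image, cam)
            return normalized_fa_intensity(corr, fa, cellular_background(corr, cell, fa))
        base = normalized(img)
        assert normalized(img * 3.0) == pytest.approx(base, rel=1e-9)
        assert normalized(img + 40.0) == pytest.approx(base, rel=1e-9)

    def test_nonpositive_background_rejected(self):
        img, _, fa = constructed_scene()
        with pytest.raises(ValueError):
            normalized_fa_intensity(img, fa, 0.0)


class TestDualStain:
    def test_identical_channels_give_ratio_one(self):
        img, cell, fa = constructed_scene()
        scene = FAScene(primary_channel=img, secondary_channel=img.copy())
        m = measure_scene(scene, cell_mask=cell, fa_labels=fa)
        assert m.ratio == pytest.approx(1.0, rel=1e-9)

    def test_planted_two_to_one_ratio_recovered(self):
        # normalized level per FA px is (cyto+amp)/cyto: 200/50=4 vs 400/50=8
        params = FASimParams(seed=5, punctum_intensity=150.0,
                             secondary_punctum_intensity=350.0,
                             secondary_cytoplasm_level=50.0)
        scene, truth = simulate_fa_scene(params)
        m = measure_scene(scene, cell_mask=truth.cell_mask,
                          fa_labels=LabelImage(truth.fa_labels))
        assert m.ratio == pytest.approx(truth.ratio, rel=1e-9)
        assert truth.ratio == pytest.approx(2.0, rel=0.01)

    def test_zero_secondary_signal_gives_zero_ratio(self):
        img, cell, fa = constructed_scene()
        # secondary: cytoplasm present but FA pixels at the camera floor,
        # so their corrected intensity is zero
        secondary = np.full_like(img, 10.0)
        secondary[cell] = 60.0
        secondary[fa.grid > 0] = 10.0
        scene = FAScene(primary_channel=img, secondary_channel=secondary)
        m = measure_scene(scene, cell_mask=cell, fa_labels=fa)
        assert m.ratio == pytest.approx(0.0, abs=1e-9)

    def test_single_stain_has_no_ratio(self):
        img, cell, fa = constructed_scene()
        m = measure_scene(FAScene(primary_channel=img), cell_mask=cell,
                          fa_labels=fa)
        assert m.ratio is None

    def test_detection_route_ratio_within_10pct_at_snr_5(self):
        params = FASimParams(seed=11, noise_sd=30.0,  # punctum SNR 5
                             secondary_punctum_intensity=75.0)
        scene, truth = simulate_fa_scene(params)
        m = measure_scene(scene)
        assert m.ratio == pytest.approx(truth.ratio, rel=0.10)


class TestStandardizeCondition:
    def make_df(self):
        return pd.DataFrame({
            "experiment": [1, 1, 2, 2, 3, 3],
            "condition": ["007", "PP2", "007", "PP2", "007", "PP2"],
            "normalized_total_intensity": [2.0, 1.0, 4.0, 2.0, 6.0, 3.0],
        })

    def test_reference_mean_maps_to_one(self):
        out = standardize_condition(self.make_df(), "007")
        ref = out[out.condition == "007"]
        assert ref["normalized_total_intensity_standardized"].mean() == pytest.approx(1.0)

    def test_values_divided_by_reference_grand_mean(self):
        out = standardize_condition(self.make_df(), "007")
        # reference grand mean = 4.0
        np.testing.assert_allclose(
            out["normalized_total_intensity_standardized"],
            np.array([2, 1, 4, 2, 6, 3]) / 4.0, atol=1e-12)

    def test_missing_or_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            standardize_condition(self.make_df(), "missing")
        df = self.make_df()
        df.loc[df.condition == "007", "normalized_total_intensity"] = 0.0
        with pytest.raises(ValueError):
            standardize_condition(df, "007")
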