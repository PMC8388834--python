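import numpy as np
import pytest

import fluogrowth as fg
from fluogrowth.errors import BackgroundError, ThresholdError
from fluogrowth.simulate import simulate_image_pair


def brute_force_intermeans(values, t0=None, tol=0.5):
    """Independent fixed-point oracle for the intermeans threshold."""
    values = np.asarray(values, float).ravel()
    t = (values.min() + values.max()) / 2 if t0 is None else t0
    while True:
        lo, hi = values[values <= t], values[values > t]
        t_new = (lo.mean() + hi.mean()) / 2
        if abs(t_new - t) < tol:
            return t_new
        t = t_new


def disk_mask(shape, center, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


class TestIsodataThreshold:
    def test_binary_equal_counts_fixed_point(self):
        img = np.array([[0.0, 255.0]] * 8)
        assert fg.isodata_threshold(img) == pytest.approx(127.5)

    def test_two_level_fixed_point(self):
        assert fg.isodata_threshold(np.array([10.0, 10, 200, 200])) == 105.0

    def test_matches_brute_force_oracle_on_random_image(self):
        rng = np.random.default_rng(21)
        img = np.concatenate(
            [rng.normal(60, 5, 500), rng.normal(180, 10, 300)]
        ).reshape(40, 20)
        assert fg.isodata_threshold(img) == pytest.approx(
            brute_force_intermeans(img), abs=1e-9
        )

    def test_close_to_skimage_isodata_on_8bit(self):
        filters = pytest.importorskip("skimage.filters")
        rng = np.random.default_rng(22)
        img = np.concatenate(
            [rng.normal(60, 8, 2000), rng.normal(190, 12, 1000)]
        ).clip(0, 255).astype(np.uint8).reshape(50, 60)
        # exact intermeans vs 256-bin IsoData differ by < 1 gray level
        assert abs(fg.isodata_threshold(img) - filters.threshold_isodata(img)) <= 1.0

    def test_constant_image_is_error(self):
        with pytest.raises(ThresholdError):
            fg.isodata_threshold(np.full((5, 5), 7.0))


def planted_scene(px=0.1):
    """Bright background, 5 in-window disks, one speck, one oversized blob."""
    img = np.full((200, 200), 200.0)
    in_window = [(30, 30), (30, 100), (100, 40), (120, 120), (170, 60)]
    for c in in_window:
        img[disk_mask(img.shape, c, 6.2)] = 60.0     # ~121 px ~ 1.21 um^2
    img[disk_mask(img.shape, (60, 170), 2.5)] = 60.0  # speck ~ 0.21 um^2
    img[disk_mask(img.shape, (160, 170), 14)] = 60.0  # blob ~ 6.2 um^2
    return img, in_window


class TestSegmentCells:
    def test_size_filter_keeps_only_planted_in_window_disks(self):
        img, in_window = planted_scene()
        labels = fg.segment_cells(img, pixel_size_um=0.1)
        assert labels.max() == len(in_window)

    def test_border_touching_cell_excluded(self):
        img, in_window = planted_scene()
        img[disk_mask(img.shape, (0, 80), 6.2)] = 60.0  # qualifies but on row 0
        labels = fg.segment_cells(img, pixel_size_um=0.1)
        assert labels.max() == len(in_window)
        assert not labels[0, :].any()

    def test_diagonal_touch_is_one_component_under_8_connectivity(self):
        img = np.full((7, 7), 200.0)
        img[2, 2] = img[3, 3] = 60.0  # touching only diagonally
        lab8 = fg.segment_cells(
            img, pixel_size_um=1.0, min_area_um2=0, max_area_um2=10,
            opening_iterations=0, connectivity=8,
        )
        lab4 = fg.segment_cells(
            img, pixel_size_um=1.0, min_area_um2=0, max_area_um2=10,
            opening_iterations=0, connectivity=4,
        )
        assert lab8.max() == 1 and lab4.max() == 2

    def test_opening_never_increases_foreground(self):
        rng = np.random.default_rng(23)
        img = rng.choice([60.0, 200.0], size=(80, 80), p=[0.3, 0.7])
        t = fg.isodata_threshold(img)
        raw = (img <= t).sum()
        opened = fg.segment_cells(
            img, pixel_size_um=1.0, min_area_um2=0, max_area_um2=1e9,
        )
        assert (opened > 0).sum() <= raw

    def test_labels_are_raster_scan_ordered(self):
        img, _ = planted_scene()
        labels = fg.segment_cells(img, pixel_size_um=0.1)
        firsts = [
            np.flatnonzero((labels == i).ravel())[0]
            for i in range(1, labels.max() + 1)
        ]
        assert firsts == sorted(firsts)

    def test_translation_equivariance_away_from_borders(self):
        img, _ = planted_scene()
        dy, dx = 7, -5
        shifted = np.roll(img, (dy, dx), axis=(0, 1))
        m0 = fg.measure_cells(
            fg.segment_cells(img, 0.1), img, 0.1, exposure_ms=400
        )
        m1 = fg.measure_cells(
            fg.segment_cells(shifted, 0.1), shifted, 0.1, exposure_ms=400
        )
        c0 = sorted((m.centroid[0] + dy, m.centroid[1] + dx) for m in m0)
        c1 = sorted(m.centroid for m in m1)
        np.testing.assert_allclose(c0, c1, atol=1e-9)

    def test_retained_count_monotone_as_window_narrows(self):
        img, _ = simulate_image_pair(n_cells=15, seed=3)
        img = img.phase
        wide = fg.segment_cells(img, 0.1, min_area_um2=0.5, max_area_um2=3.0)
        default = fg.segment_cells(img, 0.1)
        narrow = fg.segment_cells(img, 0.1, min_area_um2=1.0, max_area_um2=1.5)
        assert wide.max() >= default.max() >= narrow.max()


class TestMeasureCells:
    def test_flat_background_uniform_cell(self):
        fluo = np.full((50, 50), 100.0)
        labels = np.zeros((50, 50), dtype=int)
        cell = disk_mask((50, 50), (25, 25), 5)
        labels[cell] = 1
        fluo[cell] = 600.0
        (m,) = fg.measure_cells(labels, fluo, pixel_size_um=0.1, exposure_ms=400)
        assert m.mean_intensity_corrected == pytest.approx(500.0)
        assert m.area_um2 == pytest.approx(cell.sum() * 0.01)

    def test_exposure_normalization_cancels_exposure_scaling(self):
        base = np.full((40, 40), 100.0)
        labels = np.zeros((40, 40), dtype=int)
        cell = disk_mask((40, 40), (20, 20), 4)
        labels[cell] = 1
        base[cell] = 900.0
        m400 = fg.measure_cells(labels, base * (400 / 400), 0.1,
                                exposure_ms=400, reference_exposure_ms=400)
        m350 = fg.measure_cells(labels, base * (350 / 400), 0.1,
                                exposure_ms=350, reference_exposure_ms=400)
        assert m350[0].mean_intensity_corrected == pytest.approx(
            m400[0].mean_intensity_corrected
        )

    def test_mask_covering_image_is_background_error(self):
        labels = np.ones((10, 10), dtype=int)
        with pytest.raises(BackgroundError):
            fg.measure_cells(labels, np.ones((10, 10)), 0.1, exposure_ms=400)

    def test_recovers_planted_intensities_within_two_percent(self):
        image, truth = simulate_image_pair(n_cells=20, seed=9)
        labels = fg.segment_cells(image.phase, image.pixel_size_um)
        assert labels.max() == 20
        measured = fg.measure_cells(
            labels, image.fluorescence, image.pixel_size_um,
            exposure_ms=image.exposure_ms,
        )
        planted = truth.set_index("label")
        # match planted cells to measurements by nearest centroid
        for m in measured:
            d = np.hypot(
                planted["centroid_row"] - m.centroid[0],
                planted["centroid_col"] - m.centroid[1],
            )
            want = planted.loc[d.idxmin(), "mean_intensity"]
            assert m.mean_intensity_corrected == pytest.approx(want, rel=0.02)
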