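"""Segmentation chain: denoising, thresholding, morphology, watershed, records."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from colonynet.segmentation import (
    ColonyImage,
    DegenerateHistogramError,
    LabeledMask,
    SegmentationParams,
    binarize_otsu,
    denoise,
    extract_cells,
    filter_small_and_border,
    load_tiff,
    morphological_cleanup,
    segment_image,
    watershed_segment,
)


def as_image(arr, bit_depth=14):
    return ColonyImage(pixels=np.asarray(arr, dtype=np.uint16), bit_depth=bit_depth)


def disc_mask(shape, center, radius):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2


class TestDenoise:
    def test_constant_image_unchanged(self):
        img = as_image(np.full((64, 64), 500))
        out = denoise(img)
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_impulse_amplitude_reduced(self):
        base = np.full((64, 64), 100, dtype=np.uint16)
        base[32, 32] = 1100
        out = denoise(as_image(base))
        assert out.pixels[32, 32] < 1100
        assert out.pixels[32, 32] > 100  # shrunk toward, not past, the background

    def test_shrinkage_formula_direct_evaluation(self):
        """Independent evaluation of the local-mean/variance shrinkage rule
        (written out in full here) on an impulse image."""
        px = np.full((64, 64), 100, dtype=np.uint16)
        px[32, 32] = 1100
        x = px.astype(float)
        mu = ndi.uniform_filter(x, 3, mode="reflect")
        var = np.maximum(ndi.uniform_filter(x * x, 3, mode="reflect") - mu * mu, 0)
        noise = var.mean()
        gain = np.where(var > noise, (var - noise) / np.where(var > 0, var, 1), 0)
        expected = np.rint(mu + gain * (x - mu))
        out = denoise(as_image(px))
        np.testing.assert_allclose(out.pixels.astype(float), expected, atol=0)

    def test_output_within_input_range(self):
        rng = np.random.default_rng(0)
        px = rng.integers(100, 4000, size=(80, 80)).astype(np.uint16)
        out = denoise(as_image(px))
        assert out.pixels.min() >= px.min() and out.pixels.max() <= px.max()


class TestOtsu:
    def test_two_level_image_separates_exactly(self):
        px = np.full((64, 64), 200, dtype=np.uint16)
        px[10:30, 10:30] = 8000
        mask = binarize_otsu(as_image(px))
        np.testing.assert_array_equal(mask, px == 8000)

    def test_threshold_maximizes_between_class_variance(self):
        rng = np.random.default_rng(1)
        data = np.concatenate([rng.normal(300, 40, 2048), rng.normal(3000, 300, 2048)])
        data = np.clip(np.rint(data), 0, 16383)
        px = data.astype(np.uint16).reshape(64, 64)
        mask = binarize_otsu(as_image(px))
        thresh = float(data[~mask.ravel()].max())  # largest background value

        def between_var(t):
            lo, hi = data[data <= t], data[data > t]
            if len(lo) == 0 or len(hi) == 0:
                return -1.0
            w0, w1 = len(lo) / len(data), len(hi) / len(data)
            return w0 * w1 * (lo.mean() - hi.mean()) ** 2

        # brute-force scan over all candidate thresholds
        best = max(between_var(t) for t in np.unique(data))
        assert between_var(thresh) == pytest.approx(best, rel=1e-6)

    def test_constant_image_raises(self):
        with pytest.raises(DegenerateHistogramError):
            binarize_otsu(as_image(np.full((64, 64), 7)))


class TestMorphologicalCleanup:
    def test_isolated_pixel_removed(self):
        m = np.zeros((64, 64), bool)
        m[10, 10] = True
        assert not morphological_cleanup(m).any()

    def test_small_hole_filled(self):
        m = np.zeros((64, 64), bool)
        m[20:29, 20:29] = True
        m[24, 24] = False
        out = morphological_cleanup(m)
        assert out[24, 24]

    def test_large_square_unchanged_and_idempotent(self):
        m = np.zeros((64, 64), bool)
        m[20:40, 20:40] = True
        once = morphological_cleanup(m)
        np.testing.assert_array_equal(once, m)
        np.testing.assert_array_equal(morphological_cleanup(once), once)


class TestSizeAndBorderFilter:
    def test_seven_px_removed_eight_px_kept(self):
        m = np.zeros((64, 64), bool)
        m[5:12, 5] = True  # 7 px
        m[20:28, 20] = True  # 8 px
        out = filter_small_and_border(m)
        assert not out[5:12, 5].any()
        assert out[20:28, 20].all()

    def test_border_component_suppressed(self):
        m = np.zeros((64, 64), bool)
        m[0:10, 30:40] = True  # touches row 0
        m[30:40, 30:40] = True  # interior
        out = filter_small_and_border(m)
        assert not out[0:10, 30:40].any()
        assert out[30:40, 30:40].all()
        kept = filter_small_and_border(m, SegmentationParams(clear_border=False))
        assert kept[0:10, 30:40].all()

    def test_empty_mask_passthrough(self):
        m = np.zeros((64, 64), bool)
        assert not filter_small_and_border(m).any()


class TestWatershed:
    def test_disjoint_discs_two_regions(self):
        m = disc_mask((100, 100), (25, 50), 10) | disc_mask((100, 100), (65, 50), 10)
        lab = watershed_segment(m)
        assert lab.n_regions == 2

    def test_touching_discs_split_by_ridge(self):
        m = disc_mask((100, 100), (43, 50), 10) | disc_mask((100, 100), (57, 50), 10)
        assert ndi.label(m)[1] == 1  # genuinely merged input
        lab = watershed_segment(m)
        assert lab.n_regions == 2
        assert lab.labels[50, 43] != lab.labels[50, 57]
        assert lab.labels[50, 43] > 0 and lab.labels[50, 57] > 0

    def test_single_disc_one_region_any_depth(self):
        m = disc_mask((80, 80), (40, 40), 12)
        for h in (0.5, 2.0, 5.0):
            lab = watershed_segment(m, SegmentationParams(hmin_depth=h))
            assert lab.n_regions == 1

    def test_empty_mask_zero_regions(self):
        lab = watershed_segment(np.zeros((64, 64), bool))
        assert lab.n_regions == 0

    def test_label_partition_covers_foreground(self):
        m = disc_mask((100, 100), (30, 40), 9) | disc_mask((100, 100), (60, 60), 9)
        lab = watershed_segment(m)
        assert ((lab.labels > 0) == m).all()
        assert sorted(np.unique(lab.labels)) == [0, 1, 2]


class TestExtractCells:
    def test_empty_mask_gives_no_records(self):
        assert extract_cells(LabeledMask(np.zeros((64, 64), np.int32), 0)) == []

    def test_square_centroid_at_geometric_center(self):
        lab = np.zeros((64, 64), np.int32)
        lab[10:20, 30:40] = 1
        (rec,) = extract_cells(LabeledMask(lab, 1))
        assert rec.x == pytest.approx(34.5)
        assert rec.y == pytest.approx(14.5)
        assert rec.area == 100

    def test_recovery_on_well_separated_colony(self, well_separated_colony):
        img, truth, cfg = well_separated_colony
        _, cells = segment_image(ColonyImage(img))
        assert len(cells) == truth.n_cells
        errs = [
            np.hypot(truth.centers[:, 0] - c.x, truth.centers[:, 1] - c.y).min()
            for c in cells
        ]
        assert np.mean(errs) <= 2.0


class TestPipelineComposition:
    def test_deterministic_end_to_end(self, well_separated_colony):
        img, _, _ = well_separated_colony
        _, a = segment_image(ColonyImage(img))
        _, b = segment_image(ColonyImage(img))
        assert [(r.cell_id, r.x, r.y, r.area) for r in a] == \
               [(r.cell_id, r.x, r.y, r.area) for r in b]

    def test_noisy_count_within_five_percent(self):
        """With additive noise up to 5% of the contrast, the recovered count
        stays within 5% of truth (10 seeds)."""
        from colonynet.synthetic import ColonyConfig, render_colony, sample_centers_uniform, sample_shapes

        contrast = 8000 - 200
        for seed in range(10):
            cfg = ColonyConfig(field_width_px=500, field_height_px=500, n_cells=30,
                               nucleus_mean_radius_px=5, nucleus_axis_ratio=1.2,
                               noise_sigma=0.05 * contrast, seed=seed)
            inner = sample_centers_uniform(30, 460, 460, min_separation=30, seed=seed)
            shapes = sample_shapes(30, cfg, seed=seed + 1)
            img, truth = render_colony(inner + 20, shapes, cfg)
            _, cells = segment_image(ColonyImage(img))
            assert abs(len(cells) - 30) <= max(1, 0.05 * 30)


def test_load_tiff_rejects_multichannel(tmp_path):
    import tifffile

    rgb = np.zeros((64, 64, 3), dtype=np.uint16)
    tifffile.imwrite(tmp_path / "rgb.tif", rgb)
    with pytest.raises(ValueError, match="single-channel"):
        load_tiff(tmp_path / "rgb.tif")
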