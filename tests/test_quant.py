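"""IHC quantification: correction, filters, thresholds, counting, overlays."""

import numpy as np
import pytest

from spharray import (
    correct_background,
    crop_to_content,
    cytoplasmic_section,
    despeckle,
    make_qc_overlay,
    morpho_clean,
    quantify_cytoplasmic,
    quantify_cytoplasmic_image,
    quantify_nuclear,
    quantify_nuclear_image,
    random_nuclear_section,
    render_section,
    segment_nuclei,
    threshold_channel,
)
from spharray.errors import (
    CalibrationError,
    DegenerateBlankError,
    DegenerateThresholdError,
    NoNucleiError,
    NoTissueError,
)


def disk_mask(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


class TestCorrectBackground:
    def test_flat_field_is_identity(self):
        img = np.full((32, 32, 3), 180, dtype=np.uint8)
        blank = np.full((32, 32, 3), 250, dtype=np.uint8)
        np.testing.assert_array_equal(correct_background(img, blank), img)

    def test_recovers_flat_scene_under_known_gain(self):
        h, w = 64, 64
        xx = np.mgrid[0:h, 0:w][1]
        gain = (0.7 + 0.3 * xx / (w - 1))[..., None] * np.ones(3)  # lateral falloff
        img = np.clip(np.rint(160.0 * gain), 0, 255).astype(np.uint8)
        blank = np.clip(np.rint(250.0 * gain), 0, 255).astype(np.uint8)
        out = correct_background(img, blank, smooth_sigma=0)
        expected = 160.0 * np.median(250.0 * gain) / 250.0  # blank -> its median
        assert np.abs(out.astype(float) - expected).max() <= 1.0001

    def test_self_estimated_gain_flattens_smooth_illumination(self):
        h, w = 96, 96
        xx = np.mgrid[0:h, 0:w][1]
        gain = 0.6 + 0.4 * xx / (w - 1)
        img = np.clip(np.rint(200.0 * gain[..., None] * np.ones((h, w, 3))),
                      0, 255).astype(np.uint8)
        out = correct_background(img).astype(float)
        assert out.std() < img.astype(float).std() / 3

    def test_zero_blank_rejected(self):
        img = np.full((16, 16, 3), 100, dtype=np.uint8)
        blank = np.zeros((16, 16, 3), dtype=np.uint8)
        with pytest.raises(DegenerateBlankError):
            correct_background(img, blank, smooth_sigma=0)


class TestCropToContent:
    def test_single_disk_bounding_box(self):
        img = np.full((80, 100, 3), 255, dtype=np.uint8)
        d = disk_mask((80, 100), (40, 60), 12)
        img[d] = 40
        rect = crop_to_content([img])
        rows = np.flatnonzero(d.any(axis=1))
        cols = np.flatnonzero(d.any(axis=0))
        assert (rect.top, rect.bottom) == (rows[0], rows[-1] + 1)
        assert (rect.left, rect.right) == (cols[0], cols[-1] + 1)
        assert not rect.degenerate

    def test_all_white_stack_full_frame_with_warning(self):
        img = np.full((20, 30, 3), 255, dtype=np.uint8)
        rect = crop_to_content([img, img])
        assert (rect.top, rect.bottom, rect.left, rect.right) == (0, 20, 0, 30)
        assert rect.degenerate

    def test_disks_in_opposite_corners_span_both(self):
        a = np.full((100, 100, 3), 255, dtype=np.uint8)
        b = a.copy()
        da = disk_mask((100, 100), (15, 15), 8)
        db = disk_mask((100, 100), (85, 85), 8)
        a[da] = 30
        b[db] = 30
        rect = crop_to_content([a, b])
        both = da | db
        rows = np.flatnonzero(both.any(axis=1))
        cols = np.flatnonzero(both.any(axis=0))
        assert (rect.top, rect.bottom) == (rows[0], rows[-1] + 1)
        assert (rect.left, rect.right) == (cols[0], cols[-1] + 1)


class TestFilters:
    def test_despeckle_removes_isolated_pixel(self):
        m = np.zeros((9, 9), dtype=bool)
        m[4, 4] = True
        assert not despeckle(m).any()

    def test_despeckle_constant_unchanged(self):
        m = np.full((7, 7), 3, dtype=np.uint8)
        np.testing.assert_array_equal(despeckle(m), m)

    def test_despeckle_matches_direct_median_on_square(self):
        from scipy.ndimage import median_filter as ref

        m = np.zeros((11, 11), dtype=np.uint8)
        m[3:8, 3:8] = 1
        np.testing.assert_array_equal(despeckle(m), ref(m, size=3))

    def test_opening_removes_small_speck(self):
        m = np.zeros((12, 12), dtype=bool)
        m[5:7, 5:7] = True
        assert not morpho_clean(m, radius=2).any()

    def test_opening_preserves_large_square_and_shrinks_area(self):
        m = np.zeros((30, 30), dtype=bool)
        m[5:25, 5:25] = True
        out = morpho_clean(m, radius=2)
        assert out[10:20, 10:20].all()          # interior intact
        assert out.sum() <= m.sum()             # opening never grows

    def test_opening_area_never_grows_random_masks(self, rng):
        for _ in range(10):
            m = rng.random((24, 24)) < 0.4
            assert morpho_clean(m, radius=2).sum() <= m.sum()

    def test_opening_empty_mask(self):
        m = np.zeros((8, 8), dtype=bool)
        assert not morpho_clean(m).any()


def intermeans_oracle(values, n_iter=500):
    """Exhaustive iterative-intermeans fixed point on the raw values."""
    t = values.mean()
    for _ in range(n_iter):
        lo, hi = values[values <= t], values[values > t]
        t_new = (lo.mean() + hi.mean()) / 2
        if abs(t_new - t) < 1e-12:
            break
        t = t_new
    return t


class TestThresholdChannel:
    def test_isodata_separates_bimodal_modes(self, rng):
        low = rng.normal(0.1, 0.02, 3000)
        high = rng.normal(1.0, 0.05, 3000)
        data = np.concatenate([low, high]).reshape(60, 100)
        mask, thr = threshold_channel(data, method="isodata")
        assert 0.2 < thr < 0.9                   # strictly between the modes
        assert abs(thr - intermeans_oracle(data.ravel())) < 0.05
        # mask covers the high mode's pixels
        assert mask.ravel()[3000:].all()
        assert not mask.ravel()[:3000].any()

    def test_fixed_threshold_exact_coverage(self):
        m = np.zeros((10, 10))
        m[:5] = 0.5
        mask, thr = threshold_channel(m, method="fixed", value=0.3)
        assert thr == 0.3
        assert mask.sum() == 50 and mask[:5].all()

    def test_constant_map_rejected_for_automatic(self):
        with pytest.raises(DegenerateThresholdError):
            threshold_channel(np.full((5, 5), 0.7), method="isodata")


class TestQuantifyCytoplasmic:
    def test_ratio_arithmetic(self):
        tissue = np.zeros((20, 20), dtype=bool)
        tissue.ravel()[:200] = True
        dab = np.zeros_like(tissue)
        dab.ravel()[:25] = True
        res = quantify_cytoplasmic(tissue, dab)
        assert res.tissue_area_px == 200 and res.dab_area_px == 25
        assert res.percent_positive == 12.5

    def test_empty_dab_zero_percent_and_full_dab_hundred(self):
        tissue = disk_mask((40, 40), (20, 20), 10)
        assert quantify_cytoplasmic(tissue, np.zeros_like(tissue)).percent_positive == 0.0
        assert quantify_cytoplasmic(tissue, tissue).percent_positive == 100.0

    def test_dab_outside_tissue_is_clipped(self):
        tissue = np.zeros((10, 10), dtype=bool)
        tissue[:5] = True
        dab = np.ones((10, 10), dtype=bool)
        assert quantify_cytoplasmic(tissue, dab).percent_positive == 100.0

    def test_empty_tissue_rejected(self):
        with pytest.raises(NoTissueError):
            quantify_cytoplasmic(np.zeros((5, 5), dtype=bool),
                                 np.zeros((5, 5), dtype=bool))


class TestSegmentNuclei:
    def test_single_disk_counted_once(self):
        m = disk_mask((40, 40), (20, 20), 8)
        assert segment_nuclei(m, min_area_px=50).count == 1

    def test_touching_dumbbell_split_in_two(self):
        m = disk_mask((48, 48), (24, 16), 8) | disk_mask((48, 48), (24, 32), 8)
        assert segment_nuclei(m, min_area_px=50).count == 2

    def test_min_area_filter_drops_small_disk(self):
        # radius-5 disk: 81 px raw, ~69 px after the cleaning filters
        m = disk_mask((40, 40), (20, 20), 5)
        assert segment_nuclei(m, min_area_px=200).count == 0
        # physical units at 0.5 um/px: 69 px ~= 17 um^2
        assert segment_nuclei(m, min_area=20.0, pixel_size=0.5).count == 0
        assert segment_nuclei(m, min_area=10.0, pixel_size=0.5).count == 1

    def test_um_min_area_requires_pixel_size(self):
        with pytest.raises(CalibrationError):
            segment_nuclei(np.zeros((5, 5), dtype=bool), min_area=20.0)


class TestQuantifyNuclear:
    def test_empty_dab_and_identical_masks(self):
        h = np.zeros((120, 120), dtype=bool)
        for i in range(3):
            for j in range(3):
                h |= disk_mask(h.shape, (20 + 40 * i, 20 + 40 * j), 7)
        empty = np.zeros_like(h)
        assert quantify_nuclear(h, empty, min_area_px=30).percent_positive == 0.0
        assert quantify_nuclear(h, h, min_area_px=30).percent_positive == 100.0

    def test_rendered_section_recovers_planted_fraction(self):
        spec = random_nuclear_section(20, 13, shape=(360, 360), seed=11)
        img, truth = render_section(spec)
        res, _, _ = quantify_nuclear_image(img, min_area_px=30)
        assert res.n_nuclei_h == 20 and res.n_nuclei_dab == 13
        assert res.percent_positive == pytest.approx(65.0)

    def test_strict_ratio_mode_uncapped(self):
        h = disk_mask((60, 60), (20, 20), 7)
        dab = h | disk_mask((60, 60), (42, 42), 7)
        strict = quantify_nuclear(h, dab, min_area_px=30, mode="strict")
        assert strict.percent_positive == 200.0
        capped = quantify_nuclear(h, dab, min_area_px=30, mode="union")
        assert capped.percent_positive == 100.0

    def test_no_nuclei_rejected(self):
        z = np.zeros((30, 30), dtype=bool)
        with pytest.raises(NoNucleiError):
            quantify_nuclear(z, z, min_area_px=30)


class TestQcOverlay:
    def test_empty_masks_leave_image_unchanged(self):
        img = np.full((10, 10, 3), 128, dtype=np.uint8)
        empty = np.zeros((10, 10), dtype=bool)
        np.testing.assert_array_equal(make_qc_overlay(img, empty, empty), img)

    def test_square_mask_outer_perimeter_count(self):
        img = np.full((20, 20, 3), 255, dtype=np.uint8)
        tissue = np.zeros((20, 20), dtype=bool)
        tissue[5:10, 5:10] = True                # 5x5 square
        out = make_qc_overlay(img, tissue, np.zeros_like(tissue))
        green = np.all(out == (0, 255, 0), axis=-1)
        # 8-connected outer ring of an n x n square has (n+2)^2 - n^2 pixels
        assert green.sum() == 7 * 7 - 5 * 5
        assert not green[tissue].any()           # contour lies outside the mask

    def test_positive_contour_drawn_on_top(self):
        img = np.full((12, 12, 3), 255, dtype=np.uint8)
        tissue = np.zeros((12, 12), dtype=bool)
        tissue[4:8, 4:8] = True
        out = make_qc_overlay(img, tissue, tissue)  # contours coincide
        magenta = np.all(out == (255, 0, 255), axis=-1)
        green = np.all(out == (0, 255, 0), axis=-1)
        assert magenta.sum() > 0 and green.sum() == 0


class TestEndToEndCytoplasmic:
    @pytest.mark.parametrize("fraction", [0.0, 0.05, 0.25, 0.5, 1.0])
    def test_positive_fraction_recovered(self, fraction):
        spec = cytoplasmic_section(fraction, noise_sigma=3.0,
                                   gain_amplitude=0.05, seed=21)
        img, truth = render_section(spec)
        res, _, _ = quantify_cytoplasmic_image(img)
        assert res.percent_positive == pytest.approx(
            100.0 * truth["positive_fraction"], abs=2.0
        )

    def test_raising_dab_threshold_never_increases_percent(self):
        spec = cytoplasmic_section(0.4, noise_sigma=2.0, seed=5)
        img, _ = render_section(spec)
        percents = [
            quantify_cytoplasmic_image(
                img, dab_threshold_mode="fixed", dab_threshold_value=v
            )[0].percent_positive
            for v in np.linspace(0.1, 0.9, 9)
        ]
        assert all(a >= b for a, b in zip(percents, percents[1:]))

    def test_percent_invariant_to_translation_and_rotation(self):
        spec = cytoplasmic_section(0.3, seed=9)
        img, _ = render_section(spec)
        base = quantify_cytoplasmic_image(img)[0].percent_positive
        rotated = quantify_cytoplasmic_image(np.rot90(img))[0].percent_positive
        padded = np.pad(img, ((13, 0), (7, 0), (0, 0)), constant_values=255)
        translated = quantify_cytoplasmic_image(padded)[0].percent_positive
        assert rotated == pytest.approx(base, abs=1e-9)
        assert translated == pytest.approx(base, abs=0.2)
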