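import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from stalkscan.io import Calibration, ScanImage
from stalkscan.preprocess import (
    CropBox,
    DegenerateImageError,
    extract_objects,
    filter_objects,
    measure_morphology,
    morphometry_px,
    otsu_threshold,
    region_eccentricity,
    segment_foreground,
    to_grayscale,
)

from conftest import disc_mask


def brute_force_otsu(gray):
    """Independent oracle: exhaustive scan of between-class variance."""
    vals = np.round(np.asarray(gray, float).ravel()).astype(int)
    best_t, best_var = None, -1.0
    for t in range(vals.min(), vals.max()):
        bg = vals[vals <= t]
        fg = vals[vals > t]
        if bg.size == 0 or fg.size == 0:
            continue
        w0, w1 = bg.size, fg.size
        var = w0 * w1 * (bg.mean() - fg.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


class TestGrayscale:
    def test_luminance_weights(self):
        px = np.zeros((1, 3, 3), dtype=np.uint8)
        px[0, 0] = (255, 255, 255)
        px[0, 1] = (0, 255, 0)
        px[0, 2] = (0, 0, 0)
        gray = to_grayscale(ScanImage(pixels=px, dpi=800))
        assert gray[0, 0] == pytest.approx(255.0)
        assert gray[0, 1] == pytest.approx(0.587 * 255)
        assert gray[0, 2] == 0.0


class TestOtsu:
    def test_bimodal_split(self):
        img = np.array([10] * 50 + [200] * 50)
        t = otsu_threshold(img)
        assert 10 <= t < 200

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            img = rng.integers(0, 256, size=(24, 24)).astype(np.uint8)
            assert otsu_threshold(img) == brute_force_otsu(img)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_oracle_property_bimodal_mixtures(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(60, 15, size=300)
        b = rng.normal(180, 20, size=200)
        img = np.clip(np.concatenate([a, b]), 0, 255)
        assert otsu_threshold(img) == brute_force_otsu(img)

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateImageError):
            otsu_threshold(np.full((10, 10), 42))


class TestSegmentForeground:
    def test_disc_on_dark_background_is_solid(self):
        img = np.where(disc_mask((100, 100), (50, 50), 30), 200.0, 10.0)
        mask = segment_foreground(img)
        assert np.array_equal(mask, disc_mask((100, 100), (50, 50), 30))

    def test_interior_specks_filled(self):
        img = np.where(disc_mask((100, 100), (50, 50), 30), 200.0, 10.0)
        img[48:53, 48:53] = 5.0  # dark hole inside the disc
        mask = segment_foreground(img)
        assert mask[50, 50]  # hole filled
        assert not mask[5, 5]

    def test_component_count_matches_labeling_oracle(self):
        img = np.full((400, 600), 10.0)
        for k in range(4):  # discs
            img[disc_mask(img.shape, (100 + 60 * k, 60 + 80 * k), 40)] = 200.0
        for k in range(10):  # small separated scratches
            r = 30 + 35 * k
            img[r, 450:458] = 180.0
        mask = segment_foreground(img)
        _, n = ndimage.label(mask, structure=np.ones((3, 3), bool))
        assert n == 14


class TestFilterObjects:
    def _mask_with_area(self, area):
        # 100-row rectangle plus a partial last column: exact pixel count
        mask = np.zeros((120, 200), bool)
        full_cols, rem = divmod(area, 100)
        mask[10:110, 10 : 10 + full_cols] = True
        if rem:
            mask[10 : 10 + rem, 10 + full_cols] = True
        assert mask.sum() == area
        return mask

    def test_min_area_boundary(self):
        assert not filter_objects(self._mask_with_area(14_999)).any()
        kept = filter_objects(self._mask_with_area(15_000))
        assert kept.sum() == 15_000

    def test_high_eccentricity_bar_removed(self):
        mask = np.zeros((20, 5100), bool)
        mask[8:12, 50:5050] = True  # 4 x 5000 = 20000 px thin bar
        assert region_eccentricity(mask) > 0.99
        assert not filter_objects(mask).any()

    def test_filled_circle_kept(self):
        mask = disc_mask((300, 300), (150, 150), 100)  # area ~31416
        out = filter_objects(mask)
        assert np.array_equal(out, mask)
        assert region_eccentricity(mask) < 0.1

    def test_one_pixel_line_eccentricity(self):
        mask = np.zeros((100, 100), bool)
        mask[50, 10:90] = True
        assert region_eccentricity(mask) > 0.99

    def test_idempotent(self, realistic_scan):
        scan, _ = realistic_scan
        mask = segment_foreground(to_grayscale(scan))
        once = filter_objects(mask)
        twice = filter_objects(once)
        assert np.array_equal(once, twice)


class TestExtractObjects:
    def test_tight_bounding_box(self):
        mask = disc_mask((200, 200), (100, 100), 40)
        objs = extract_objects(np.zeros((200, 200, 3), np.uint8), mask)
        assert len(objs) == 1
        box = objs[0].box
        assert (box.top, box.left, box.bottom, box.right) == (60, 60, 141, 141)
        assert objs[0].area_px == mask.sum()

    def test_override_box_halves_disc(self):
        mask = disc_mask((200, 200), (100, 100), 40)
        override = CropBox(top=60, left=60, bottom=141, right=101)  # left half
        objs = extract_objects(np.zeros((200, 200, 3), np.uint8), mask, [override])
        expected = mask[:, 60:101].sum()
        assert objs[0].area_px == expected
        assert objs[0].area_px < mask.sum()

    def test_override_without_intersection_rejected(self):
        mask = disc_mask((200, 200), (100, 100), 30)
        override = CropBox(top=0, left=0, bottom=20, right=20)
        with pytest.raises(ValueError):
            extract_objects(np.zeros((200, 200, 3), np.uint8), mask, [override])

    def test_row_major_centroid_order(self):
        mask = np.zeros((300, 300), bool)
        centers = [(60, 200), (60, 60), (220, 60), (220, 200)]
        for c in centers:
            mask |= disc_mask(mask.shape, c, 25)
        objs = extract_objects(np.zeros((300, 300, 3), np.uint8), mask)
        got = [(round(o.centroid[0]), round(o.centroid[1])) for o in objs]
        assert got == [(60, 60), (60, 200), (220, 60), (220, 200)]


class TestMorphometry:
    def test_circle_diameter_and_area(self):
        cal = Calibration(px_per_cm=315.0)
        mask = disc_mask((700, 700), (350, 350), 315)
        objs = extract_objects(np.zeros((700, 700, 3), np.uint8), mask)
        area, diam, perim = measure_morphology(objs[0], cal)
        assert diam == pytest.approx(2.0, rel=0.02)
        assert area == pytest.approx(np.pi, rel=0.02)
        assert perim == pytest.approx(2 * np.pi, rel=0.02)

    def test_square_area_exact(self):
        cal = Calibration(px_per_cm=315.0)
        mask = np.zeros((400, 400), bool)
        mask[10:325, 20:335] = True
        objs = extract_objects(np.zeros((400, 400, 3), np.uint8), mask)
        area, _, _ = measure_morphology(objs[0], cal)
        assert area == 315 * 315 / 315.0**2  # exactly 1 cm^2

    def test_ellipse_perimeter_vs_ramanujan(self):
        a, b = 400, 200  # semi-axes
        yy, xx = np.mgrid[0:900, 0:1700]
        mask = ((yy - 450) / b) ** 2 + ((xx - 850) / a) ** 2 <= 1
        _, _, perim, _ = morphometry_px(mask)
        h = ((a - b) / (a + b)) ** 2
        ramanujan = np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))
        assert perim == pytest.approx(ramanujan, rel=0.03)

    def test_pixel_area_conversion_is_exact(self):
        cal = Calibration(px_per_cm=123.456)
        mask = disc_mask((200, 200), (100, 100), 55)
        objs = extract_objects(np.zeros((200, 200, 3), np.uint8), mask)
        area_cm2, _, _ = measure_morphology(objs[0], cal)
        assert area_cm2 * cal.px_per_cm**2 == pytest.approx(objs[0].area_px, abs=1e-9)
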