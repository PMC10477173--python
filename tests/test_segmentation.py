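import numpy as np
import pytest
from scipy.ndimage import maximum_filter, minimum_filter

from meningiodet import (
    BrainImage,
    PhantomSpec,
    StructuringElement,
    ValidationError,
    average_pdf,
    difference_image,
    extract_mask,
    generate_phantom,
    intensity_pdf,
    morph_close,
    morph_open,
    probable_images,
    segment,
)


def _img(arr):
    return BrainImage(np.asarray(arr, dtype=np.uint8))


SE = StructuringElement(radius=2)
FOOT = SE.footprint


def open_oracle(grid):
    """erode-then-dilate from primitive min/max filters."""
    return maximum_filter(minimum_filter(grid, footprint=FOOT), footprint=FOOT)


def close_oracle(grid):
    return minimum_filter(maximum_filter(grid, footprint=FOOT), footprint=FOOT)


class TestMorphology:
    def test_constant_images_are_fixed_points(self):
        img = _img(np.full((16, 16), 77))
        assert (morph_open(img, SE) == 77).all()
        assert (morph_close(img, SE) == 77).all()

    def test_opening_removes_single_bright_pixel(self):
        px = np.zeros((15, 15))
        px[7, 7] = 200
        assert (morph_open(_img(px), SE) == 0).all()

    def test_closing_fills_single_dark_pixel(self):
        px = np.full((15, 15), 200.0)
        px[7, 7] = 0
        assert (morph_close(_img(px), SE) == 200).all()

    def test_matches_primitive_filter_oracles_exactly(self, rng):
        for _ in range(5):
            grid = rng.integers(0, 256, size=(20, 20)).astype(float)
            assert (morph_open(grid, SE) == open_oracle(grid)).all()
            assert (morph_close(grid, SE) == close_oracle(grid)).all()

    def test_idempotence_and_extensivity(self, rng):
        grid = rng.integers(0, 256, size=(24, 24)).astype(float)
        opened, closed = morph_open(grid, SE), morph_close(grid, SE)
        assert (opened <= grid).all() and (closed >= grid).all()
        assert (morph_open(opened, SE) == opened).all()
        assert (morph_close(closed, SE) == closed).all()

    def test_commutes_with_constant_shift(self, rng):
        grid = rng.integers(0, 200, size=(18, 18)).astype(float)
        k = 31.0
        assert np.allclose(morph_open(grid + k, SE), morph_open(grid, SE) + k)
        assert np.allclose(morph_close(grid + k, SE), morph_close(grid, SE) + k)


class TestIntensityPDF:
    def test_constant_image(self):
        pdf = intensity_pdf(np.full((8, 8), 42.0))
        assert pdf.bins[42] == 1.0 and pdf.bins.sum() == 1.0
        assert (pdf.pixel_map == 1.0).all()

    def test_half_and_half(self):
        grid = np.zeros((4, 4))
        grid[:2] = 255
        pdf = intensity_pdf(grid)
        assert (pdf.pixel_map == 0.5).all()

    def test_matches_counting_oracle(self, rng):
        grid = rng.integers(0, 256, size=(13, 9)).astype(float)
        pdf = intensity_pdf(grid)
        counts = np.bincount(grid.astype(int).ravel(), minlength=256)
        assert np.array_equal(pdf.bins, counts / grid.size)
        assert pdf.bins.sum() == pytest.approx(1.0, abs=1e-12)
        assert (pdf.pixel_map > 0).all()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError):
            intensity_pdf(np.zeros((0, 4)))


class TestProbabilitySteps:
    def test_average_of_identical_pdfs(self, rng):
        grid = rng.integers(0, 256, size=(9, 9)).astype(float)
        pdf = intensity_pdf(grid)
        assert np.array_equal(average_pdf(pdf, pdf), pdf.pixel_map)

    def test_average_arithmetic(self, rng):
        g1 = rng.integers(0, 256, size=(7, 7)).astype(float)
        g2 = rng.integers(0, 256, size=(7, 7)).astype(float)
        p1, p2 = intensity_pdf(g1), intensity_pdf(g2)
        want = 0.5 * (p1.pixel_map + p2.pixel_map)
        assert np.allclose(average_pdf(p1, p2), want, atol=1e-15)

    def test_probable_images_unit_denominator(self):
        M = np.full((6, 6), 50.0)
        A_t = np.ones((6, 6))
        P_open, P_close = probable_images(M, M, A_t)
        assert np.array_equal(P_open, M) and np.array_equal(P_close, M)

    def test_probable_images_elementwise_oracle(self, rng):
        M_o = rng.random((5, 5)) * 100
        M_c = rng.random((5, 5)) * 100
        A_t = rng.random((5, 5)) * 0.1 + 0.01
        P_open, P_close = probable_images(M_o, M_c, A_t)
        assert np.allclose(P_open, M_o / A_t, rtol=1e-12)
        assert np.allclose(P_close, M_c / A_t, rtol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            probable_images(np.zeros((3, 3)), np.zeros((3, 3)), np.zeros((4, 4)))
        with pytest.raises(ValidationError):
            difference_image(np.zeros((3, 3)), np.zeros((2, 2)))

    def test_difference_of_equal_probables_is_zero(self, rng):
        P = rng.random((6, 6))
        assert (difference_image(P, P) == 0).all()
        assert (difference_image(P, P * 0.5) >= 0).all()


class TestExtractMask:
    def test_all_zero_yields_empty_mask(self):
        assert extract_mask(np.zeros((10, 10))).area == 0

    def test_two_level_disk_recovered_exactly(self):
        rr, cc = np.mgrid[:64, :64]
        disk = (rr - 30) ** 2 + (cc - 33) ** 2 <= 100
        M_diff = np.where(disk, 5.0, 0.0)
        mask = extract_mask(M_diff, min_area=30)
        assert (mask.mask == disk).all()

    def test_negative_input_rejected(self):
        with pytest.raises(ValidationError):
            extract_mask(np.full((4, 4), -1.0))


class TestSegmentPipeline:
    def test_constant_image_gives_empty_mask(self):
        assert segment(_img(np.full((32, 32), 128))).area == 0

    def test_tumor_region_responds_above_background(self):
        ph = generate_phantom(PhantomSpec(seed=21), with_tumor=True)
        M_o = morph_open(ph.image)
        M_c = morph_close(ph.image)
        A_t = average_pdf(intensity_pdf(M_o), intensity_pdf(M_c))
        P_open, P_close = probable_images(M_o, M_c, A_t)
        M_diff = difference_image(P_open, P_close)
        inside = M_diff[ph.mask.mask].mean()
        outside = M_diff[~ph.mask.mask].mean()
        assert inside > outside

    def test_phantom_tumor_recovered(self):
        ph = generate_phantom(PhantomSpec(seed=21), with_tumor=True)
        mask = segment(ph.image)
        inter = (mask.mask & ph.mask.mask).sum()
        dice = 2 * inter / (mask.area + ph.mask.area)
        assert dice > 0.8

    def test_rerun_is_bitwise_identical_and_pure(self):
        ph = generate_phantom(PhantomSpec(seed=33), with_tumor=True)
        m1 = segment(ph.image)
        renamed = BrainImage(ph.image.pixels, source_id="other-name")
        m2 = segment(renamed)
        assert (m1.mask == m2.mask).all()
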