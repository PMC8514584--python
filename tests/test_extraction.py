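"""Tiling, grayscale conversion and Otsu thresholding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from admil_cyto import (ExtractionConfig, SpecimenImage, candidate_grid,
                        extract_instances, otsu_threshold, to_grayscale)


def brute_force_otsu(gray):
    """Independent oracle: scan all 256 thresholds, maximise between-class
    variance of the split {<t, >=t}; lowest level on ties; None if no split."""
    pixels = gray.ravel().astype(float)
    n = pixels.size
    best_t, best_v = None, 0.0
    for t in range(256):
        lo = pixels[pixels < t]
        hi = pixels[pixels >= t]
        if lo.size == 0 or hi.size == 0:
            continue
        v = (lo.size / n) * (hi.size / n) * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_t, best_v = t, v
    return best_t


def _image(pixels, image_id="img0", label="benign"):
    return SpecimenImage(image_id=image_id, case_id="c0", label=label,
                         pixels=np.asarray(pixels, dtype=np.uint8))


class TestGrayscale:
    @pytest.mark.parametrize("rgb,expected", [
        ((128, 128, 128), 128),   # gray fixed point
        ((255, 0, 0), 76),        # 0.299 * 255 = 76.245
        ((255, 255, 255), 255),   # weights sum to 1
    ])
    def test_luminance_values(self, rgb, expected):
        img = np.full((4, 4, 3), rgb, dtype=np.uint8)
        assert int(to_grayscale(img)[0, 0]) == expected

    def test_rejects_non_rgb(self):
        with pytest.raises(ValueError):
            to_grayscale(np.zeros((4, 4), dtype=np.uint8))


class TestOtsu:
    def test_bimodal_image_separates_the_modes(self):
        gray = np.array([20] * 50 + [200] * 50, dtype=np.uint8).reshape(10, 10)
        t = otsu_threshold(gray)
        assert t == brute_force_otsu(gray)
        assert ((gray < t) == (gray == 20)).all()

    def test_constant_image_has_no_foreground(self):
        assert otsu_threshold(np.full((5, 5), 128, dtype=np.uint8)) is None

    def test_two_pixel_image(self):
        gray = np.array([[0, 255]], dtype=np.uint8)
        t = otsu_threshold(gray)
        assert t == brute_force_otsu(gray)
        assert (gray < t).sum() == 1 and gray[gray < t][0] == 0

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_brute_force_on_random_images(self, seed):
        rng = np.random.default_rng(seed)
        gray = rng.integers(0, 256, size=(12, 12)).astype(np.uint8)
        assert otsu_threshold(gray) == brute_force_otsu(gray)

    def test_agrees_with_skimage_partition(self):
        from skimage.filters import threshold_otsu
        rng = np.random.default_rng(5)
        for _ in range(20):
            gray = np.concatenate([rng.integers(0, 90, 80),
                                   rng.integers(150, 256, 60)]).astype(np.uint8)
            gray = gray.reshape(10, 14)
            ours = otsu_threshold(gray)
            sk = threshold_otsu(gray)
            # same foreground/background partition (conventions differ by <=/<)
            assert ((gray < ours) == (gray <= sk)).all()


class TestExtraction:
    @pytest.mark.parametrize("size,expected", [(64, (15, 20)), (96, (10, 13)),
                                               (128, (7, 10))])
    def test_candidate_grid_at_native_geometry(self, size, expected):
        assert candidate_grid(1280, 960, size) == expected

    def test_all_background_image_yields_nothing(self):
        img = _image(np.full((192, 256, 3), 230, dtype=np.uint8))
        assert extract_instances(img, ExtractionConfig()) == []

    def test_single_dark_blob_retains_exactly_its_tile(self):
        """A 40x40 blob centered in tile (1,1): 1600/4096 > 10% there, 0 elsewhere."""
        px = np.full((192, 256, 3), 230, dtype=np.uint8)
        px[76:116, 76:116] = 30  # centered in the 64-px tile at row 1, col 1
        inst = extract_instances(_image(px), ExtractionConfig())
        assert [(i.grid_row, i.grid_col) for i in inst] == [(1, 1)]
        assert inst[0].foreground_fraction == pytest.approx(1600 / 4096)
        assert (inst[0].origin_x, inst[0].origin_y) == (64, 64)

    def test_undersized_image_returns_empty_with_warning(self, caplog):
        img = _image(np.zeros((32, 32, 3), dtype=np.uint8))
        with caplog.at_level("WARNING"):
            assert extract_instances(img, ExtractionConfig()) == []
        assert "smaller than patch size" in caplog.text

    def test_instances_are_row_major_and_grid_aligned(self, tiny_dataset):
        img = tiny_dataset.images[0]
        inst = extract_instances(img, ExtractionConfig())
        coords = [(i.grid_row, i.grid_col) for i in inst]
        assert coords == sorted(coords)
        for i in inst:
            assert i.origin_x == i.grid_col * 64 and i.origin_y == i.grid_row * 64
            assert i.pixels.shape == (64, 64, 3)
            assert 0.0 <= i.foreground_fraction <= 1.0

    def test_retention_is_monotone_in_min_cell_fraction(self, tiny_dataset):
        img = tiny_dataset.images[0]
        counts = [len(extract_instances(img, ExtractionConfig(min_cell_fraction=f)))
                  for f in (0.0, 0.05, 0.10, 0.2, 0.4, 0.8)]
        assert counts == sorted(counts, reverse=True)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ExtractionConfig(patch_size=0)
        with pytest.raises(ValueError):
            ExtractionConfig(min_cell_fraction=1.0)
        with pytest.raises(ValueError):
            ExtractionConfig(edge_policy="pad")
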