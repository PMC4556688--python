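"""Binarization, opening and component filtering against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from conftest import rasterize_disk
from fibrilquant.pipeline import RunConfig, segment_micrograph
from fibrilquant.segmentation import (
    BinaryMask,
    Micrograph,
    adaptive_binarize,
    filter_by_area,
    filter_by_eccentricity,
    label_components,
    morphological_open,
)
from fibrilquant.synthetic import render_micrograph


def local_mean_threshold_oracle(img, block, offset):
    """O(N^2 B^2) per-pixel local-mean thresholding with reflective padding."""
    pad = block // 2
    padded = np.pad(img, pad, mode="symmetric")
    out = np.zeros(img.shape, dtype=bool)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = img[i, j] - padded[i : i + block, j : j + block].mean() > offset
    return out


def moments_eccentricity_oracle(mask):
    """Eccentricity of the ellipse of inertia, from raw second central moments."""
    rows, cols = np.nonzero(mask)
    r, c = rows - rows.mean(), cols - cols.mean()
    # covariance of pixel centers (point-mass convention, as regionprops uses)
    mrr = np.mean(r * r)
    mcc = np.mean(c * c)
    mrc = np.mean(r * c)
    common = np.sqrt((mrr - mcc) ** 2 + 4 * mrc**2)
    lam1 = (mrr + mcc + common) / 2.0
    lam2 = (mrr + mcc - common) / 2.0
    return np.sqrt(1.0 - lam2 / lam1)


class TestAdaptiveBinarize:
    def test_constant_image_has_empty_foreground(self):
        mask = adaptive_binarize(np.full((40, 40), 0.3), block_size_px=9, offset=0.01)
        assert not mask.pixels.any()

    @pytest.mark.parametrize("block", [3, 5, 9])
    def test_matches_bruteforce_on_random_images(self, block):
        rng = np.random.default_rng(7)
        for shape in [(10, 10), (32, 32)]:
            img = rng.uniform(0, 1, shape)
            mask = adaptive_binarize(img, block_size_px=block, offset=0.01)
            oracle = local_mean_threshold_oracle(img, block, 0.01)
            np.testing.assert_array_equal(mask.pixels, oracle)

    def test_bright_disk_interior_is_foreground(self):
        img = np.where(rasterize_disk((32, 32), (16, 16), 8.0), 0.8, 0.2)
        mask = adaptive_binarize(img, block_size_px=31, offset=0.0)
        interior = rasterize_disk((32, 32), (16, 16), 6.5)
        assert np.all(mask.pixels[interior])
        np.testing.assert_array_equal(
            mask.pixels, local_mean_threshold_oracle(img, 31, 0.0)
        )

    def test_dark_objects_polarity_mirrors_inverted_image(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 1, (24, 24))
        bright = adaptive_binarize(img, 7, 0.05, polarity="bright_objects")
        dark = adaptive_binarize(1.0 - img, 7, 0.05, polarity="dark_objects")
        np.testing.assert_array_equal(bright.pixels, dark.pixels)

    def test_invalid_block_sizes_rejected(self):
        img = np.zeros((20, 20))
        with pytest.raises(ValueError):
            adaptive_binarize(img, block_size_px=4)
        with pytest.raises(ValueError):
            adaptive_binarize(img, block_size_px=21)


class TestMorphologicalOpen:
    def test_radius_zero_is_identity(self):
        rng = np.random.default_rng(0)
        mask = rng.uniform(size=(30, 30)) > 0.7
        np.testing.assert_array_equal(morphological_open(mask, 0).pixels, mask)

    def test_single_pixel_is_removed(self):
        mask = np.zeros((15, 15), dtype=bool)
        mask[7, 7] = True
        assert not morphological_open(mask, 1).pixels.any()

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        mask=hnp.arrays(bool, (20, 20)),
        radius=st.integers(0, 3),
    )
    def test_opening_never_adds_foreground(self, mask, radius):
        opened = morphological_open(mask, radius).pixels
        assert not np.any(opened & ~mask)


class TestLabelComponents:
    def test_two_separated_squares(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:5, 2:5] = True
        mask[10:13, 10:13] = True
        comps = label_components(mask, calibration_nm_per_px=1.0)
        assert len(comps) == 2
        assert all(c.area_px2 == 9 for c in comps)
        assert all(not c.touches_border for c in comps)

    def test_disk_has_low_eccentricity(self):
        mask = rasterize_disk((64, 64), (32, 32), 14.0)
        (comp,) = label_components(mask, 1.0)
        assert comp.eccentricity < 0.3
        assert comp.eccentricity == pytest.approx(
            moments_eccentricity_oracle(mask), abs=1e-6
        )

    def test_thin_rectangle_has_high_eccentricity(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[5:25, 10:12] = True  # 20 x 2 px bar
        (comp,) = label_components(mask, 1.0)
        assert comp.eccentricity > 0.95
        assert comp.eccentricity == pytest.approx(
            moments_eccentricity_oracle(mask), abs=1e-6
        )

    def test_equivalent_diameter_uses_calibration(self):
        mask = rasterize_disk((64, 64), (32, 32), 10.0)
        (comp,) = label_components(mask, calibration_nm_per_px=2.5)
        expected = 2.0 * np.sqrt(mask.sum() / np.pi) * 2.5
        assert comp.equivalent_diameter_nm == pytest.approx(expected)

    def test_border_clipped_component_is_flagged(self):
        mask = rasterize_disk((40, 40), (0.0, 20.0), 8.0)
        (comp,) = label_components(mask, 1.0)
        assert comp.touches_border


class TestFilters:
    def test_empty_and_vacuous_filters(self):
        assert filter_by_eccentricity([], 0.5) == []
        mask = rasterize_disk((40, 40), (20, 20), 8.0)
        comps = label_components(mask, 1.0)
        assert filter_by_eccentricity(comps, 1.0) == comps
        assert filter_by_area(comps, 1) == comps
        assert filter_by_area(comps, comps[0].area_px2 + 1) == []

    def test_area_filter_matches_bruteforce_on_random_masks(self):
        rng = np.random.default_rng(5)
        mask = rng.uniform(size=(60, 60)) > 0.6
        comps = label_components(mask, 1.0)
        for min_area in (1, 3, 10):
            got = filter_by_area(comps, min_area)
            expected = [c for c in comps if c.area_px2 >= min_area]
            assert got == expected

    def test_line_artifacts_excluded_disks_retained(self, small_scene):
        """Ground-truth check: elongated artifacts fall to the eccentricity filter."""
        image = render_micrograph(small_scene)  # noise-free
        cfg = RunConfig(sim_image_px=512, window_size_px=300)
        _, comps = segment_micrograph(image, cfg)
        assert len(comps) == small_scene.n_fibrils
        # every retained component is near a true fibril center, not an artifact
        centers = small_scene.fibril_centers
        for c in comps:
            d = np.linalg.norm(centers - np.array(c.centroid), axis=1)
            assert d.min() < small_scene.fibril_radii_px.max()


class TestMicrographType:
    def test_rejects_tiny_or_nonfinite_images(self):
        with pytest.raises(ValueError):
            Micrograph(np.zeros((32, 32)), 1.0)
        bad = np.zeros((64, 64))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            Micrograph(bad, 1.0)
        with pytest.raises(ValueError):
            Micrograph(np.zeros((64, 64)), -1.0)
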