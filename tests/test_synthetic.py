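"""Generators: hard-disk scenes, rendered micrographs, thermograms, group tables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import rasterize_disk
from fibrilquant.fixtures import (
    load_cct_table,
    load_dsc_table,
    load_morphometry_table,
)
from fibrilquant.synthetic import (
    InfeasibleDensityError,
    SyntheticScene,
    ThermogramSpec,
    generate_group_table,
    generate_scene,
    generate_thermogram,
    render_micrograph,
)


class TestGenerateScene:
    def test_zero_density_gives_empty_scene(self):
        scene = generate_scene(0.0, image_shape_px=(128, 128), seed=0)
        assert scene.n_fibrils == 0
        assert len(scene.fibril_centers) == 0

    @pytest.mark.parametrize("density", [10.0, 30.0, 60.0])
    def test_realized_count_is_rounded_density_times_area(self, density):
        scene = generate_scene(
            density, image_shape_px=(600, 600), calibration_nm_per_px=2.0, seed=3
        )
        area_um2 = 600 * 600 * 4.0 / 1e6
        assert scene.n_fibrils == round(density * area_um2)
        assert scene.true_density_per_um2 == pytest.approx(density, rel=0.05)

    def test_same_seed_reproduces_scene_field_for_field(self):
        a = generate_scene(40.0, n_artifacts=3, image_shape_px=(300, 300), seed=11)
        b = generate_scene(40.0, n_artifacts=3, image_shape_px=(300, 300), seed=11)
        np.testing.assert_array_equal(a.fibril_centers, b.fibril_centers)
        np.testing.assert_array_equal(a.fibril_radii_px, b.fibril_radii_px)
        assert a.artifact_segments == b.artifact_segments

    def test_centers_inside_bounds(self, small_scene):
        c = small_scene.fibril_centers
        assert np.all(c >= 0)
        assert np.all(c[:, 0] <= small_scene.image_height_px)
        assert np.all(c[:, 1] <= small_scene.image_width_px)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        density=st.floats(5.0, 60.0),
        gap_nm=st.floats(0.0, 8.0),
    )
    def test_hard_disk_condition_holds(self, seed, density, gap_nm):
        """Every pair of disks is separated by at least r_i + r_j + gap."""
        scene = generate_scene(
            density,
            min_gap_nm=gap_nm,
            image_shape_px=(400, 400),
            calibration_nm_per_px=2.0,
            seed=seed,
        )
        c, r = scene.fibril_centers, scene.fibril_radii_px
        gap_px = gap_nm / 2.0
        for i in range(scene.n_fibrils):
            d = np.linalg.norm(c - c[i], axis=1)
            d[i] = np.inf
            assert np.all(d >= r + r[i] + gap_px - 1e-9)

    def test_overdense_request_is_rejected(self):
        with pytest.raises((ValueError, InfeasibleDensityError)):
            generate_scene(
                2000.0, image_shape_px=(256, 256), calibration_nm_per_px=2.0, seed=0
            )
        with pytest.raises(InfeasibleDensityError):
            # feasible packing but an impossible spacing demand
            generate_scene(
                60.0,
                min_gap_nm=200.0,
                image_shape_px=(400, 400),
                calibration_nm_per_px=2.0,
                seed=0,
            )

    def test_nonpositive_calibration_rejected(self):
        with pytest.raises(ValueError):
            generate_scene(10.0, calibration_nm_per_px=0.0, seed=0)

    def test_artifacts_are_long_and_clear_of_fibrils(self, small_scene):
        mean_diam_px = 40.0 / 2.0
        for (a, b, thickness) in small_scene.artifact_segments:
            length = np.hypot(a[0] - b[0], a[1] - b[1])
            assert length >= 5.0 * mean_diam_px
            assert thickness > 0


class TestRenderMicrograph:
    def test_single_disk_bright_area_matches_rasterization(self):
        scene = SyntheticScene(
            image_height_px=64,
            image_width_px=64,
            calibration_nm_per_px=1.0,
            fibril_centers=np.array([[32.0, 32.0]]),
            fibril_radii_px=np.array([10.0]),
            artifact_segments=(),
            seed=0,
        )
        img = render_micrograph(scene)
        oracle = rasterize_disk((64, 64), (32.0, 32.0), 10.0)
        assert np.array_equal(img.pixels > 0.5, oracle)

    def test_empty_scene_renders_constant_background(self):
        scene = SyntheticScene(64, 64, 1.0, np.empty((0, 2)), np.empty(0), (), 0)
        img = render_micrograph(scene)
        assert np.all(img.pixels == img.pixels[0, 0])

    def test_noise_preserves_mean_intensity(self, small_scene):
        clean = render_micrograph(small_scene).pixels.mean()
        n_px = small_scene.image_height_px * small_scene.image_width_px
        noise_sd = 0.05
        means = [
            render_micrograph(small_scene, noise_sd=noise_sd, seed=s).pixels.mean()
            for s in range(20)
        ]
        se = noise_sd / np.sqrt(20 * n_px)
        assert abs(np.mean(means) - clean) < 3 * se

    def test_same_seed_renders_identical_images(self, small_scene):
        a = render_micrograph(small_scene, noise_sd=0.05, blur_sigma_px=1.0)
        b = render_micrograph(small_scene, noise_sd=0.05, blur_sigma_px=1.0)
        np.testing.assert_array_equal(a.pixels, b.pixels)


class TestGenerateThermogram:
    def test_noise_free_peak_sits_at_requested_temperature(self):
        spec = ThermogramSpec(peak_temp_C=72.0, baseline_slope=0.0, noise_sd=0.0)
        curve = generate_thermogram(spec)
        t_at_max = curve.temperature_C[np.argmax(curve.heat_flow)]
        assert abs(t_at_max - 72.0) <= spec.step_C / 2
        # exactly one local maximum attributable to the peak
        interior = curve.heat_flow[1:-1]
        is_max = (interior > curve.heat_flow[:-2]) & (interior > curve.heat_flow[2:])
        assert is_max.sum() == 1

    def test_zero_amplitude_gives_straight_line(self):
        curve = generate_thermogram(
            ThermogramSpec(peak_temp_C=72.0, peak_amplitude=0.0, baseline_slope=0.5)
        )
        fitted = np.polyfit(curve.temperature_C, curve.heat_flow, 1)
        residual = curve.heat_flow - np.polyval(fitted, curve.temperature_C)
        assert np.max(np.abs(residual)) < 1e-9

    def test_same_seed_gives_identical_curves(self):
        a = generate_thermogram(ThermogramSpec(peak_temp_C=71.0, noise_sd=0.05, seed=9))
        b = generate_thermogram(ThermogramSpec(peak_temp_C=71.0, noise_sd=0.05, seed=9))
        np.testing.assert_array_equal(a.heat_flow, b.heat_flow)

    def test_out_of_range_spec_rejected(self):
        with pytest.raises(ValueError):
            ThermogramSpec(peak_temp_C=72.0, temp_range_C=(5.0, 95.0))
        with pytest.raises(ValueError):
            ThermogramSpec(peak_temp_C=100.0)


class TestGroupTable:
    def test_zero_sd_replicates_equal_mean(self):
        df = generate_group_table([("Control", 362.0, 0.0, 5)], seed=0)
        assert np.all(df["value"] == 362.0)

    def test_large_sample_mean_recovers_setting(self):
        df = generate_group_table([("Control", 362.0, 12.0, 1000)], seed=1)
        # 3 SE = 3 * 12 / sqrt(1000) ~ 1.14
        assert abs(df["value"].mean() - 362.0) < 1.2

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            generate_group_table([("g", 1.0, -1.0, 5)])
        with pytest.raises(ValueError):
            generate_group_table([("g", 1.0, 1.0, 1)])


class TestPackagedTables:
    def test_cct_fixture_carries_published_thickness_values(self):
        df = load_cct_table().set_index("group")
        assert df.loc["Control", "cct_um_mean"] == 362
        assert df.loc["COLG", "cct_um_mean"] == 331
        assert df.loc["ChaseABC", "cct_um_mean"] == 316

    def test_morphometry_and_dsc_fixtures_are_complete(self):
        t2, t3 = load_morphometry_table(), load_dsc_table()
        assert len(t2) == len(t3) == 9
        assert t2.set_index("group").loc["Control", "diameter_nm_mean"] == 40.67
        assert t3.set_index("group").loc["ChaseABC", "transition_C_mean"] == 70.70
        assert t3["transition_C_mean"].between(70.70, 74.95).all()
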