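import numpy as np
import pytest
from dataclasses import replace

from pigdepth.synthetic_scene import (
    DepthImage,
    PigPhenotype,
    SceneConfig,
    expected_mean_bw,
    generate_dataset,
    phenotype_from_latent,
    render_depth,
    rendered_volume_mm3,
    sample_phenotype,
    solid_volume_cm3,
)


class TestSamplePhenotype:
    def test_same_seed_identical(self):
        assert sample_phenotype((16.5, 117.0), 123) == sample_phenotype(
            (16.5, 117.0), 123
        )

    def test_different_seeds_differ(self):
        assert sample_phenotype((16.5, 117.0), 1) != sample_phenotype(
            (16.5, 117.0), 2
        )

    def test_latent_doubling_scales_dims_linearly_weight_cubically(self):
        a = phenotype_from_latent(0.4)
        b = phenotype_from_latent(0.8)
        for field in (
            "body_length_cm",
            "shoulder_width_cm",
            "shoulder_height_cm",
            "hip_width_cm",
            "hip_height_cm",
        ):
            assert getattr(b, field) == pytest.approx(2 * getattr(a, field))
        assert b.body_weight_kg == pytest.approx(8 * a.body_weight_kg, rel=1e-9)

    def test_monte_carlo_mean_against_closed_form(self):
        # 1000 draws, noise on: all in range, empirical mean within 3 SE of
        # the generator's closed-form mean
        rng_range = (16.5, 117.0)
        bws = np.array(
            [
                sample_phenotype(rng_range, seed).body_weight_kg
                for seed in range(1000)
            ]
        )
        assert bws.min() >= rng_range[0] and bws.max() <= rng_range[1]
        se = bws.std(ddof=1) / np.sqrt(len(bws))
        assert abs(bws.mean() - expected_mean_bw(rng_range)) <= 3 * se

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError, match="weight_range_kg"):
            sample_phenotype((0.0, 250.0), 0)

    def test_invalid_density_rejected(self):
        with pytest.raises(ValueError, match="density"):
            sample_phenotype((16.5, 117.0), 0, density_g_cm3=float("nan"))

    def test_head_pitch_within_four_cm(self):
        for seed in range(50):
            p = sample_phenotype((16.5, 117.0), seed)
            assert abs(p.head_pitch_cm) <= 4.0

    def test_phenotype_invariants_enforced(self):
        with pytest.raises(ValueError, match="shoulder_width_cm"):
            PigPhenotype(100, -1, 55, 34, 57, 80)
        with pytest.raises(ValueError, match="head_pitch"):
            PigPhenotype(100, 32, 55, 34, 57, 80, head_pitch_cm=5.0)


class TestRenderDepth:
    def test_apex_sets_min_pixel(self, small_config):
        # SH=60, HH=55, no head displacement -> apex 600 mm -> min 1050 mm
        ph = PigPhenotype(100, 32, 60, 34, 55, 80.0)
        cfg = replace(small_config, image_height_px=256, image_width_px=256)
        img = render_depth(ph, cfg)
        assert abs(int(img.data.min()) - 1050) <= 1

    def test_empty_scene_is_background(self, small_config):
        img = render_depth(None, small_config)
        assert np.all(img.data == small_config.camera_distance_mm)

    def test_background_conservation_outside_body(self, small_config):
        ph = PigPhenotype(80, 26, 45, 28, 47, 60.0)
        img = render_depth(ph, small_config)
        # corners are far from the centred body
        assert img.data[0, 0] == small_config.camera_distance_mm
        assert img.data[-1, -1] == small_config.camera_distance_mm

    def test_sh_monotonicity_of_min_pixel(self, small_config):
        mins = []
        for sh in (40.0, 48.0, 56.0, 64.0):
            ph = PigPhenotype(100, 32, sh, 34, 38, 80.0)
            mins.append(int(render_depth(ph, small_config).data.min()))
        assert all(a >= b for a, b in zip(mins, mins[1:]))

    def test_platform_bound_violation_names_bound(self, small_config):
        ph = PigPhenotype(100, 32, 55, 34, 57, 80.0, yaw_deg=60.0)
        with pytest.raises(ValueError, match="platform_width_m"):
            render_depth(ph, small_config)
        huge = PigPhenotype(160.0, 32, 55, 34, 57, 80.0)
        with pytest.raises(ValueError, match="platform_length_m"):
            render_depth(huge, small_config)

    def test_apex_above_camera_rejected(self):
        cfg = SceneConfig(camera_distance_mm=400.0, image_height_px=64,
                          image_width_px=64, depth_noise_std_mm=0.0)
        ph = PigPhenotype(80, 26, 45, 28, 47, 60.0)
        with pytest.raises(ValueError, match="camera"):
            render_depth(ph, cfg)

    def test_noise_clipped_and_quantized(self, noisy_small_config):
        img = render_depth(None, noisy_small_config,
                           rng=np.random.default_rng(0))
        assert img.data.dtype == np.uint16
        assert img.data.max() <= noisy_small_config.camera_distance_mm


class TestVolumeOracle:
    def _base(self, px):
        return SceneConfig(image_height_px=px, image_width_px=px,
                           depth_noise_std_mm=0.0,
                           mm_per_pixel=1500.0 / px)

    def test_volume_within_2pct_at_base_resolution(self):
        cfg = self._base(160)
        for seed in range(8):
            p = sample_phenotype((16.5, 117.0), seed)
            rendered = rendered_volume_mm3(render_depth(p, cfg), cfg) / 1000.0
            analytic = solid_volume_cm3(p, as_imaged=True)
            assert rendered == pytest.approx(analytic, rel=0.02)

    def test_volume_within_half_pct_at_4x_resolution(self):
        cfg = self._base(640)
        for seed in (0, 5):
            p = sample_phenotype((16.5, 117.0), seed)
            rendered = rendered_volume_mm3(render_depth(p, cfg), cfg) / 1000.0
            analytic = solid_volume_cm3(p, as_imaged=True)
            assert rendered == pytest.approx(analytic, rel=0.005)

    def test_10x_grid_rendering_matches_analytic(self):
        # the high-resolution numeric integration of the lofted solid is an
        # independent oracle for the quadrature-based analytic volume
        p = sample_phenotype((16.5, 117.0), 3)
        cfg = self._base(1600)
        rendered = rendered_volume_mm3(render_depth(p, cfg), cfg) / 1000.0
        assert rendered == pytest.approx(
            solid_volume_cm3(p, as_imaged=True), rel=0.002
        )

    def test_shear_and_rotation_preserve_volume(self):
        cfg = self._base(320)
        p = PigPhenotype(80, 26, 45, 28, 47, 60.0)
        straight = replace(p, yaw_deg=0.0, bend_deg=0.0, lateral_offset_cm=0.0)
        posed = replace(p, yaw_deg=5.0, bend_deg=6.0, lateral_offset_cm=1.0)
        v0 = rendered_volume_mm3(render_depth(straight, cfg), cfg)
        v1 = rendered_volume_mm3(render_depth(posed, cfg), cfg)
        assert v1 == pytest.approx(v0, rel=0.01)


class TestGenerateDataset:
    def test_byte_identical_reruns(self, noisy_small_config):
        a = generate_dataset(5, noisy_small_config, seed=9)
        b = generate_dataset(5, noisy_small_config, seed=9)
        for (img_a, lab_a), (img_b, lab_b) in zip(a, b):
            np.testing.assert_array_equal(img_a.data, img_b.data)
            np.testing.assert_array_equal(lab_a, lab_b)
            assert img_a.timestamp_ms == img_b.timestamp_ms

    def test_labels_positive_and_weight_in_range(self, noisy_small_config):
        data = generate_dataset(100, noisy_small_config, seed=21)
        labels = np.stack([lab for _, lab in data])
        assert np.all(labels > 0)
        lo, hi = noisy_small_config.weight_range_kg
        assert np.all((labels[:, 0] >= lo) & (labels[:, 0] <= hi))

    def test_weight_tracks_rendered_volume(self, small_config):
        data = generate_dataset(200, small_config, seed=33)
        bw = np.array([lab[0] for _, lab in data])
        vol = np.array(
            [rendered_volume_mm3(img, small_config) for img, _ in data]
        )
        assert np.corrcoef(bw, vol)[0, 1] > 0.99

    def test_label_mode_flag_controls_sh_label(self, small_config):
        at_rest = replace(small_config, label_mode="at-rest")
        a = generate_dataset(5, small_config, seed=2)
        b = generate_dataset(5, at_rest, seed=2)
        sh_imaged = np.array([lab[2] for _, lab in a])
        sh_rest = np.array([lab[2] for _, lab in b])
        assert not np.allclose(sh_imaged, sh_rest)
        assert np.all(np.abs(sh_imaged - sh_rest) <= 4.0 + 1e-9)

    def test_n_validation(self, small_config):
        with pytest.raises(ValueError, match="n must be"):
            generate_dataset(0, small_config, seed=0)


class TestSceneConfig:
    def test_image_dims_validated(self):
        with pytest.raises(ValueError, match="64"):
            SceneConfig(image_height_px=32)

    def test_default_scale_from_platform(self):
        cfg = SceneConfig()
        assert cfg.scale_mm_per_px == pytest.approx(1500.0 / 1280.0)

    def test_weight_range_validated(self):
        with pytest.raises(ValueError, match="weight_range_kg"):
            SceneConfig(weight_range_kg=(50.0, 20.0))
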