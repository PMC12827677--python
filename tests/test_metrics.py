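"""Rigid MSE registration, modified LNCC, layer sweep and overlays."""

import numpy as np
import pytest

from conefuse.metrics import (EmptyOverlapError, RegistrationParams, RigidTransform2D,
                              apply_rigid, lncc, lncc_layer_sweep, overlay_checkerboard,
                              rigid_register)
from conefuse.volume import VoxelVolume
from helpers import naive_lncc


def noise_image(shape=(96, 96), seed=0):
    return np.random.default_rng(seed).uniform(0, 1, shape)


class TestLnccProperties:
    def test_self_correlation_is_one(self):
        img = noise_image()
        res = lncc(img, img, 15)
        assert np.allclose(res.heatmap, 1.0, atol=1e-9)
        assert res.mean_lncc == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("a, b", [(-2.0, 0.3), (0.5, -10.0), (3.0, 0.0)])
    def test_invariance_to_linear_intensity_maps(self, a, b):
        img = noise_image(seed=1)
        res = lncc(img, a * img + b, 15)
        assert res.mean_lncc == pytest.approx(1.0, abs=1e-9)

    def test_heatmap_dimensions(self):
        img = noise_image((80, 120), seed=2)
        res = lncc(img, noise_image((80, 120), seed=3), 45)
        assert res.heatmap.shape == (80 - 45 + 1, 120 - 45 + 1)

    def test_zero_variance_windows_score_zero(self):
        img = noise_image((64, 64), seed=4)
        flat = img.copy()
        flat[:40, :40] = 0.5  # a constant patch larger than the window
        res = lncc(flat, img, 15)
        assert res.heatmap[10, 10] == 0.0
        const = np.full((64, 64), 2.0)
        assert lncc(const, img, 15).mean_lncc == 0.0

    def test_symmetry(self):
        I, J = noise_image(seed=5), noise_image(seed=6)
        assert lncc(I, J, 15).mean_lncc == pytest.approx(lncc(J, I, 15).mean_lncc, abs=1e-12)

    def test_bounds(self):
        I, J = noise_image(seed=7), noise_image(seed=8)
        res = lncc(I, J, 21)
        assert res.heatmap.min() >= 0.0 and res.heatmap.max() <= 1.0
        assert 0.0 <= res.mean_lncc <= res.max_lncc <= 1.0

    def test_dimension_mismatch_and_oversized_window(self):
        with pytest.raises(ValueError):
            lncc(np.zeros((10, 10)), np.zeros((11, 10)), 5)
        with pytest.raises(ValueError):
            lncc(np.zeros((10, 10)), np.zeros((10, 10)), 21)
        with pytest.raises(ValueError):
            lncc(np.zeros((30, 30)), np.zeros((30, 30)), 10)  # even window

    @pytest.mark.parametrize("window", [15, 45])
    def test_matches_naive_double_loop(self, window):
        """Vectorized implementation equals the literal per-window oracle."""
        rng = np.random.default_rng(99)
        shape = (64, 70)
        I, J = rng.normal(0, 1, shape), rng.normal(0, 1, shape)
        res = lncc(I, J, window)
        oracle = naive_lncc(I, J, window)
        assert np.abs(res.heatmap - oracle).max() < 1e-6

    def test_white_noise_mean_is_small(self):
        I, J = noise_image((128, 128), seed=10), noise_image((128, 128), seed=11)
        res = lncc(I, J, 45)
        # E|NCC| for n = 2025 independent samples ~ sqrt(2/(pi n)) ≈ 0.018
        assert res.mean_lncc < 0.05


@pytest.fixture(scope="module")
def fixed(clean_phantom):
    from conefuse import phantom as ph
    vol, truth = clean_phantom
    plane, shape = ph.make_cutting_plane(truth.shape, truth.voxel_size, z0_mm=5.9,
                                         pixel_size=truth.voxel_size)
    sec = ph.sample_section_image(vol, truth, plane, truth.voxel_size, shape, seed=12)
    return sec.image.astype(float)


class TestRigidRegistration:
    def test_identity_registration(self, fixed):
        t = rigid_register(fixed, fixed)
        assert abs(t.rotation) < 0.1
        assert np.hypot(*t.translation) < 0.2

    def test_translation_recovered(self, fixed):
        rng = np.random.default_rng(13)
        planted = RigidTransform2D(rotation=0.0, translation=(5.0, -3.0))
        moving = apply_rigid(fixed, planted.inverse(), cval=0.0)
        moving += rng.normal(0, 0.1 * np.ptp(fixed), moving.shape)
        t = rigid_register(moving, fixed)
        assert t.translation[0] == pytest.approx(5.0, abs=0.5)
        assert t.translation[1] == pytest.approx(-3.0, abs=0.5)

    def test_rotation_recovered(self, fixed):
        rng = np.random.default_rng(14)
        planted = RigidTransform2D(rotation=4.0, translation=(0.0, 0.0))
        moving = apply_rigid(fixed, planted.inverse(), cval=0.0)
        moving += rng.normal(0, 0.1 * np.ptp(fixed), moving.shape)
        t = rigid_register(moving, fixed)
        assert t.rotation == pytest.approx(4.0, abs=0.25)

    def test_combined_transform_recovered(self, fixed):
        rng = np.random.default_rng(15)
        planted = RigidTransform2D(rotation=-3.0, translation=(-8.0, 6.0))
        moving = apply_rigid(fixed, planted.inverse(), cval=0.0)
        moving += rng.normal(0, 0.1 * np.ptp(fixed), moving.shape)
        t = rigid_register(moving, fixed)
        assert t.rotation == pytest.approx(-3.0, abs=0.25)
        assert t.translation[0] == pytest.approx(-8.0, abs=0.5)
        assert t.translation[1] == pytest.approx(6.0, abs=0.5)

    def test_masked_registration_uses_only_masked_region(self, fixed):
        """A fixed-image mask restricts the metric (align on tissue only)."""
        rng = np.random.default_rng(22)
        planted = RigidTransform2D(rotation=0.0, translation=(4.0, 2.0))
        moving = apply_rigid(fixed, planted.inverse(), cval=0.0)
        # corrupt the moving image outside the central region; with the mask
        # limited to the center, registration should still recover the shift
        corrupted = moving.copy()
        corrupted[: fixed.shape[0] // 4] = rng.uniform(0, 1, corrupted[: fixed.shape[0] // 4].shape)
        mask = np.zeros(fixed.shape, bool)
        h, w = fixed.shape
        mask[h // 3: 2 * h // 3, w // 3: 2 * w // 3] = True
        t = rigid_register(corrupted, fixed, fixed_mask=mask)
        assert t.translation[0] == pytest.approx(4.0, abs=0.5)
        assert t.translation[1] == pytest.approx(2.0, abs=0.5)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            rigid_register(np.zeros((64, 64)), np.ones((64, 64)))

    def test_transform_inverse_composition(self):
        t = RigidTransform2D(rotation=23.0, translation=(4.5, -7.25))
        inv = t.inverse()
        m = t.as_matrix((64, 64)).params @ inv.as_matrix((64, 64)).params
        assert np.allclose(m, np.eye(3), atol=1e-9)


class TestLayerSweep:
    def test_flat_truth_plane_maximizes_at_true_layer(self, clean_phantom):
        from conefuse import phantom as ph
        vol, truth = clean_phantom
        k_star = 58
        plane, shape = ph.make_cutting_plane(truth.shape, truth.voxel_size,
                                             z0_mm=k_star * truth.voxel_size,
                                             pixel_size=truth.voxel_size)
        sec = ph.sample_section_image(vol, truth, plane, truth.voxel_size, shape, seed=16)
        scores, best = lncc_layer_sweep(vol, sec.image.astype(float), 45)
        assert best == k_star

    def test_tied_layers_first_wins(self):
        layer = noise_image((60, 60), seed=17)
        vol = VoxelVolume(np.stack([layer] * 5), 1.0)
        scores, best = lncc_layer_sweep(vol, layer, 15)
        assert best == 0
        assert np.allclose(scores, scores[0])

    def test_empty_volume_rejected(self):
        with pytest.raises(ValueError):
            lncc_layer_sweep(np.zeros((0, 10, 10)), np.zeros((10, 10)), 5)

    def test_tilted_plane_extraction_beats_flat_layers(self, clean_phantom):
        """The oblique in-silico plane scores at least as high as any flat layer."""
        from conefuse import phantom as ph
        from conefuse.plane import extract_oblique_slice
        vol, truth = clean_phantom
        plane, shape = ph.make_cutting_plane(truth.shape, truth.voxel_size, z0_mm=5.8,
                                             tilt_deg=4.0, azimuth_deg=60.0,
                                             pixel_size=truth.voxel_size)
        sec = ph.sample_section_image(vol, truth, plane, truth.voxel_size, shape, seed=18)
        section = sec.image.astype(float)
        extracted = extract_oblique_slice(vol, plane, shape)
        scores, _ = lncc_layer_sweep(vol, section, 45)
        h = min(section.shape[0], extracted.shape[0])
        w = min(section.shape[1], extracted.shape[1])
        plane_score = lncc(extracted[:h, :w], section[:h, :w], 45).mean_lncc
        assert plane_score >= scores.max()


class TestCheckerboard:
    def test_identical_inputs_identity(self):
        a = noise_image((32, 32), seed=19)
        assert np.array_equal(overlay_checkerboard(a, a, 8), a)

    def test_single_tile_returns_first(self):
        a, b = noise_image((16, 16), seed=20), noise_image((16, 16), seed=21)
        assert np.array_equal(overlay_checkerboard(a, b, 16), a)
        assert np.array_equal(overlay_checkerboard(a, b, 64), a)

    def test_two_by_two_block_pattern(self):
        a = np.zeros((4, 4))
        b = np.ones((4, 4))
        out = overlay_checkerboard(a, b, 2)
        expected = np.array([[0, 0, 1, 1],
                             [0, 0, 1, 1],
                             [1, 1, 0, 0],
                             [1, 1, 0, 0]], dtype=float)
        assert np.array_equal(out, expected)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            overlay_checkerboard(np.zeros((4, 4)), np.zeros((4, 5)), 2)
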