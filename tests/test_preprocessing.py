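"""Resampling, centering, cropping, normalization, paired augmentation."""

import numpy as np
import pytest
from scipy import ndimage

from surf2vol import (
    AugmentationPolicy,
    NormalizationRecord,
    SurfaceMatrix,
    VolumeGrid,
    apply_normalization,
    augment_pair,
    center_by_mass,
    crop_or_pad,
    downsample_half,
    fit_normalization,
    invert_normalization,
    resample,
    upsample_to,
)
from surf2vol.preprocess import mass_center_shift


def grid_of(data, spacing=(1, 1, 1)):
    return VolumeGrid(np.asarray(data, dtype=np.float32), spacing)


class TestResample:
    def test_identity_at_same_spacing(self):
        rng = np.random.default_rng(0)
        vol = grid_of(rng.normal(size=(6, 7, 5)), (2.0, 3.0, 1.5))
        out = resample(vol, (2.0, 3.0, 1.5))
        assert out.shape == vol.shape
        np.testing.assert_allclose(out.intensities, vol.intensities, atol=1e-5)

    def test_constant_stays_constant(self):
        vol = grid_of(np.full((8, 8, 8), 42.0), (1, 1, 1))
        out = resample(vol, (1.7, 2.3, 0.9))
        np.testing.assert_allclose(out.intensities, 42.0, atol=1e-4)

    def test_linear_ramp_sampled_at_centers(self):
        # intensity = physical z coordinate of the voxel center
        n = 16
        z = (np.arange(n) + 0.5) * 1.0
        vol = grid_of(np.broadcast_to(z[:, None, None], (n, 4, 4)).copy(), (1, 1, 1))
        out = resample(vol, (2.0, 1.0, 1.0))
        expected = (np.arange(n // 2) + 0.5) * 2.0
        # interior values follow the analytic ramp exactly
        np.testing.assert_allclose(out.intensities[1:-1, 0, 0], expected[1:-1], atol=1e-4)

    def test_bounded_by_input_range(self):
        rng = np.random.default_rng(1)
        vol = grid_of(rng.normal(size=(9, 9, 9)) * 100)
        out = resample(vol, (0.7, 1.3, 2.1))
        assert out.intensities.min() >= vol.intensities.min() - 1e-3
        assert out.intensities.max() <= vol.intensities.max() + 1e-3

    def test_bad_spacing(self):
        vol = grid_of(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            resample(vol, (0.0, 1.0, 1.0))


def offset_cube(offset=(0, 0, 0), shape=(24, 24, 24)):
    data = np.full(shape, -1000.0, dtype=np.float32)
    c = [s // 2 + o for s, o in zip(shape, offset)]
    data[c[0] - 3 : c[0] + 3, c[1] - 3 : c[1] + 3, c[2] - 3 : c[2] + 3] = 0.0
    return grid_of(data)


class TestCenterByMass:
    def test_centered_cube_fixed_point(self):
        vol = offset_cube()
        assert mass_center_shift(vol) == (0, 0, 0)

    def test_offset_cube_translated_back(self):
        vol = offset_cube(offset=(6, 0, 0))
        assert mass_center_shift(vol) == (-6, 0, 0)
        out = center_by_mass(vol)
        mask = out.intensities >= -400.0
        com = ndimage.center_of_mass(mask)
        center = [(n - 1) / 2 for n in out.shape]
        assert all(abs(c - m) <= 0.5 for c, m in zip(center, com))

    def test_idempotent(self):
        out = center_by_mass(offset_cube(offset=(5, -4, 2)))
        assert mass_center_shift(out) == (0, 0, 0)

    def test_empty_mask(self):
        vol = grid_of(np.full((8, 8, 8), -1000.0))
        with pytest.raises(ValueError):
            center_by_mass(vol)


class TestCropOrPad:
    def test_identity(self):
        rng = np.random.default_rng(2)
        vol = grid_of(rng.normal(size=(6, 8, 6)))
        out = crop_or_pad(vol, (6, 8, 6))
        assert np.array_equal(out.intensities, vol.intensities)

    def test_ramp_padded_centrally(self):
        vol = grid_of(np.arange(4, dtype=np.float32)[:, None, None] + np.zeros((4, 2, 2)))
        out = crop_or_pad(vol, (8, 2, 2), pad_value=-1.0)
        assert out.shape == (8, 2, 2)
        np.testing.assert_array_equal(out.intensities[2:6, 0, 0], [0, 1, 2, 3])
        assert np.all(out.intensities[:2] == -1.0) and np.all(out.intensities[6:] == -1.0)

    def test_crop_then_pad_round_trip(self):
        rng = np.random.default_rng(3)
        vol = grid_of(rng.normal(size=(10, 10, 10)))
        cropped = crop_or_pad(vol, (6, 6, 6))
        back = crop_or_pad(cropped, (10, 10, 10))
        np.testing.assert_array_equal(
            back.intensities[2:8, 2:8, 2:8], vol.intensities[2:8, 2:8, 2:8]
        )


class TestNormalization:
    def test_endpoints(self):
        vols = [grid_of(np.array([[[-1000.0, 1000.0]]]))]
        rec = fit_normalization(vols)
        assert (rec.global_min, rec.global_max) == (-1000.0, 1000.0)
        out = apply_normalization(vols[0], rec).intensities
        np.testing.assert_allclose(out, [[[0.0, 1.0]]])

    def test_midpoint(self):
        rec = NormalizationRecord(-1000.0, 1000.0)
        out = apply_normalization(grid_of([[[0.0]]]), rec)
        assert out.intensities[0, 0, 0] == pytest.approx(0.5)

    def test_round_trip(self):
        rng = np.random.default_rng(4)
        vol = grid_of(rng.uniform(-1000, 1000, size=(8, 8, 8)))
        rec = NormalizationRecord(-1000.0, 1000.0)
        back = invert_normalization(apply_normalization(vol, rec), rec)
        assert np.max(np.abs(back.intensities - vol.intensities)) < 1e-5

    def test_degenerate_range(self):
        with pytest.raises(ValueError):
            fit_normalization([grid_of(np.zeros((4, 4, 4)))])


class TestAugmentPair:
    def _pair(self, seed=0, shape=(20, 24, 20)):
        rng = np.random.default_rng(seed)
        data = np.full(shape, -1000.0, dtype=np.float32)
        data[6:14, 8:16, 6:14] = 40.0 + rng.normal(0, 5, size=(8, 8, 8))
        vol = grid_of(data)
        surf_data = np.full(shape, -1000.0, dtype=np.float32)
        surf_data[6:14, 8:16, 6] = 40.0
        surf = SurfaceMatrix(surf_data, (1, 1, 1))
        return vol, surf

    def test_probability_zero_is_identity(self):
        vol, surf = self._pair()
        policy = AugmentationPolicy(probability=0.0)
        v2, s2 = augment_pair(vol, surf, policy, np.random.default_rng(0))
        assert np.array_equal(v2.intensities, vol.intensities)
        assert np.array_equal(s2.intensities, surf.intensities)

    def test_degenerate_affine_is_identity(self):
        vol, surf = self._pair()
        policy = AugmentationPolicy(probability=1.0, shear_max=0, rotation_max=0, scale_max=0)
        v2, s2 = augment_pair(vol, surf, policy, np.random.default_rng(0))
        np.testing.assert_allclose(v2.intensities, vol.intensities, atol=1e-3)

    def test_same_transform_applied_to_both(self):
        vol, surf = self._pair()
        policy = AugmentationPolicy(probability=1.0)
        rng = np.random.default_rng(11)
        v2, s2, params = augment_pair(vol, surf, policy, rng, return_params=True)
        assert params is not None

        def centroid(grid):
            mask = grid.intensities >= -400.0
            return np.array(ndimage.center_of_mass(mask))

        shift_vol = centroid(v2) - centroid(vol)
        shift_surf = centroid(s2) - centroid(surf)
        # the shared affine moves the paired body centroids together
        assert np.all(np.abs(shift_vol - shift_surf) < 1.5)

    def test_seeded_reproducibility(self):
        vol, surf = self._pair()
        policy = AugmentationPolicy(probability=1.0)
        a = augment_pair(vol, surf, policy, np.random.default_rng(7))
        b = augment_pair(vol, surf, policy, np.random.default_rng(7))
        assert np.array_equal(a[0].intensities, b[0].intensities)


class TestResolutionChanges:
    def test_constant_downsample(self):
        vol = grid_of(np.full((8, 8, 8), 3.25), (1, 1, 1))
        out = downsample_half(vol)
        assert out.shape == (4, 4, 4)
        assert out.spacing == (2.0, 2.0, 2.0)
        np.testing.assert_allclose(out.intensities, 3.25)

    def test_odd_shape_rejected(self):
        with pytest.raises(ValueError):
            downsample_half(grid_of(np.zeros((7, 8, 8))))

    def test_round_trip_on_smooth_field(self):
        n = 32
        ax = np.linspace(0, np.pi, n)
        z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
        field = np.sin(z) * np.cos(y) * np.sin(x)
        vol = grid_of(field)
        back = upsample_to(downsample_half(vol), (n, n, n))
        err = np.max(np.abs(back.intensities - field))
        assert err < 0.05 * (field.max() - field.min())

    def test_full_scale_half_shape(self):
        vol = grid_of(np.zeros((160, 32, 8)))
        out = downsample_half(vol)
        assert out.shape == (80, 16, 4)
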