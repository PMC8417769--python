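"""The stochastic augmentation chain and its invariants."""

import numpy as np
import pytest

from hypothseg.augment import (
    AffineTransform,
    AugmentConfig,
    DenseTransform,
    apply_bias,
    augment_intensity,
    augment_pair,
    compose_displacements,
    flip_pair,
    integrate_svf,
    minmax_normalize,
    random_crop_pair,
    random_flip_pair,
    sample_affine,
    sample_bias_field,
    sample_svf,
    warp,
    VelocityField,
)
from hypothseg.io import Volume, hard_assign, one_hot_encode


@pytest.fixture()
def cfg():
    return AugmentConfig(svf_grid=(6, 6, 6), crop_size=(16, 16, 16), translation_range=1.5)


class TestSampleSvf:
    def test_zero_width_gives_zero_field(self, cfg, rng):
        from dataclasses import replace

        v = sample_svf((16, 16, 16), replace(cfg, svf_std_max=0.0), rng)
        assert np.all(v.data == 0.0)

    def test_same_seed_same_field(self, cfg):
        v1 = sample_svf((16, 16, 16), cfg, np.random.default_rng(5))
        v2 = sample_svf((16, 16, 16), cfg, np.random.default_rng(5))
        np.testing.assert_array_equal(v1.data, v2.data)

    def test_corner_std_matches_sampler_scale(self, cfg):
        # the (0,0,0) voxel coincides with a coarse-grid sample; with the
        # per-draw sigma uniform on [0, m] its marginal std is m/sqrt(3)
        rng = np.random.default_rng(6)
        draws = np.array(
            [sample_svf((8, 8, 8), cfg, rng).data[0, 0, 0] for _ in range(1000)]
        )
        expected = cfg.svf_std_max / np.sqrt(3.0)
        assert draws.std() == pytest.approx(expected, rel=0.05)

    def test_shape_smaller_than_grid_rejected(self, cfg, rng):
        with pytest.raises(ValueError, match="smaller"):
            sample_svf((4, 4, 4), cfg, rng)


class TestIntegrateSvf:
    def test_zero_velocity_zero_displacement(self):
        u = integrate_svf(VelocityField(np.zeros((8, 8, 8, 3), np.float32)), 7)
        assert np.all(u.data == 0.0)

    def test_constant_velocity_is_translation(self):
        v = np.zeros((12, 12, 12, 3), np.float32)
        v[..., 2] = 1.5
        u = integrate_svf(VelocityField(v), 7)
        # away from the clamped border the flow of a constant field is a shift
        interior = u.data[3:-3, 3:-3, 3:-3]
        np.testing.assert_allclose(interior[..., 2], 1.5, atol=1e-3)
        np.testing.assert_allclose(interior[..., :2], 0.0, atol=1e-3)

    def test_forward_inverse_composition_near_identity(self):
        # a sigma=2 field on the default 10^3 grid, upsampled to a
        # realistically smooth per-voxel scale (96^3 keeps the runtime low;
        # the residual only shrinks further at full 160^3 size)
        cfg = AugmentConfig()
        rng = np.random.default_rng(3)
        sigma = 2.0
        small = rng.normal(0.0, sigma, size=(10, 10, 10, 3)).astype(np.float32)
        from hypothseg.augment import _upsample_trilinear

        v = VelocityField(_upsample_trilinear(small, (96, 96, 96)))
        fwd = integrate_svf(v, cfg.integration_steps)
        bwd = integrate_svf(-v, cfg.integration_steps)
        residual = compose_displacements(fwd, bwd)
        mean_mag = np.linalg.norm(residual.data, axis=-1).mean()
        assert mean_mag < 0.05


class TestSampleAffine:
    def test_degenerate_ranges_give_identity(self, rng):
        ident = AugmentConfig().identity()
        m = sample_affine(ident, rng, shape=(10, 10, 10)).matrix
        np.testing.assert_allclose(m, np.eye(4), atol=1e-12)

    def test_pure_rotation_about_third_axis(self):
        from hypothseg.augment import _rotation_matrix

        r = _rotation_matrix(2, np.deg2rad(90.0))
        np.testing.assert_allclose(r[:3, :3] @ [1, 0, 0], [0, 1, 0], atol=1e-12)

    def test_equals_explicit_factor_product(self):
        # reproduce the six factors from the same uniform draws
        cfg = AugmentConfig()
        rng = np.random.default_rng(9)
        m = sample_affine(cfg, rng).matrix
        rng = np.random.default_rng(9)
        ang = np.deg2rad(rng.uniform(-cfg.rotation_range, cfg.rotation_range, 3))
        sc = rng.uniform(*cfg.scaling_range, 3)
        sh = rng.uniform(-cfg.shear_range, cfg.shear_range, 3)
        tr = rng.uniform(-cfg.translation_range, cfg.translation_range, 3)

        def rot(axis, a):
            c, s = np.cos(a), np.sin(a)
            r = np.eye(4)
            i, j = [(1, 2), (0, 2), (0, 1)][axis]
            r[i, i], r[i, j], r[j, i], r[j, j] = c, -s, s, c
            return r

        shm = np.eye(4)
        shm[0, 1], shm[0, 2], shm[1, 2] = sh
        tm = np.eye(4)
        tm[:3, 3] = tr
        expected = tm @ rot(0, ang[0]) @ rot(1, ang[1]) @ rot(2, ang[2]) @ shm @ np.diag(
            [sc[0], sc[1], sc[2], 1.0]
        )
        np.testing.assert_allclose(m, expected, atol=1e-12)

    def test_singular_matrix_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            AffineTransform(np.diag([1.0, 0.0, 1.0, 1.0]))


class TestWarp:
    def test_identity_transform_preserves_input(self, tiny_phantom):
        img, _ = tiny_phantom
        out = warp(img, DenseTransform(AffineTransform.identity()))
        np.testing.assert_allclose(out.data, img.data, atol=1e-6)

    def test_integer_translation_shifts_content(self, tiny_phantom):
        img, _ = tiny_phantom
        m = np.eye(4)
        m[0, 3] = 1.0  # source = x + 1: content moves one voxel towards 0
        out = warp(img, DenseTransform(AffineTransform(m)))
        np.testing.assert_allclose(out.data[:-1], img.data[1:], atol=1e-5)

    def test_warped_one_hot_stays_partition_of_unity(self, tiny_phantom, cfg, rng):
        _, lm = tiny_phantom
        labels = one_hot_encode(lm)
        disp = integrate_svf(sample_svf(lm.shape, cfg, rng), 7)
        affine = sample_affine(cfg, rng, shape=lm.shape)
        out = warp(labels, DenseTransform(affine, disp))
        np.testing.assert_allclose(out.data.sum(axis=-1), 1.0, atol=1e-5)

    def test_warped_categorical_matches_one_hot_in_constant_interior(self, tiny_phantom):
        # nearest-neighbour on the label map agrees with warp+argmax away
        # from label boundaries
        img, lm = tiny_phantom
        m = np.eye(4)
        m[1, 3] = 0.25
        t = DenseTransform(AffineTransform(m))
        via_soft = hard_assign(warp(one_hot_encode(lm), t))
        interior = np.ones(lm.shape, bool)
        from scipy.ndimage import binary_erosion, generate_binary_structure

        for c in lm.taxonomy.codes:
            region = lm.data == c
            eroded = binary_erosion(region, generate_binary_structure(3, 3))
            interior &= ~(region ^ eroded) | eroded
        same = via_soft.data == lm.data
        assert np.all(same[binary_erosion(interior, iterations=1)])


class TestBiasField:
    def test_zero_width_gives_unit_field(self, cfg, rng):
        from dataclasses import replace

        b = sample_bias_field((8, 8, 8), replace(cfg, bias_log_std_max=0.0), rng)
        np.testing.assert_allclose(b.data, 1.0)

    def test_strictly_positive_across_draws(self, cfg):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            b = sample_bias_field((5, 5, 5), cfg, rng)
            assert b.data.min() > 0.0

    def test_log_field_centred(self, cfg):
        rng = np.random.default_rng(2)
        means = [
            np.log(sample_bias_field((6, 6, 6), cfg, rng).data).mean()
            for _ in range(1000)
        ]
        assert abs(np.mean(means)) < 0.02

    def test_apply_bias_is_voxelwise_product(self, tiny_phantom, cfg, rng):
        img, _ = tiny_phantom
        b = sample_bias_field(img.shape, cfg, rng)
        out = apply_bias(img, b)
        nz = img.data != 0
        np.testing.assert_allclose(out.data[nz] / img.data[nz], b.data[nz], rtol=1e-5)
        doubled = apply_bias(img, type(b)(np.full(img.shape, 2.0, np.float32)))
        np.testing.assert_allclose(doubled.data, 2.0 * img.data)


class TestIntensityAugmentation:
    def test_identity_ranges_leave_image_unchanged(self, tiny_phantom, rng):
        img, _ = tiny_phantom
        out = augment_intensity(img, AugmentConfig().identity(), rng)
        np.testing.assert_allclose(out.data, img.data, atol=1e-5)

    def test_pure_shift_adds_constant(self, tiny_phantom):
        from dataclasses import replace

        img, _ = tiny_phantom
        cfg = replace(
            AugmentConfig().identity(), brightness_shift_range=0.1
        )
        rng = np.random.default_rng(0)
        out = augment_intensity(img, cfg, rng)
        shifts = out.data - img.data
        assert np.ptp(shifts) < 1e-4  # constant shift everywhere

    def test_std_scales_with_gain(self, tiny_phantom, rng):
        from dataclasses import replace

        img, _ = tiny_phantom
        cfg = replace(AugmentConfig().identity(), contrast_factor_range=(0.75, 0.75))
        out = augment_intensity(img, cfg, rng)
        assert out.data.std() == pytest.approx(0.75 * img.data.std(), rel=1e-5)


class TestFlip:
    def test_zero_probability_never_flips(self, tiny_phantom):
        from dataclasses import replace

        img, lm = tiny_phantom
        labels = one_hot_encode(lm)
        cfg = replace(AugmentConfig(), flip_probability=0.0)
        rng = np.random.default_rng(0)
        for _ in range(20):
            out_i, out_l, flipped = random_flip_pair(img, labels, cfg, rng)
            assert not flipped
            np.testing.assert_array_equal(out_i.data, img.data)

    def test_double_flip_restores_pair(self, tiny_phantom):
        img, lm = tiny_phantom
        labels = one_hot_encode(lm)
        i2, l2 = flip_pair(*flip_pair(img, labels))
        np.testing.assert_array_equal(i2.data, img.data)
        np.testing.assert_array_equal(l2.data, labels.data)

    def test_flip_swaps_lateral_labels(self, tiny_phantom):
        img, lm = tiny_phantom
        labels = one_hot_encode(lm)
        _, flipped = flip_pair(img, labels)
        lm_f = hard_assign(flipped)
        tax = lm.taxonomy
        for c in tax.foreground_codes:
            assert (lm_f.data == tax.lr_swap[c]).sum() == (lm.data == c).sum()

    def test_empirical_flip_rate_near_half(self, tiny_phantom):
        img, lm = tiny_phantom
        labels = one_hot_encode(lm)
        cfg = AugmentConfig()
        rng = np.random.default_rng(123)
        flips = sum(
            random_flip_pair(img, labels, cfg, rng)[2] for _ in range(10_000)
        )
        assert 0.48 <= flips / 10_000 <= 0.52


class TestCrop:
    def test_full_size_crop_is_identity(self, tiny_phantom, rng):
        from dataclasses import replace

        img, lm = tiny_phantom
        labels = one_hot_encode(lm)
        cfg = replace(AugmentConfig(), crop_size=img.shape)
        out_i, out_l = random_crop_pair(img, labels, cfg, rng)
        np.testing.assert_array_equal(out_i.data, img.data)
        np.testing.assert_array_equal(out_l.data, labels.data)

    def test_foreground_preserved_and_size_correct(self, desk_phantom):
        from dataclasses import replace

        img, lm = desk_phantom
        labels = one_hot_encode(lm)
        cfg = replace(AugmentConfig(), crop_size=(20, 20, 20))
        rng = np.random.default_rng(0)
        n_fg = (lm.data > 0).sum()
        for _ in range(10):
            out_i, out_l = random_crop_pair(img, labels, cfg, rng)
            assert out_i.shape == (20, 20, 20)
            assert (out_l.data[..., 0] < 0.5).sum() == n_fg

    def test_crop_larger_than_image_rejected(self, tiny_phantom, rng):
        from dataclasses import replace

        img, lm = tiny_phantom
        cfg = replace(AugmentConfig(), crop_size=(64, 64, 64))
        with pytest.raises(ValueError, match="exceeds"):
            random_crop_pair(img, one_hot_encode(lm), cfg, rng)


class TestMinMaxNormalize:
    def test_basic_rescaling(self):
        v = Volume(np.array([[[2.0, 4.0, 6.0]]]))
        np.testing.assert_allclose(minmax_normalize(v).data, [[[0.0, 0.5, 1.0]]])

    def test_constant_maps_to_zero(self):
        v = Volume(np.full((3, 3, 3), 7.0))
        assert np.all(minmax_normalize(v).data == 0.0)

    def test_invariant_to_positive_affine_intensity_maps(self, tiny_phantom):
        img, _ = tiny_phantom
        remapped = Volume(3.5 * img.data + 11.0, img.voxel_size, img.affine)
        np.testing.assert_allclose(
            minmax_normalize(remapped).data, minmax_normalize(img).data, atol=1e-5
        )


class TestAugmentPair:
    def test_identity_config_returns_normalised_input(self, tiny_phantom):
        img, lm = tiny_phantom
        cfg = AugmentConfig(crop_size=img.shape).identity()
        sample = augment_pair(img, lm, cfg, np.random.default_rng(0))
        np.testing.assert_allclose(
            sample.image.data, minmax_normalize(img).data, atol=1e-6
        )
        np.testing.assert_array_equal(hard_assign(sample.labels).data, lm.data)

    def test_same_seed_bit_identical(self, tiny_phantom):
        img, lm = tiny_phantom
        cfg = AugmentConfig(svf_grid=(6, 6, 6), crop_size=img.shape, translation_range=1.5)
        s1 = augment_pair(img, lm, cfg, np.random.default_rng(42))
        s2 = augment_pair(img, lm, cfg, np.random.default_rng(42))
        np.testing.assert_array_equal(s1.image.data, s2.image.data)
        np.testing.assert_array_equal(s1.labels.data, s2.labels.data)

    def test_successive_draws_are_distinct(self, tiny_phantom):
        # 200 successive draws never produce the same image twice
        img, lm = tiny_phantom
        cfg = AugmentConfig(svf_grid=(6, 6, 6), crop_size=img.shape, translation_range=1.5)
        rng = np.random.default_rng(7)
        seen = set()
        for _ in range(200):
            s = augment_pair(img, lm, cfg, rng)
            seen.add(s.image.data.tobytes())
        assert len(seen) == 200

    def test_labels_stay_simplex_through_full_chain(self, tiny_phantom):
        img, lm = tiny_phantom
        cfg = AugmentConfig(svf_grid=(6, 6, 6), crop_size=img.shape, translation_range=1.5)
        rng = np.random.default_rng(11)
        for _ in range(5):
            s = augment_pair(img, lm, cfg, rng)
            np.testing.assert_allclose(s.labels.data.sum(axis=-1), 1.0, atol=1e-5)
            assert s.image.data.min() >= 0.0 and s.image.data.max() <= 1.0
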