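"""Preprocessing chain: crop, resize, green channel, CLAHE, gamma, NLM,
patch grid, stitching and augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from masegnet.preprocess import (
    AugmentSpec,
    PatchSet,
    PreprocessConfig,
    apply_clahe,
    apply_gamma,
    augment,
    crop_border,
    denoise_nlm,
    extract_green,
    extract_patches,
    preprocess,
    stitch_patches,
    resize,
)


class TestCropBorder:
    def test_black_columns_and_rows_removed(self):
        img = np.zeros((120, 200, 3))
        img[10:110, 50:150] = 200.0  # content block 100x100
        out = crop_border(img, threshold=10)
        assert out.shape == (100, 100, 3)

    def test_no_border_returns_full_frame(self, rng):
        img = rng.uniform(50, 255, (30, 40, 3))
        assert crop_border(img, threshold=10).shape == (30, 40, 3)

    def test_all_black_raises(self):
        with pytest.raises(ValueError, match="below the crop threshold"):
            crop_border(np.zeros((10, 10, 3)), threshold=10)


class TestResize:
    def test_identity_resize_bilinear(self, rng):
        img = rng.uniform(0, 255, (16, 16))
        np.testing.assert_allclose(resize(img, (16, 16)), img, atol=1e-9)

    def test_constant_preserved(self):
        out = resize(np.full((8, 10), 42.0), (5, 7))
        np.testing.assert_allclose(out, 42.0)

    def test_checkerboard_halving_is_block_mean(self):
        cb = np.indices((4, 4)).sum(axis=0) % 2 * 255.0
        out = resize(cb, (2, 2))
        expected = np.array([[cb[r: r + 2, c: c + 2].mean()
                              for c in (0, 2)] for r in (0, 2)])
        np.testing.assert_allclose(out, expected)

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ValueError):
            resize(np.ones((4, 4)), (0, 4))


class TestExtractGreen:
    def test_matches_channel_slice(self, rng):
        img = rng.uniform(0, 255, (12, 9, 3))
        np.testing.assert_array_equal(extract_green(img), img[..., 1])

    def test_pure_colors(self):
        green = np.zeros((4, 4, 3))
        green[..., 1] = 200
        assert np.all(extract_green(green) == 200)
        red = np.zeros((4, 4, 3))
        red[..., 0] = 200
        assert np.all(extract_green(red) == 0)

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError, match="RGB"):
            extract_green(np.zeros((4, 4)))


class TestClahe:
    def test_constant_image_unchanged(self):
        out = apply_clahe(np.full((64, 64), 90.0))
        np.testing.assert_allclose(out, 90.0)

    def test_output_range(self, rng):
        out = apply_clahe(rng.uniform(0, 255, (64, 64)))
        assert out.min() >= 0.0 and out.max() <= 255.0

    def test_low_contrast_ramp_gains_contrast(self):
        ramp = np.tile(np.linspace(100, 140, 64), (64, 1))
        assert apply_clahe(ramp).std() > ramp.std()

    def test_nonpositive_clip_rejected(self):
        with pytest.raises(ValueError):
            apply_clahe(np.ones((8, 8)), clip_limit=0.0)


class TestGamma:
    def test_r_max_fixed_point(self):
        for gamma in (0.5, 0.9, 2.0):
            assert apply_gamma(np.array([[255.0]]), gamma)[0, 0] == \
                pytest.approx(255.0)

    def test_gamma_one_is_identity(self, rng):
        img = rng.uniform(0, 255, (8, 8))
        np.testing.assert_allclose(apply_gamma(img, 1.0), img, rtol=1e-12)

    def test_scalar_power_oracle(self):
        # (128/255)**0.9 * 255, evaluated independently
        out = apply_gamma(np.array([[128.0]]), 0.9)
        assert out[0, 0] == pytest.approx(137.1333200989732, abs=1e-9)

    def test_gamma_below_one_brightens_everywhere(self, rng):
        img = rng.uniform(0, 255, (16, 16))
        assert np.all(apply_gamma(img, 0.9) >= img - 1e-9)

    def test_nonpositive_gamma_rejected(self):
        with pytest.raises(ValueError):
            apply_gamma(np.ones((2, 2)), 0.0)


class TestNlm:
    def test_constant_unchanged(self):
        out = denoise_nlm(np.full((32, 32), 100.0))
        np.testing.assert_allclose(out, 100.0, atol=1e-9)

    def test_noise_variance_reduced(self, rng):
        noisy = 100.0 + rng.normal(0, 10, (32, 32))
        assert denoise_nlm(noisy).var() < noisy.var()

    def test_impulse_attenuated(self):
        img = np.full((25, 25), 100.0)
        img[12, 12] = 150.0
        out = denoise_nlm(img)
        assert out[12, 12] - 100.0 < 0.5 * 50.0

    def test_even_windows_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            denoise_nlm(np.ones((8, 8)), template_window=6)


class TestPatchGrid:
    def test_primary_grid_of_64(self, rng):
        pset = extract_patches(rng.uniform(0, 255, (512, 512)), 64)
        assert len(pset) == 64
        assert pset.coords[0] == (0, 0) and pset.coords[-1] == (7, 7)

    def test_single_patch_identity(self, rng):
        img = rng.uniform(0, 255, (64, 64))
        pset = extract_patches(img, 64)
        assert len(pset) == 1
        np.testing.assert_array_equal(pset.patches[0], img)

    def test_residual_margin_dropped(self, rng):
        pset = extract_patches(rng.uniform(0, 255, (130, 70)), 64)
        assert len(pset) == 2
        assert set(pset.coords) == {(0, 0), (1, 0)}

    def test_oversized_patch_rejected(self):
        with pytest.raises(ValueError):
            extract_patches(np.ones((32, 32)), 64)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(1, 4), st.integers(1, 4), st.integers(2, 8),
           st.integers(0, 2**31 - 1))
    def test_stitch_extract_roundtrip(self, nr, nc, p, seed):
        rng = np.random.default_rng(seed)
        img = rng.uniform(0, 255, (nr * p, nc * p))
        out = stitch_patches(extract_patches(img, p))
        np.testing.assert_array_equal(out, img)

    def test_permuted_tiles_still_stitch(self, rng):
        img = rng.uniform(0, 255, (128, 128))
        pset = extract_patches(img, 64)
        perm = [2, 0, 3, 1]
        shuffled = PatchSet([pset.patches[i] for i in perm],
                            [pset.coords[i] for i in perm],
                            pset.source_size, pset.patch_size)
        np.testing.assert_array_equal(stitch_patches(shuffled), img)

    def test_missing_tile_reported(self, rng):
        pset = extract_patches(rng.uniform(0, 255, (128, 128)), 64)
        broken = PatchSet(pset.patches[:-1], pset.coords[:-1],
                          pset.source_size, pset.patch_size)
        with pytest.raises(ValueError, match=r"\(1, 1\)"):
            stitch_patches(broken)


class TestAugment:
    def _pair(self, rng, n=4):
        imgs = [rng.uniform(0, 255, (8, 8)) for _ in range(n)]
        msks = [(rng.uniform(0, 1, (8, 8)) > 0.9).astype(np.uint8)
                for _ in range(n)]
        mk = lambda lst: PatchSet(lst, [(0, i) for i in range(n)], (8, 8 * n), 8)
        return mk(imgs), mk(msks)

    def test_default_spec_quadruples(self, rng):
        p, m = self._pair(rng)
        ap, am = augment(p, m)
        assert len(ap) == 4 * len(p) and len(am) == 4 * len(m)

    def test_ops_are_involutions_or_order_four(self, rng):
        a = rng.uniform(0, 255, (6, 6))
        assert np.array_equal(a[:, ::-1][:, ::-1], a)
        assert np.array_equal(a[::-1][::-1], a)
        r = a
        for _ in range(4):
            r = np.rot90(r)
        assert np.array_equal(r, a)

    def test_hflip_moves_lesion_to_mirrored_column(self):
        msk = np.zeros((8, 8), np.uint8)
        msk[3, 2] = 1
        img = msk.astype(float) * 255
        p = PatchSet([img], [(0, 0)], (8, 8), 8)
        m = PatchSet([msk], [(0, 0)], (8, 8), 8)
        _, am = augment(p, m, AugmentSpec(ops=("hflip",)))
        flipped = am.patches[1]
        assert flipped[3, 8 - 1 - 2] == 1 and flipped.sum() == 1

    def test_lesion_count_invariant_under_every_op(self, rng):
        p, m = self._pair(rng)
        ap, am = augment(p, m)
        for i in range(len(p)):
            base = m.patches[i].sum()
            for k in range(4):
                assert am.patches[4 * i + k].sum() == base

    def test_misaligned_inputs_rejected(self, rng):
        p, m = self._pair(rng)
        short = PatchSet(m.patches[:-1], m.coords[:-1], m.source_size, 8)
        with pytest.raises(ValueError, match="misaligned"):
            augment(p, short)


class TestFullChain:
    def test_stage_order_logged(self, small_fundus):
        img, _ = small_fundus
        log = []
        preprocess(img, PreprocessConfig(target_size=128), log=log)
        assert log == ["crop", "resize", "green", "clahe", "gamma", "nlm"]

    def test_output_shape_and_range(self, small_fundus):
        img, _ = small_fundus
        out = preprocess(img, PreprocessConfig(target_size=128))
        assert out.shape == (128, 128)
        assert out.min() >= 0.0 and out.max() <= 255.0

    def test_composition_equals_manual_chaining(self, small_fundus):
        from masegnet.preprocess import (apply_clahe, apply_gamma,
                                         crop_border, denoise_nlm,
                                         extract_green, resize)

        img, _ = small_fundus
        cfg = PreprocessConfig(target_size=128)
        manual = crop_border(img, cfg.crop_threshold)
        manual = resize(manual, (128, 128))
        manual = extract_green(manual)
        manual = apply_clahe(manual, cfg.clahe_tiles, cfg.clahe_clip)
        manual = apply_gamma(manual, cfg.gamma)
        manual = denoise_nlm(manual, cfg.nlm_strength,
                             cfg.nlm_template_window, cfg.nlm_search_window)
        np.testing.assert_array_equal(preprocess(img, cfg), manual)
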