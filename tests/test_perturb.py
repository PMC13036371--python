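"""Bit-exact semantics of the photometric perturbation engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from photosense.perturb import (
    ENHANCE_KINDS,
    FactorSample,
    apply_perturbation,
    enhance,
    hsv8_to_rgb,
    hue_shift_amount,
    resize_image,
    rgb_to_hsv8,
    round_half_away,
    shift_hue,
)


def random_image(seed, shape=(32, 32, 3)):
    return np.random.default_rng(seed).integers(0, 256, shape, dtype=np.uint8)


class TestResize:
    def test_same_size_is_byte_identity(self):
        img = random_image(0, (128, 128, 3))
        np.testing.assert_array_equal(resize_image(img, 128), img)

    def test_constant_color_preserved(self):
        img = np.full((256, 256, 3), (13, 200, 77), dtype=np.uint8)
        out = resize_image(img, 128)
        assert out.shape == (128, 128, 3)
        np.testing.assert_array_equal(out, np.full((128, 128, 3), (13, 200, 77), np.uint8))

    def test_checkerboard_downscale_averages_blocks(self):
        """Exact 2x downscale of a checkerboard gives per-block means (127.5 -> 128)."""
        cb = np.zeros((4, 4, 3), np.uint8)
        cb[::2, 1::2] = 255
        cb[1::2, ::2] = 255
        np.testing.assert_array_equal(resize_image(cb, 2), np.full((2, 2, 3), 128, np.uint8))

    def test_block_mean_on_general_blocks(self):
        img = np.zeros((4, 4, 3), np.uint8)
        img[:2, :2] = 100
        img[:2, 2:] = 40
        img[2:, :2] = 200
        img[2:, 2:] = 8
        out = resize_image(img, 2)
        np.testing.assert_array_equal(out[..., 0], [[100, 40], [200, 8]])

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            resize_image(np.zeros((0, 4, 3), np.uint8))


class TestEnhance:
    @pytest.mark.parametrize("kind", ENHANCE_KINDS)
    def test_factor_one_is_byte_identity(self, kind):
        img = random_image(1)
        np.testing.assert_array_equal(enhance(img, kind, 1.0), img)

    def test_brightness_scales_constant_image(self):
        img = np.full((8, 8, 3), 100, np.uint8)
        np.testing.assert_array_equal(enhance(img, "brightness", 0.5),
                                      np.full((8, 8, 3), 50, np.uint8))

    def test_brightness_clips_at_255(self):
        img = np.full((8, 8, 3), 200, np.uint8)
        np.testing.assert_array_equal(enhance(img, "brightness", 1.5),
                                      np.full((8, 8, 3), 255, np.uint8))

    def test_sharpness_fixes_constant_images(self):
        img = np.full((8, 8, 3), 100, np.uint8)
        np.testing.assert_array_equal(enhance(img, "sharpness", 1.9), img)

    def test_contrast_zero_gives_uniform_mean_luma(self):
        img = random_image(2)
        out = enhance(img, "contrast", 0.0)
        assert np.unique(out.reshape(-1, 3), axis=0).shape[0] == 1
        f = img.astype(float)
        luma = np.floor((299 * f[..., 0] + 587 * f[..., 1] + 114 * f[..., 2]) / 1000 + 0.5)
        assert out[0, 0, 0] == np.floor(luma.mean() + 0.5)

    def test_saturation_zero_is_grayscale(self):
        img = random_image(3)
        out = enhance(img, "saturation", 0.0)
        np.testing.assert_array_equal(out[..., 0], out[..., 1])
        np.testing.assert_array_equal(out[..., 1], out[..., 2])

    def test_sharpness_border_ring_copied(self):
        img = random_image(4)
        out = enhance(img, "sharpness", 0.0)
        np.testing.assert_array_equal(out[0, :], img[0, :])
        np.testing.assert_array_equal(out[-1, :], img[-1, :])
        np.testing.assert_array_equal(out[:, 0], img[:, 0])
        np.testing.assert_array_equal(out[:, -1], img[:, -1])

    def test_errors(self):
        img = random_image(5)
        with pytest.raises(ValueError, match=">= 0"):
            enhance(img, "brightness", -0.1)
        with pytest.raises(ValueError, match="unknown"):
            enhance(img, "gamma", 1.0)

    @settings(max_examples=25, deadline=None)
    @given(kind=st.sampled_from(ENHANCE_KINDS),
           factor=st.floats(0.0, 2.0),
           seed=st.integers(0, 100))
    def test_output_always_uint8_in_range(self, kind, factor, seed):
        out = enhance(random_image(seed, (16, 16, 3)), kind, factor)
        assert out.dtype == np.uint8 and out.shape == (16, 16, 3)


class TestHueShift:
    def test_zero_shift_is_byte_identity(self):
        img = random_image(6)
        np.testing.assert_array_equal(shift_hue(img, 0.0), img)

    def test_shift_arithmetic_h240_plus_0p1_wraps_to_10(self):
        """H=240 shifted by +0.1: round(25.5)=26, (240+26) mod 256 = 10."""
        assert hue_shift_amount(0.1) == 26
        hsv = np.array([[[240, 255, 255]]], dtype=np.uint8)
        img = hsv8_to_rgb(hsv)  # exactly representable triple
        np.testing.assert_array_equal(rgb_to_hsv8(img)[0, 0], [240, 255, 255])
        out = shift_hue(img, 0.1)
        np.testing.assert_array_equal(rgb_to_hsv8(out)[0, 0, 0], 10)
        np.testing.assert_array_equal(out, hsv8_to_rgb(np.array([[[10, 255, 255]]], np.uint8)))

    def test_integer_shifts_compose_additively_mod_256(self):
        """On exactly-representable hues, two shifts equal their mod-256 sum."""
        # hues chosen so no intermediate hits the 255<->0 alias of the 8-bit wheel
        H = (np.arange(64).reshape(8, 8) * 3)
        hsv = np.stack([
            H, np.full((8, 8), 255), np.full((8, 8), 255),
        ], axis=2).astype(np.uint8)
        img = hsv8_to_rgb(hsv)
        two_step = shift_hue(shift_hue(img, 0.3), 0.2)
        # round(0.3*255)+round(0.2*255) = 77+51 = 128 = round(0.502*255)
        one_step = shift_hue(img, 128 / 255)
        np.testing.assert_array_equal(two_step, one_step)

    def test_round_trip_restores_hue_channel_and_pixels(self, study_dataset):
        """+d then -d restores H exactly on representable hues; on dermoscopy-like
        images the RGB round trip is within 1 unit per channel."""
        records, _ = study_dataset
        for r in records[:3]:
            back = shift_hue(shift_hue(r.image, 0.1), -0.1)
            assert np.max(np.abs(back.astype(int) - r.image.astype(int))) <= 1

    def test_s_and_v_channels_untouched(self):
        img = random_image(8)
        hsv_in = rgb_to_hsv8(img)
        out_hsv = rgb_to_hsv8(shift_hue(img, 0.25))
        # V is exact under conversion round trips; S within quantization
        np.testing.assert_array_equal(out_hsv[..., 2], hsv_in[..., 2])
        assert np.max(np.abs(out_hsv[..., 1].astype(int) - hsv_in[..., 1].astype(int))) <= 1

    def test_delta_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            shift_hue(random_image(9), 1.5)


class TestPipeline:
    def test_nominal_sample_is_resize_identity(self, study_dataset):
        records, _ = study_dataset
        img = records[0].image
        out = apply_perturbation(img, FactorSample.nominal())
        np.testing.assert_array_equal(out, resize_image(img, 128))

    def test_deterministic_across_runs(self):
        img = random_image(10, (64, 64, 3))
        s = FactorSample(1.3, 0.9, 1.1, 0.7, 0.05)
        np.testing.assert_array_equal(
            apply_perturbation(img, s), apply_perturbation(img, s)
        )

    def test_constant_gray_brightness_arithmetic(self):
        img = np.full((16, 16, 3), 128, np.uint8)
        out = apply_perturbation(img, FactorSample(brightness=1.5), side=16)
        np.testing.assert_array_equal(out, np.full((16, 16, 3), 192, np.uint8))

    def test_stage_order_matters(self, gradient_image):
        """Brightness-then-contrast differs from contrast-then-brightness on a
        gradient: the stages do not commute on quantized data, which is why
        the pipeline order is part of the contract."""
        a = enhance(enhance(gradient_image, "brightness", 1.4), "contrast", 1.2)
        b = enhance(enhance(gradient_image, "contrast", 1.2), "brightness", 1.4)
        assert not np.array_equal(a, b)

    @settings(max_examples=10, deadline=None)
    @given(seed=st.integers(0, 50),
           b=st.floats(0.5, 1.5), c=st.floats(0.8, 1.2),
           sh=st.floats(0.8, 1.2), sa=st.floats(0.5, 1.5),
           h=st.floats(-0.1, 0.1))
    def test_full_pipeline_output_contract(self, seed, b, c, sh, sa, h):
        out = apply_perturbation(
            random_image(seed, (24, 24, 3)), FactorSample(b, c, sh, sa, h), side=16
        )
        assert out.dtype == np.uint8 and out.shape == (16, 16, 3)


def test_round_half_away_from_zero():
    np.testing.assert_array_equal(
        round_half_away(np.array([0.5, 1.5, 2.4, -0.5, -1.5, -2.4])),
        [1.0, 2.0, 2.0, -1.0, -2.0, -2.0],
    )
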