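"""Channel fusion (arithmetic/geometric, with optional 3-D blur) and SNR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from tellimc import (ChannelImage, ImageStack, arithmetic_combine,
                     blur_stack_3d, combine, geometric_combine,
                     generate_phantom, snr)
from tellimc.phantom import PhantomSpec


def _stack(grids, masses):
    return ImageStack([ChannelImage(np.asarray(g, dtype=float), "Te", m)
                       for g, m in zip(grids, masses)])


class TestArithmetic:
    def test_pixelwise_sum(self):
        stack = _stack([[[1.0]], [[2.0]], [[3.0]]], (126, 128, 130))
        assert arithmetic_combine(stack, (126, 128, 130)).pixels[0, 0] == 6.0

    def test_single_channel_is_identity(self):
        stack = _stack([[[4.5]]], (128,))
        assert arithmetic_combine(stack, (128,)).pixels[0, 0] == 4.5

    def test_missing_mass_is_error(self):
        with pytest.raises(KeyError, match="125"):
            arithmetic_combine(_stack([[[1.0]]], (128,)), (125,))


class TestGeometric:
    def test_geometric_mean(self):
        stack = _stack([[[4.0]], [[9.0]]], (126, 128))
        assert geometric_combine(stack, (126, 128)).pixels[0, 0] == \
            pytest.approx(6.0)

    def test_zero_in_any_channel_propagates_to_exact_zero(self):
        stack = _stack([[[0.0]], [[100.0]], [[100.0]]], (126, 128, 130))
        assert geometric_combine(stack, (126, 128, 130)).pixels[0, 0] == 0.0

    def test_idempotent_on_equal_channels(self, rng):
        g = rng.uniform(0, 9, (5, 5))
        stack = _stack([g, g, g], (126, 128, 130))
        np.testing.assert_allclose(
            geometric_combine(stack, (126, 128, 130)).pixels, g, rtol=1e-12)

    def test_negative_input_rejected(self):
        stack = ImageStack([ChannelImage([[-1.0]], "Te", 126,
                                         allow_negative=True),
                            ChannelImage([[1.0]], "Te", 128)])
        with pytest.raises(ValueError, match="non-negative"):
            geometric_combine(stack, (126, 128))

    def test_permutation_invariant_in_channel_list(self, rng):
        grids = rng.uniform(0, 9, (3, 4, 4))
        stack = _stack(grids, (126, 128, 130))
        np.testing.assert_allclose(
            geometric_combine(stack, (126, 128, 130)).pixels,
            geometric_combine(stack, (130, 126, 128)).pixels, rtol=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(hnp.arrays(np.float64, (3, 3, 3),
                      elements=st.floats(0, 1e6, allow_nan=False)))
    def test_am_gm_inequality_pixelwise(self, grids):
        stack = _stack(grids, (126, 128, 130))
        geo = geometric_combine(stack, (126, 128, 130)).pixels
        arith = arithmetic_combine(stack, (126, 128, 130)).pixels / 3.0
        assert np.all(geo <= arith + 1e-9 * np.abs(arith))


class TestBlur3D:
    def test_sigma_zero_is_identity(self, rng):
        grids = rng.uniform(0, 9, (3, 5, 5))
        stack = _stack(grids, (126, 128, 130))
        out = blur_stack_3d(stack, (126, 128, 130), sigma=0.0)
        for ch, g in zip(out, grids):
            np.testing.assert_array_equal(ch.pixels, g)

    def test_constant_stack_unchanged(self):
        stack = _stack([np.full((6, 6), 3.0)] * 3, (126, 128, 130))
        out = blur_stack_3d(stack, (126, 128, 130), sigma=1.0)
        for ch in out:
            np.testing.assert_allclose(ch.pixels, 3.0, rtol=1e-12)

    def test_unit_impulse_mass_is_conserved(self):
        grids = np.zeros((3, 15, 15))
        grids[1, 7, 7] = 1.0
        stack = _stack(grids, (126, 128, 130))
        out = blur_stack_3d(stack, (126, 128, 130), sigma=1.0)
        total = sum(ch.pixels.sum() for ch in out)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_channel_order_matters(self, rng):
        # swapping two neighbours changes who smooths into whom (a pure
        # reversal would not, by symmetry of the reflective kernel)
        grids = rng.uniform(0, 9, (3, 6, 6))
        stack = _stack(grids, (126, 128, 130))
        a = blur_stack_3d(stack, (126, 128, 130), sigma=1.0)
        b = blur_stack_3d(stack, (128, 126, 130), sigma=1.0)
        assert not np.allclose(a.get("Te", 130).pixels,
                               b.get("Te", 130).pixels)

    def test_needs_two_channels(self):
        with pytest.raises(ValueError, match="at least 2"):
            blur_stack_3d(_stack([[[1.0]]], (128,)), (128,), sigma=1.0)


class TestCombineComposition:
    @pytest.mark.parametrize("mode, direct",
                             [("arithmetic", arithmetic_combine),
                              ("geometric", geometric_combine)])
    def test_unblurred_combine_equals_direct_collapse(self, rng, mode, direct):
        grids = rng.uniform(0, 9, (3, 5, 5))
        stack = _stack(grids, (126, 128, 130))
        np.testing.assert_array_equal(
            combine(stack, (126, 128, 130), mode=mode, blur_sigma=0.0).pixels,
            direct(stack, (126, 128, 130)).pixels)

    def test_unknown_mode_rejected(self, rng):
        stack = _stack(rng.uniform(0, 9, (2, 3, 3)), (126, 128))
        with pytest.raises(ValueError, match="mode"):
            combine(stack, (126, 128), mode="harmonic")

    def test_background_accrues_arithmetically_not_geometrically(self):
        # pure-noise phantom: the arithmetic background mean grows with the
        # number of channels; the geometric background mean does not
        spec = PhantomSpec(height=128, width=128, tissue_fraction=0.0,
                           xenon_baseline=5.0, streak_rows=0, seed=9)
        stack, _ = generate_phantom(spec)
        isobars = (124, 126, 128, 130)
        arith_means = [arithmetic_combine(stack, isobars[:k]).pixels.mean()
                       for k in (2, 3, 4)]
        geo_means = [geometric_combine(stack, isobars[:k]).pixels.mean()
                     for k in (2, 3, 4)]
        assert arith_means[0] < arith_means[1] < arith_means[2]
        assert max(geo_means) <= geo_means[0] + 1e-9


class TestSnr:
    def test_mean_over_population_std(self):
        pixels = np.zeros((2, 8))
        pixels[0, :] = 10.0                     # signal row
        pixels[1, :] = [0, 4] * 4               # noise row, std 2 (ddof=0)
        img = ChannelImage(pixels, "Te", 128)
        signal = np.zeros((2, 8), bool)
        signal[0] = True
        result = snr(img, signal, ~signal)
        assert result.snr == 5.0
        assert result.signal_mean == 10.0 and result.noise_std == 2.0

    def test_overlapping_masks_rejected(self):
        img = ChannelImage(np.ones((3, 3)), "Te", 128)
        mask = np.ones((3, 3), bool)
        with pytest.raises(ValueError, match="overlap"):
            snr(img, mask, mask)

    def test_constant_noise_region_is_error_not_infinity(self):
        img = ChannelImage(np.ones((2, 4)), "Te", 128)
        signal = np.zeros((2, 4), bool)
        signal[0] = True
        with pytest.raises(ValueError, match="degenerate"):
            snr(img, signal, ~signal)

    def test_fused_image_beats_every_single_channel(self, corrected_stack,
                                                    snr_masks):
        signal, noise = snr_masks
        fused = combine(corrected_stack, (126, 128, 130), mode="geometric",
                        blur_sigma=1.0)
        best_single = max(
            snr(corrected_stack.get("Te", m), signal, noise).snr
            for m in (126, 128, 130))
        assert snr(fused, signal, noise).snr > best_single
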