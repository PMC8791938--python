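import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import oracles
from conftest import flat_config
from octlayers import (
    BRIGHT_TO_DARK,
    DARK_TO_BRIGHT,
    Polarity,
    ValidationError,
    axial_gradient,
    boundary_enhance,
    denoise,
    generate_bscan,
    large_scale_smooth,
    nonmax_suppress_axial,
)
from octlayers.enhance import EnhancedImage

small_images = arrays(
    dtype=float,
    shape=st.tuples(st.integers(5, 20), st.integers(4, 20)),
    elements=st.floats(0, 1, width=32),
)


class TestDenoise:
    def test_constant_image_unchanged(self):
        img = np.full((10, 10), 0.4)
        assert np.allclose(denoise(img), img)

    def test_impulse_response_is_binomial_kernel(self):
        img = np.zeros((9, 9))
        img[4, 4] = 1.0
        out = denoise(img)
        kernel = np.outer([1, 2, 1], [1, 2, 1]) / 16.0
        assert np.allclose(out[3:6, 3:6], kernel)
        assert out.sum() == pytest.approx(1.0)

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        img = rng.random((12, 12))
        assert np.array_equal(denoise(img), denoise(img))


class TestAxialGradient:
    def test_rising_step_peaks_at_step_row(self):
        col = np.array([0.0, 0, 0, 1, 1, 1])
        img = np.tile(col[:, None], (1, 3))
        out = axial_gradient(img, Polarity.DARK_TO_BRIGHT)
        assert np.allclose(out.pixels[:, 0], [0, 0, 1, 2, 1, 0])

    def test_descending_template_ignores_rising_step(self):
        col = np.array([0.0, 0, 0, 1, 1, 1])
        img = np.tile(col[:, None], (1, 3))
        out = axial_gradient(img, Polarity.BRIGHT_TO_DARK)
        assert np.all(out.pixels == 0)

    def test_constant_image_zero_for_both_polarities(self):
        img = np.full((8, 5), 0.7)
        for pol in Polarity:
            assert np.all(axial_gradient(img, pol).pixels == 0)

    def test_too_short_image_rejected(self):
        with pytest.raises(ValidationError):
            axial_gradient(np.zeros((3, 5)), Polarity.DARK_TO_BRIGHT)

    @given(small_images)
    def test_matches_bruteforce_oracle(self, img):
        for pol in Polarity:
            expected = oracles.bf_axial_gradient(img, pol.template)
            got = axial_gradient(img, pol).pixels
            assert np.allclose(got, expected)


class TestLargeScaleSmooth:
    def test_window_one_is_identity(self):
        rng = np.random.default_rng(1)
        img = rng.random((9, 9))
        assert np.allclose(large_scale_smooth(img, (1, 1)), img)

    def test_constant_invariant(self):
        img = np.full((12, 12), 0.3)
        assert np.allclose(large_scale_smooth(img, (5, 7)), img)

    def test_interior_pixel_is_neighbourhood_mean(self):
        rng = np.random.default_rng(2)
        img = rng.random((9, 9))
        out = large_scale_smooth(img, (3, 3))
        assert out[4, 4] == pytest.approx(img[3:6, 3:6].mean())

    def test_even_window_rounded_up_to_odd(self):
        rng = np.random.default_rng(3)
        img = rng.random((9, 9))
        assert np.allclose(
            large_scale_smooth(img, (2, 2)), large_scale_smooth(img, (3, 3))
        )

    def test_oversized_window_rejected(self):
        with pytest.raises(ValidationError):
            large_scale_smooth(np.zeros((5, 5)), (11, 11))


class TestBoundaryEnhance:
    def test_zero_smooth_annihilates(self):
        g = EnhancedImage(np.random.default_rng(0).random((4, 4)), Polarity.DARK_TO_BRIGHT)
        assert np.all(boundary_enhance(g, np.zeros((4, 4))).pixels == 0)

    def test_ones_smooth_is_identity(self):
        g = EnhancedImage(np.random.default_rng(1).random((4, 4)), Polarity.DARK_TO_BRIGHT)
        assert np.array_equal(boundary_enhance(g, np.ones((4, 4))).pixels, g.pixels)

    def test_hand_multiplication(self):
        g = EnhancedImage(np.array([[2.0, 0], [1, 3]]), Polarity.DARK_TO_BRIGHT)
        s = np.array([[0.5, 1.0], [1.0, 0.5]])
        assert np.array_equal(boundary_enhance(g, s).pixels, [[1.0, 0], [1, 1.5]])

    def test_shape_mismatch_rejected(self):
        g = EnhancedImage(np.zeros((4, 4)), Polarity.DARK_TO_BRIGHT)
        with pytest.raises(ValidationError):
            boundary_enhance(g, np.zeros((5, 4)))


class TestNonmaxSuppressAxial:
    def _peaks(self, col, min_response=0.0):
        img = np.array(col, dtype=float)[:, None]
        enh = EnhancedImage(img, Polarity.DARK_TO_BRIGHT)
        return nonmax_suppress_axial(enh, min_response).flags[:, 0]

    def test_unique_peak_flagged(self):
        assert self._peaks([0, 1, 3, 1, 0], 0.5).tolist() == [
            False, False, True, False, False,
        ]

    def test_monotone_column_has_no_flags(self):
        assert not self._peaks([0, 1, 2, 3, 4]).any()

    def test_plateau_yields_single_topmost_flag(self):
        assert self._peaks([0, 2, 2, 1]).tolist() == [False, True, False, False]

    def test_min_response_suppresses_small_peaks(self):
        assert not self._peaks([0, 1, 3, 1, 0], min_response=3.5).any()

    @given(small_images)
    def test_matches_bruteforce_oracle(self, img):
        enh = EnhancedImage(img, Polarity.DARK_TO_BRIGHT)
        thr = 0.05 * float(img.max()) if img.size else 0.0
        got = nonmax_suppress_axial(enh, thr).flags
        expected = oracles.bf_nonmax_axial(img, thr)
        assert np.array_equal(got, expected)


class TestOnPhantom:
    def test_flat_phantom_peaks_sit_on_truth_boundaries(self, flat_phantom):
        """Per polarity, the flagged rows are exactly that polarity's
        truth boundaries, within one pixel."""
        bscan, truth = flat_phantom
        den = denoise(bscan)
        smooth = large_scale_smooth(den, (9, 9))
        for pol, names in (
            (Polarity.DARK_TO_BRIGHT, DARK_TO_BRIGHT),
            (Polarity.BRIGHT_TO_DARK, BRIGHT_TO_DARK),
        ):
            enh = boundary_enhance(axial_gradient(den, pol), smooth)
            peaks = nonmax_suppress_axial(enh)
            truth_rows = sorted(
                int(round(truth.boundaries[n][0])) for n in names
            )
            for j in range(0, bscan.shape[1], 64):
                flagged = np.flatnonzero(peaks.flags[:, j])
                assert len(flagged) == len(truth_rows)
                assert np.all(np.abs(flagged - np.array(truth_rows)) <= 1)

    def test_enhancement_is_laterally_shift_equivariant(self):
        cfg = flat_config(rng_seed=9, undulation_amplitude=2.0, fovea_depth=25.0)
        bscan, _ = generate_bscan(cfg)
        k = 16
        shifted = np.roll(bscan.pixels, k, axis=1)
        for pol in Polarity:
            a = boundary_enhance(
                axial_gradient(denoise(bscan.pixels), pol),
                large_scale_smooth(denoise(bscan.pixels), (9, 9)),
            ).pixels
            b = boundary_enhance(
                axial_gradient(denoise(shifted), pol),
                large_scale_smooth(denoise(shifted), (9, 9)),
            ).pixels
            # compare away from the lateral borders
            assert np.allclose(np.roll(a, k, axis=1)[:, 2 * k : -2 * k], b[:, 2 * k : -2 * k])
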