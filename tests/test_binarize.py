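"""Adaptive local Gaussian-mean thresholding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from fats.binarize import (
    BinarizationParams,
    binarize,
    kernel_size_px,
    local_threshold_field,
    make_gaussian_kernel,
)
from fats.core import ParameterError, PixelGrid

from conftest import grid, naive_local_gaussian_binarize


class TestGaussianKernel:
    def test_size_one_degenerates_to_identity(self):
        k = make_gaussian_kernel(1)
        assert k.sigma == 0.5
        np.testing.assert_array_equal(k.weights, [[1.0]])

    def test_size_three_matches_direct_evaluation(self):
        k = make_gaussian_kernel(3)
        assert k.sigma == pytest.approx(0.8)
        raw = np.exp(-(np.array([1.0, 0.0, 1.0])[:, None] ** 2
                       + np.array([1.0, 0.0, 1.0])[None, :] ** 2) / (2 * 0.8**2))
        np.testing.assert_allclose(k.weights, raw / raw.sum(), atol=1e-12)

    @pytest.mark.parametrize("size", [1, 3, 5, 9, 33, 65])
    def test_unit_sum_and_radial_symmetry(self, size):
        k = make_gaussian_kernel(size)
        assert abs(k.weights.sum() - 1.0) < 1e-9
        np.testing.assert_array_equal(k.weights, k.weights[::-1, :])
        np.testing.assert_array_equal(k.weights, k.weights[:, ::-1])
        np.testing.assert_array_equal(k.weights, k.weights.T)

    @pytest.mark.parametrize("size", [0, -3, 2, 10])
    def test_rejects_even_or_nonpositive_sizes(self, size):
        with pytest.raises(ParameterError):
            make_gaussian_kernel(size)

    def test_separable_factor_reproduces_weights(self):
        k = make_gaussian_kernel(9)
        np.testing.assert_allclose(
            np.outer(k.weights_1d, k.weights_1d), k.weights, atol=1e-12
        )


class TestKernelSizing:
    @pytest.mark.parametrize(
        "um,pitch,expected",
        [(33, 1.0, 33), (66, 2.0, 33), (33, 0.65, 51), (66, 0.65, 103), (1, 1.0, 3)],
    )
    def test_physical_to_pixel_conversion(self, um, pitch, expected):
        assert kernel_size_px(um, pitch) == expected

    def test_even_rounding_bumps_up_to_odd(self):
        assert kernel_size_px(40, 1.0) == 41

    def test_rejects_nonpositive(self):
        with pytest.raises(ParameterError):
            kernel_size_px(0, 1.0)
        with pytest.raises(ParameterError):
            kernel_size_px(33, -1.0)


class TestThresholdField:
    def test_constant_image_gives_constant_threshold(self):
        img = grid(np.full((16, 16), 77))
        t = local_threshold_field(img, make_gaussian_kernel(5))
        np.testing.assert_allclose(t, 77.0, atol=1e-9)

    def test_single_bright_pixel_center_value(self):
        values = np.zeros((7, 7), dtype=np.uint8)
        values[3, 3] = 255
        k = make_gaussian_kernel(3)
        t = local_threshold_field(grid(values), k)
        assert t[3, 3] == pytest.approx(255.0 * k.weights[1, 1])

    def test_offset_is_pure_subtraction(self, rng):
        img = grid(rng.integers(0, 256, (20, 20), dtype=np.uint8))
        k = make_gaussian_kernel(5)
        np.testing.assert_allclose(
            local_threshold_field(img, k, offset=10.0),
            local_threshold_field(img, k) - 10.0,
            atol=1e-12,
        )

    def test_kernel_larger_than_image_rejected(self):
        with pytest.raises(ParameterError):
            local_threshold_field(grid(np.zeros((4, 4))), make_gaussian_kernel(5))

    def test_threshold_bounded_by_image_range(self, rng):
        img = grid(rng.integers(10, 240, (32, 32), dtype=np.uint8))
        t = local_threshold_field(img, make_gaussian_kernel(9), offset=5.0)
        assert t.min() >= img.values.min() - 5.0 - 1e-9
        assert t.max() <= img.values.max() + 5.0 + 1e-9


class TestBinarize:
    def test_flat_image_yields_empty_mask(self):
        mask = binarize(grid(np.full((20, 20), 128)), BinarizationParams(3.0))
        assert not mask.foreground.any()

    def test_single_bright_pixel_is_sole_foreground(self):
        values = np.zeros((7, 7), dtype=np.uint8)
        values[3, 3] = 255
        mask = binarize(grid(values), BinarizationParams(3.0))
        expected, _ = naive_local_gaussian_binarize(values, 3)
        np.testing.assert_array_equal(mask.values, expected)
        assert mask.values[3, 3] == 255
        assert mask.foreground.sum() == 1

    def test_alphabet_is_exactly_0_255(self, rng):
        img = grid(rng.integers(0, 256, (32, 32), dtype=np.uint8))
        mask = binarize(img, BinarizationParams(5.0))
        assert set(np.unique(mask.values)) <= {0, 255}

    def test_disc_on_sloped_background_recovered(self):
        # bright disc on a strong gradient: the gradient itself must not fire
        yy, xx = np.mgrid[0:128, 0:128]
        bg = 40 + 120 * xx / 127  # sweeps past the disc's absolute level
        img = np.asarray(bg, dtype=np.float64)
        truth = np.hypot(yy - 64, xx - 64) <= 10
        img[truth] += 60
        # a small offset keeps the quantisation staircase of the ramp (and
        # the replicate-padding pull at the steep border) out of the
        # foreground; the disc stands 60 counts proud of it
        mask = binarize(
            grid(np.clip(img, 0, 255).astype(np.uint8)),
            BinarizationParams(33.0, offset=-5.0),
        )
        inter = (mask.foreground & truth).sum()
        dice = 2 * inter / (mask.foreground.sum() + truth.sum())
        assert dice >= 0.9

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        img=arrays(np.uint8, (24, 24), elements=st.integers(0, 255)),
        shift=st.tuples(st.integers(-4, 4), st.integers(-4, 4)),
    )
    def test_translation_equivariance_away_from_borders(self, img, shift):
        dy, dx = shift
        params = BinarizationParams(5.0)
        m1 = binarize(grid(img), params).foreground
        m2 = binarize(grid(np.roll(img, (dy, dx), axis=(0, 1))), params).foreground
        # compare the interior safely inside one kernel radius + shift
        pad = 8
        np.testing.assert_array_equal(
            np.roll(m1, (dy, dx), axis=(0, 1))[pad:-pad, pad:-pad],
            m2[pad:-pad, pad:-pad],
        )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        img=arrays(np.uint8, (16, 16), elements=st.integers(0, 200)),
        k=st.integers(1, 55),
    )
    def test_invariant_to_global_additive_offset(self, img, k):
        params = BinarizationParams(5.0)
        m1 = binarize(grid(img), params)
        m2 = binarize(grid(img.astype(np.int32) + k, dtype=np.uint8), params)
        np.testing.assert_array_equal(m1.values, m2.values)

    @pytest.mark.parametrize("size", [3, 5, 9])
    def test_matches_naive_double_loop(self, rng, size):
        img = rng.integers(0, 256, (32, 32), dtype=np.uint8)
        mask = binarize(grid(img), BinarizationParams(float(size)))
        expected, thresh = naive_local_gaussian_binarize(img, size)
        # exclude knife-edge pixels where float association order could flip
        decisive = np.abs(img.astype(np.float64) - thresh) > 1e-6
        np.testing.assert_array_equal(mask.values[decisive], expected[decisive])
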