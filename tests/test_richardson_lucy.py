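"""Forward convolution model and the Richardson-Lucy update."""

import numpy as np
import pytest

from deglare import (
    GSFKernel,
    RLState,
    build_kernel,
    convolve,
    convolve_direct,
    rl_deconvolve,
    rl_step,
    siemens_star,
    ssim,
    StarSpec,
)

DPP = 45.0 / 400.0


def delta_kernel():
    return build_kernel((64, 64), 0.0, DPP)


def toy_kernel(weights):
    w = np.asarray(weights, dtype=float)
    return GSFKernel(w / w.sum(), DPP, 1.0, 1.0)


def brute_force_convolve(image, weights):
    """Nested-loop spatial convolution with replicate padding (oracle)."""
    kh, kw = weights.shape
    ph, pw = kh // 2, kw // 2
    padded = np.pad(image, ((ph, ph), (pw, pw)), mode="edge")
    out = np.zeros_like(image, dtype=float)
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            acc = 0.0
            for a in range(kh):
                for b in range(kw):
                    # correlation with the flipped kernel = convolution
                    acc += weights[kh - 1 - a, kw - 1 - b] * padded[i + a, j + b]
            out[i, j] = acc
    return out


class TestConvolve:
    def test_delta_kernel_is_identity(self):
        rng = np.random.default_rng(0)
        image = rng.random((32, 32))
        np.testing.assert_allclose(convolve(image, delta_kernel()), image, atol=1e-12)

    def test_constant_image_preserved(self):
        kernel = build_kernel((64, 64), 2.0, DPP)
        image = np.full((64, 64), 0.37)
        np.testing.assert_allclose(convolve(image, kernel), image, atol=1e-9)

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(1)
        image = rng.random((5, 5))
        weights = rng.random((3, 3))
        kernel = toy_kernel(weights)
        np.testing.assert_allclose(
            convolve(image, kernel),
            brute_force_convolve(image, kernel.weights),
            atol=1e-10,
        )

    @pytest.mark.parametrize("shape", [(8, 8), (16, 16), (11, 13)])
    def test_fft_equals_direct_path(self, shape):
        rng = np.random.default_rng(2)
        image = rng.random(shape)
        weights = rng.random((5, 5))
        kernel = toy_kernel(weights)
        np.testing.assert_allclose(
            convolve(image, kernel), convolve_direct(image, kernel), atol=1e-10
        )

    def test_flux_conserved_for_interior_support(self):
        image = np.zeros((120, 120))
        image[40:80, 40:80] = 0.7
        kernel = build_kernel(image.shape, 2.0, DPP)
        out = convolve(image, kernel)
        assert abs(out.sum() - image.sum()) / image.sum() < 1e-3

    def test_negative_image_rejected(self):
        with pytest.raises(ValueError):
            convolve(np.full((8, 8), -1.0), delta_kernel())


class TestRLStep:
    def test_delta_kernel_recovers_observed_in_one_step(self):
        rng = np.random.default_rng(3)
        observed = rng.random((16, 16)) + 0.1
        estimate = rng.random((16, 16)) + 0.1
        state = rl_step(RLState(estimate), observed, delta_kernel())
        np.testing.assert_allclose(state.estimate, observed, atol=1e-12)
        assert state.iteration == 1

    def test_constant_fixed_point(self):
        kernel = build_kernel((64, 64), 1.0, DPP)
        image = np.full((64, 64), 0.5)
        state = rl_step(RLState(image), image, kernel)
        np.testing.assert_allclose(state.estimate, image, atol=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rl_step(RLState(np.ones((8, 8))), np.ones((9, 9)), delta_kernel())

    def test_iterates_stay_non_negative(self):
        rng = np.random.default_rng(4)
        observed = rng.random((48, 48))
        kernel = build_kernel(observed.shape, 2.0, DPP)
        state = RLState(observed)
        for _ in range(25):
            state = rl_step(state, observed, kernel)
            assert np.all(state.estimate >= 0)

    def test_error_decreases_on_selfconsistent_degradation(self, small_star):
        kernel = build_kernel(small_star.shape, 2.0, 45.0 / 128.0)
        observed = convolve(small_star, kernel)
        state = RLState(observed)
        errors = []
        for _ in range(50):
            state = rl_step(state, observed, kernel)
            errors.append(np.abs(state.estimate - small_star).sum())
        assert np.all(np.diff(errors) < 0)


class TestRLDeconvolve:
    def test_delta_kernel_returns_observed(self):
        rng = np.random.default_rng(5)
        observed = rng.random((16, 16))
        np.testing.assert_allclose(
            rl_deconvolve(observed, delta_kernel(), 7), observed, atol=1e-12
        )

    def test_zero_image_is_fixed_point(self):
        kernel = build_kernel((32, 32), 1.0, DPP)
        out = rl_deconvolve(np.zeros((32, 32)), kernel, 5)
        np.testing.assert_array_equal(out, 0.0)

    def test_restoration_beats_degradation_in_ssim(self, small_star):
        kernel = build_kernel(small_star.shape, 2.0, 45.0 / 128.0)
        observed = convolve(small_star, kernel)
        restored = np.clip(rl_deconvolve(observed, kernel, 40), 0, 1)
        assert (
            ssim(restored, small_star).index
            > ssim(np.clip(observed, 0, 1), small_star).index
        )

    def test_ssim_nondecreasing_over_early_iterations(self, small_star):
        kernel = build_kernel(small_star.shape, 2.0, 45.0 / 128.0)
        observed = convolve(small_star, kernel)
        state = RLState(observed)
        scores = []
        for _ in range(20):
            state = rl_step(state, observed, kernel)
            scores.append(ssim(np.clip(state.estimate, 0, 1), small_star).index)
        assert np.all(np.diff(scores) >= 0)

    def test_invalid_iteration_count(self):
        with pytest.raises(ValueError):
            rl_deconvolve(np.ones((8, 8)), delta_kernel(), 0)

    def test_flux_conserved_over_many_iterations(self, small_star):
        image = np.zeros((120, 120))
        image[30:90, 30:90] = 0.6
        kernel = build_kernel(image.shape, 1.0, DPP)
        observed = convolve(image, kernel)
        state = RLState(observed)
        for _ in range(100):
            state = rl_step(state, observed, kernel)
        assert abs(state.estimate.sum() - observed.sum()) / observed.sum() < 1e-3
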