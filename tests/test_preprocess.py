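"""Phase correction, averaging, noise-map estimation and trace images."""

import numpy as np
import pytest

from dwisure import (NoiseMap, accept_external_noise_map, average_repetitions,
                     lowfreq_phase, magnitude_average,
                     noise_map_from_repetitions, phase_correct, trace_image)
from dwisure.preprocess import InsufficientRepetitionsError, preprocess_stack


class TestLowfreqPhase:
    def test_constant_image_gives_constant_phase(self):
        img = 3.0 * np.exp(1j * 0.7) * np.ones((20, 20))
        phi = lowfreq_phase(img, kernel=5)
        np.testing.assert_allclose(phi, 0.7, atol=1e-12)

    def test_kernel_one_returns_pixelwise_phase(self, rng):
        img = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
        np.testing.assert_array_equal(lowfreq_phase(img, kernel=1),
                                      np.angle(img))

    def test_linear_ramp_recovered_in_interior(self):
        """A boxcar average of a linear function is the function itself."""
        h = w = 64
        yy, xx = np.mgrid[0:h, 0:w]
        ramp = 0.01 * xx + 0.005 * yy
        img = np.exp(1j * ramp)
        phi = lowfreq_phase(img, kernel=15)
        interior = (slice(10, -10), slice(10, -10))
        np.testing.assert_allclose(phi[interior], ramp[interior], atol=1e-6)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            lowfreq_phase(np.ones((4, 4), complex), kernel=4)


class TestPhaseCorrect:
    def test_real_positive_image_unchanged(self):
        img = np.full((10, 10), 2.5, dtype=complex)
        re, im = phase_correct(img, kernel=3)
        np.testing.assert_allclose(re, 2.5, atol=1e-12)
        np.testing.assert_allclose(im, 0.0, atol=1e-12)

    def test_global_phase_rotated_out(self):
        mag = np.linspace(1, 2, 64).reshape(8, 8)
        img = mag * np.exp(1j * 1.1)
        re, im = phase_correct(img, kernel=5)
        np.testing.assert_allclose(re, mag, atol=1e-10)
        np.testing.assert_allclose(im, 0.0, atol=1e-10)

    def test_noise_distribution_preserved(self, rng):
        """Rotation is unitary: corrected real noise keeps std sigma."""
        sigma = 0.3
        mag = np.full((24, 24), 5.0)
        phase = 0.8
        draws = []
        for _ in range(400):
            noise = sigma * (rng.normal(size=(24, 24))
                             + 1j * rng.normal(size=(24, 24)))
            re, _ = phase_correct(mag * np.exp(1j * phase) + noise, kernel=9)
            draws.append(re)
        emp_std = np.stack(draws).std(axis=0, ddof=1)
        assert abs(emp_std.mean() / sigma - 1.0) < 0.05


class TestAveraging:
    def test_single_repetition_identity(self, rng):
        x = rng.normal(size=(1, 6, 6))
        assert np.array_equal(average_repetitions(x).values, x[0])

    def test_opposite_pair_cancels(self, rng):
        a = rng.normal(size=(6, 6))
        out = average_repetitions(np.stack([a, -a]))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-15)

    def test_averaging_shrinks_noise_by_sqrt_n(self, rng):
        sigma, n = 0.5, 16
        clean = np.ones((32, 32))
        errs = []
        for _ in range(300):
            stack = clean + sigma * rng.normal(size=(n, 32, 32))
            errs.append(average_repetitions(stack).values - clean)
        emp = np.stack(errs).std(ddof=1)
        assert abs(emp / (sigma / np.sqrt(n)) - 1.0) < 0.05

    def test_magnitude_average_noise_free(self, rng):
        mag = np.abs(rng.normal(size=(7, 7))) + 1.0
        stack = np.stack([mag * np.exp(1j * 0.3)] * 4)
        np.testing.assert_allclose(magnitude_average(stack), mag, atol=1e-12)

    def test_magnitude_average_has_rayleigh_floor(self, rng):
        """Zero-signal magnitude mean -> sigma*sqrt(pi/2), above complex avg."""
        sigma, n = 0.2, 12
        noise = sigma * (rng.normal(size=(n, 64, 64))
                        + 1j * rng.normal(size=(n, 64, 64)))
        mag_bg = magnitude_average(noise).mean()
        cplx_bg = np.abs(noise.mean(axis=0)).mean()
        assert abs(mag_bg / (sigma * np.sqrt(np.pi / 2)) - 1.0) < 0.02
        assert mag_bg > cplx_bg


class TestNoiseMap:
    def test_identical_repetitions_zero_map(self):
        stack = np.ones((5, 8, 8))
        nmap = noise_map_from_repetitions(stack, blur_sigma=0)
        np.testing.assert_array_equal(nmap.sigma, 0.0)

    def test_recovers_sigma_over_sqrt_n(self, rng):
        sigma, n = 0.4, 12
        stack = sigma * rng.normal(size=(n, 128, 128))
        nmap = noise_map_from_repetitions(stack, blur_sigma=0)
        assert abs(nmap.sigma.mean() / (sigma / np.sqrt(n)) - 1.0) < 0.05

    def test_blur_leaves_constant_map_unchanged(self):
        stack = np.stack([np.zeros((16, 16)), np.full((16, 16), 2.0)])
        flat = noise_map_from_repetitions(stack, blur_sigma=0)
        blurred = noise_map_from_repetitions(stack, blur_sigma=10)
        np.testing.assert_allclose(blurred.sigma, flat.sigma, rtol=1e-10)

    def test_single_repetition_raises_directing_to_external(self):
        with pytest.raises(InsufficientRepetitionsError, match="external"):
            noise_map_from_repetitions(np.ones((1, 8, 8)))

    def test_external_map_passthrough_and_scaling(self):
        sigma0 = np.full((8, 8), 0.6)
        out = accept_external_noise_map(sigma0, scale=1.0)
        assert out.provenance == "external"
        np.testing.assert_array_equal(out.sigma, sigma0)
        scaled = accept_external_noise_map(sigma0, scale=1 / np.sqrt(12))
        np.testing.assert_allclose(scaled.sigma, 0.6 / np.sqrt(12))

    def test_external_map_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            accept_external_noise_map(np.ones((4, 4)), expected_shape=(8, 8))

    def test_external_route_agrees_with_repetition_route(self, small_phantom):
        """Supplying the true sigma-map externally matches the
        repetition-derived estimate up to sampling and blur tolerance."""
        _, truth, stack = small_phantom
        from dwisure import phase_correct as pc
        reps = stack.repetitions(1000.0, 0)
        corrected = np.stack([pc(r)[0] for r in reps])
        derived = noise_map_from_repetitions(corrected, blur_sigma=3)
        n = reps.shape[0]
        external = accept_external_noise_map(truth.sigma_map,
                                             scale=1 / np.sqrt(n))
        ratio = derived.sigma.mean() / external.sigma.mean()
        assert abs(ratio - 1.0) < 0.15


class TestTraceImage:
    def test_identical_directions_identity(self, rng):
        img = np.abs(rng.normal(size=(9, 9)))
        np.testing.assert_allclose(trace_image([img, img, img]), img)

    @pytest.mark.parametrize("values,expected", [
        ((1.0, 4.0), 2.0),
        ((1.0, 8.0, 27.0), 6.0),
    ])
    def test_geometric_mean_closed_form(self, values, expected):
        imgs = [np.full((3, 3), v) for v in values]
        np.testing.assert_allclose(trace_image(imgs), expected)

    def test_permutation_invariant_and_homogeneous(self, rng):
        imgs = [np.abs(rng.normal(size=(6, 6))) for _ in range(3)]
        t1 = trace_image(imgs)
        t2 = trace_image(imgs[::-1])
        np.testing.assert_allclose(t1, t2)
        np.testing.assert_allclose(trace_image([3.0 * im for im in imgs]),
                                   3.0 * t1, rtol=1e-12)

    def test_negative_pixels_clipped(self):
        a = np.full((2, 2), -1.0)
        b = np.full((2, 2), 4.0)
        np.testing.assert_array_equal(trace_image([a, b]), 0.0)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            trace_image([])


def test_preprocess_stack_bundle_layout(small_phantom):
    cfg, _, stack = small_phantom
    bundle = preprocess_stack(stack, kernel=7, blur_sigma=3)
    assert bundle.b_values == (50.0, 1000.0)
    img = bundle.image(1000.0, 0)
    assert img.values.shape == (32, 32)
    assert img.n_repetitions_used == 12
    nmap = bundle.noise_map(1000.0, 1)
    assert nmap.sigma.shape == (32, 32)
    assert np.all(nmap.sigma >= 0)
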