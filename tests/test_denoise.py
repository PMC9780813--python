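"""Wavelet denoiser: reconstruction identities, threshold arithmetic,
straight-line oracle equivalence, and the cohort SNR benchmark."""

import numpy as np
import pytest
import pywt
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgspect import (
    BeatTemplate,
    DenoiseConfig,
    NoiseSpec,
    compute_threshold,
    decompose,
    denoise_signal,
    estimate_sigma,
    generate_record,
    threshold_coeffs,
)
from ecgspect.denoise import reconstruct
from ecgspect.synth import clean_components


class TestDecompose:
    def test_zero_series_gives_zero_coefficients(self):
        d = decompose(np.zeros(128))
        assert np.all(d.approx == 0) and np.all(d.detail == 0)

    def test_perfect_reconstruction(self, rng):
        x = rng.normal(size=1000)
        d = decompose(x)
        err = np.sqrt(np.mean((reconstruct(d) - x) ** 2))
        assert err < 1e-8

    @pytest.mark.parametrize("n", [64, 100, 101, 1000])
    def test_coefficient_lengths_match_filterbank_oracle(self, n, rng):
        # reference: periodized circular convolution + dyadic downsampling
        x = rng.normal(size=n)
        d = decompose(x)
        w = pywt.Wavelet("bior3.1")
        half = (n + 1) // 2
        ext = np.concatenate([x, x[: w.dec_len]])  # circular extension
        conv = np.convolve(ext, w.dec_lo[::-1])[: 2 * half : 2]
        assert len(d.approx) == len(conv) == half
        assert len(d.detail) == half

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            decompose(np.ones(3))


class TestEstimateSigma:
    def test_zero_coefficients_give_zero(self):
        d = decompose(np.zeros(64))
        assert estimate_sigma(d) == 0.0

    def test_mean_abs_dev_example(self):
        from ecgspect.denoise import WaveletDecomposition

        c = np.array([0.6745, -0.6745])
        d = WaveletDecomposition(c, c, input_length=4)
        # mean is 0, mean |c| is 0.6745, divided by the 0.6745 constant
        assert estimate_sigma(d, "mean_abs_dev") == pytest.approx(1.0)

    def test_mad_estimator_consistent_for_gaussian(self):
        rng = np.random.default_rng(42)
        from ecgspect.denoise import WaveletDecomposition

        c = rng.normal(0, 2.0, 10_000)
        d = WaveletDecomposition(c[:5000], c[5000:], input_length=10_000)
        assert estimate_sigma(d, "median_abs_dev") == pytest.approx(2.0, rel=0.05)

    def test_unknown_estimator_rejected(self):
        d = decompose(np.ones(64))
        with pytest.raises(ValueError, match="estimator"):
            estimate_sigma(d, "mode_abs_dev")


class TestComputeThreshold:
    def test_zero_sigma_gives_zero(self):
        assert compute_threshold(0.0, 1000) == 0.0

    def test_length_one_gives_zero_either_variant(self):
        assert compute_threshold(1.0, 1, use_sqrt=True) == 0.0
        assert compute_threshold(1.0, 1, use_sqrt=False) == 0.0

    def test_universal_threshold_value(self):
        assert compute_threshold(1.0, 1000) == pytest.approx(
            np.sqrt(2 * np.log(1000)), abs=1e-6
        )

    def test_sqrt_free_variant(self):
        assert compute_threshold(1.0, 1000, use_sqrt=False) == pytest.approx(
            2 * np.log(1000)
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compute_threshold(1.0, 0)
        with pytest.raises(ValueError):
            compute_threshold(-1.0, 10)


class TestThresholdCoeffs:
    def test_zero_threshold_is_identity_for_soft_rule(self, rng):
        d = decompose(rng.normal(size=128))
        out = threshold_coeffs(d, 0.0, "soft")
        np.testing.assert_allclose(out.approx, d.approx)
        np.testing.assert_allclose(out.detail, d.detail)

    def test_soft_rule_examples(self):
        from ecgspect.denoise import WaveletDecomposition

        d = WaveletDecomposition(np.array([5.0]), np.array([-1.5]), input_length=2)
        out = threshold_coeffs(d, 2.0, "soft")
        assert out.approx[0] == pytest.approx(3.0)
        assert out.detail[0] == 0.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_soft_rule_matches_elementwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        c = rng.normal(0, 3, 64)
        t = float(rng.uniform(0, 4))
        from ecgspect.denoise import WaveletDecomposition

        d = WaveletDecomposition(c[:32], c[32:], input_length=64)
        out = np.concatenate([threshold_coeffs(d, t).approx, threshold_coeffs(d, t).detail])
        expect = np.array([np.sign(v) * max(abs(v) - t, 0.0) for v in c])
        np.testing.assert_allclose(out, expect, atol=1e-12)

    def test_hard_rule_and_details_only(self):
        from ecgspect.denoise import WaveletDecomposition

        d = WaveletDecomposition(np.array([0.5, 4.0]), np.array([0.5, -4.0]), input_length=4)
        out = threshold_coeffs(d, 1.0, "hard")
        np.testing.assert_array_equal(out.approx, [0.0, 4.0])
        np.testing.assert_array_equal(out.detail, [0.0, -4.0])
        spared = threshold_coeffs(d, 1.0, "hard", details_only=True)
        np.testing.assert_array_equal(spared.approx, d.approx)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            threshold_coeffs(decompose(np.ones(16)), -0.1)

    def test_soft_rule_is_nonexpansive_and_monotone(self, rng):
        d = decompose(rng.normal(size=256))
        prev = np.inf
        for t in (0.0, 0.5, 1.0, 2.0):
            out = threshold_coeffs(d, t)
            mags = np.abs(np.concatenate([out.approx, out.detail]))
            assert np.all(mags <= np.abs(d.pooled) + 1e-15)
            energy = float(np.sum(mags**2))
            assert energy <= prev + 1e-12
            prev = energy


class TestDenoiseSignal:
    def test_zero_signal_fixed_point(self):
        out = denoise_signal(np.zeros(512))
        assert np.all(out.samples == 0)
        assert out.sigma == 0.0 and out.threshold == 0.0

    def test_matches_straight_line_reference(self, rng):
        x = rng.normal(size=1000)
        cfg = DenoiseConfig()
        got = denoise_signal(x, cfg).samples
        # independent straight-line evaluation of the five-step procedure
        cA, cD = pywt.dwt(x, "bior3.1", mode="periodization")
        pooled = np.concatenate([cA, cD])
        sigma = np.mean(np.abs(pooled - np.mean(pooled))) / 0.6745
        thr = sigma * np.sqrt(2 * np.log(x.size))
        fA = pywt.threshold(cA, thr, "soft")
        fD = pywt.threshold(cD, thr, "soft")
        ref = pywt.idwt(fA, fD, "bior3.1", mode="periodization")[: x.size]
        assert np.sqrt(np.mean((got - ref) ** 2)) < 1e-8

    def test_output_length_preserved_odd_input(self, rng):
        x = rng.normal(size=333)
        assert denoise_signal(x).samples.size == 333

    def test_white_noise_snr_strictly_improves_details_only(self, beat_template):
        from ecgspect.synth import white_noise_std_for_snr

        clean = clean_components(beat_template, "normal", 10.0, 100.0)
        std = white_noise_std_for_snr(clean, 10.0)
        rng = np.random.default_rng(5)
        noise = rng.normal(0, std, clean.size)
        cfg = DenoiseConfig(details_only=True)
        out = denoise_signal(clean + noise, cfg).samples
        snr_in = 10 * np.log10(np.mean(clean**2) / np.mean(noise**2))
        snr_out = 10 * np.log10(np.mean(clean**2) / np.mean((out - clean) ** 2))
        assert snr_out > snr_in
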