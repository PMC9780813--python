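"""Frequency deletion: grid arithmetic, conjugate symmetry, brute-force
equivalence of the shortened inverse transform."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgspect import count_retained_bins, filter_frequencies, spectrum


class TestSpectrum:
    def test_constant_series_has_only_dc(self):
        view = spectrum(np.full(100, 2.5), 100.0)
        assert view.values[0] == pytest.approx(250.0)
        assert np.abs(view.values[1:]).max() < 1e-9

    def test_unit_impulse_is_flat(self):
        x = np.zeros(64)
        x[0] = 1.0
        view = spectrum(x, 100.0)
        np.testing.assert_allclose(view.values, np.ones(64), atol=1e-12)

    def test_frequency_grid(self):
        view = spectrum(np.zeros(1000), 100.0)
        assert view.freqs[1] == pytest.approx(0.1)
        assert view.freqs[20] == pytest.approx(2.0)

    def test_inverse_reproduces_series(self, rng):
        x = rng.normal(size=257)
        view = spectrum(x, 50.0)
        back = np.fft.ifft(view.values).real
        assert np.sqrt(np.mean((back - x) ** 2)) < 1e-10

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            spectrum(np.array([]), 100.0)


class TestBinCounting:
    def test_symmetric_2hz_count_is_41(self):
        assert count_retained_bins(1000, 100.0, 2.0, "symmetric") == 41

    def test_positive_only_count_is_521(self):
        assert count_retained_bins(1000, 100.0, 2.0, "positive_only") == 521

    def test_cutoff_at_nyquist_keeps_all(self):
        assert count_retained_bins(1000, 100.0, 50.0) == 1000
        assert count_retained_bins(1000, 100.0, 80.0) == 1000

    @given(
        st.integers(10, 200),
        st.floats(10.0, 500.0),
        st.floats(0.5, 60.0),
        st.sampled_from(["symmetric", "positive_only"]),
    )
    @settings(max_examples=80, deadline=None)
    def test_count_matches_grid_enumeration(self, n, fs, cutoff, mode):
        freqs = [fs * k / n if k <= (n - 1) // 2 else fs * (k - n) / n for k in range(n)]
        if mode == "symmetric":
            expect = sum(1 for f in freqs if not abs(f) > cutoff)
        else:
            expect = sum(1 for f in freqs if not f > cutoff)
        assert count_retained_bins(n, fs, cutoff, mode) == expect

    def test_count_monotone_in_cutoff(self):
        ks = [count_retained_bins(500, 100.0, c) for c in np.linspace(0.5, 50, 40)]
        assert all(a <= b for a, b in zip(ks, ks[1:]))


class TestFilterFrequencies:
    def test_cutoff_at_or_above_nyquist_is_identity(self, rng):
        x = rng.normal(size=512)
        out = filter_frequencies(x, 100.0, cutoff=50.0)
        assert out.k == 512
        assert np.sqrt(np.mean((out.samples - x) ** 2)) < 1e-9

    def test_2hz_reduction_length(self, rng):
        out = filter_frequencies(rng.normal(size=1000), 100.0, cutoff=2.0)
        assert out.k == 41
        assert out.samples.size == 41
        assert out.implied_fs == pytest.approx(4.1)

    def test_pure_out_of_band_tone_removed(self):
        t = np.arange(1000) / 100.0
        x = np.sin(2 * np.pi * 10.0 * t)
        out = filter_frequencies(x, 100.0, cutoff=2.0)
        assert np.sqrt(np.mean(out.samples**2)) < 1e-9 * np.sqrt(np.mean(x**2))

    def test_symmetric_output_real_for_real_input(self, rng):
        x = rng.normal(size=600)
        out = filter_frequencies(x, 100.0, cutoff=3.3)
        assert np.isrealobj(out.samples)

    def test_positive_only_output_complex(self, rng):
        out = filter_frequencies(rng.normal(size=100), 100.0, 2.0, mode="positive_only")
        assert np.iscomplexobj(out.samples)
        assert out.k == count_retained_bins(100, 100.0, 2.0, "positive_only")

    def test_bin_exactly_at_cutoff_retained(self):
        # N=100, fs=100: bins at integer Hz; cutoff 2.0 keeps the 2 Hz bin
        t = np.arange(100) / 100.0
        x = np.sin(2 * np.pi * 2.0 * t)
        out = filter_frequencies(x, 100.0, cutoff=2.0)
        assert np.sqrt(np.mean(out.samples**2)) > 0.1

    def test_normalize_flag_preserves_dc_amplitude(self):
        x = np.full(500, 1.7)
        out = filter_frequencies(x, 100.0, cutoff=2.0, normalize=True)
        assert out.samples[0] == pytest.approx(1.7)

    def test_reduced_spectrum_has_no_out_of_band_content(self, rng):
        x = rng.normal(size=1000)
        out = filter_frequencies(x, 100.0, cutoff=2.0)
        # re-transform the 41-sample series at its implied rate
        view = spectrum(out.samples, out.implied_fs)
        assert np.abs(view.freqs).max() <= 2.0 + 1e-9

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError, match="cutoff"):
            filter_frequencies(np.ones(10), 100.0, cutoff=0.0)

    @given(st.integers(10, 200), st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_matches_bin_deletion_plus_direct_dft_sum(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        fs = float(rng.uniform(10, 500))
        cutoff = float(rng.uniform(0.5, fs / 2))
        out = filter_frequencies(x, fs, cutoff=cutoff)
        # brute force: explicit deletion loop + O(k^2) inverse-DFT summation
        xt = np.fft.fft(x)
        freqs = np.fft.fftfreq(n, d=1.0 / fs)
        kept = [xt[i] for i in range(n) if not abs(freqs[i]) > cutoff]
        k = len(kept)
        direct = np.array(
            [sum(kept[m] * np.exp(2j * np.pi * m * j / k) for m in range(k)) / k
             for j in range(k)]
        )
        assert out.k == k
        np.testing.assert_allclose(out.samples, direct.real, atol=1e-8)
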