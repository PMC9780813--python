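"""Frequency-deletion data reduction.

A low-frequency band is retained by *deleting* FFT bins above a cutoff
(default 2 Hz) rather than zeroing them, and inverse-transforming the
shortened spectrum at its reduced length.  The output is therefore a
shorter series — this is the data-reduction step, not a conventional
low-pass filter.  In ``symmetric`` mode (default) bins with |f| > cutoff
are deleted, keeping the retained set conjugate-symmetric so the reduced
series is real; ``positive_only`` deletes only positive-frequency bins,
which leaves a complex series and is kept as a literal variant.

The comparison against the cutoff is strict, so bins lying exactly at the
cutoff frequency are retained.  The shortened inverse transform divides by
k instead of N; by default this amplitude change is left alone (downstream
min–max image normalization absorbs it), ``normalize=True`` rescales by
k/N to restore DC amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpectrumView",
    "ReducedSignal",
    "spectrum",
    "filter_frequencies",
    "count_retained_bins",
]


@dataclass
class SpectrumView:
    """Complex FFT of a series with its signed bin-frequency grid."""

    values: np.ndarray
    freqs: np.ndarray
    fs: float
    n: int


@dataclass
class ReducedSignal:
    """Frequency-filtered, length-reduced series."""

    samples: np.ndarray
    k: int
    cutoff: float
    mode: str
    normalized: bool
    source_n: int
    source_fs: float

    @property
    def implied_fs(self) -> float:
        """Sampling rate that maps the k samples onto the source duration."""
        return self.source_fs * self.k / self.source_n


def spectrum(series: np.ndarray, fs: float) -> SpectrumView:
    """FFT with the standard DC-positive-negative frequency layout."""
    series = np.asarray(series)
    if series.size == 0:
        raise ValueError("cannot take the spectrum of an empty series")
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    values = np.fft.fft(series)
    freqs = np.fft.fftfreq(series.size, d=1.0 / fs)
    return SpectrumView(values, freqs, fs, series.size)


def _retained_mask(n: int, fs: float, cutoff: float, mode: str) -> np.ndarray:
    freqs = np.fft.fftfreq(n, d=1.0 / fs)
    if mode == "symmetric":
        return ~(np.abs(freqs) > cutoff)
    if mode == "positive_only":
        return ~(freqs > cutoff)
    raise ValueError(f"unknown deletion mode {mode!r}")


def count_retained_bins(
    n: int, fs: float, cutoff: float, mode: str = "symmetric"
) -> int:
    """Number of FFT bins surviving deletion (== reduced length k)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return int(np.count_nonzero(_retained_mask(n, fs, cutoff, mode)))


def filter_frequencies(
    series: np.ndarray,
    fs: float,
    cutoff: float = 2.0,
    mode: str = "symmetric",
    normalize: bool = False,
) -> ReducedSignal:
    """Delete out-of-band FFT bins and invert the shortened spectrum.

    Returns a :class:`ReducedSignal` whose length k is the retained-bin
    count.  DC is always retained, so k >= 1.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    view = spectrum(series, fs)
    mask = _retained_mask(view.n, fs, cutoff, mode)
    reduced_spectrum = view.values[mask]
    k = reduced_spectrum.size
    out = np.fft.ifft(reduced_spectrum)
    if mode == "symmetric":
        out = out.real
    if normalize:
        out = out * (k / view.n)
    return ReducedSignal(
        samples=out,
        k=k,
        cutoff=cutoff,
        mode=mode,
        normalized=normalize,
        source_n=view.n,
        source_fs=fs,
    )
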