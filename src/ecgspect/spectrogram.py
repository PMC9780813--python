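"""STFT spectrograms and 64x64 grayscale rasters.

The short-time Fourier transform here is deliberately tiny: 9-sample
segments, 9-point FFTs, hop of 5 samples (overlap 4 = floor(NFFT/2)),
matching a compact spectrogram whose x-axis counts data segments rather
than seconds.  Rendering maps magnitude (dB by default) through min–max
normalization onto an 8-bit 64x64 single-channel image with no axes or
margins; a polyline raster of the raw series at the same geometry serves
as the comparison representation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "StftParams",
    "SpectrogramMatrix",
    "stft_matrix",
    "segment_count",
    "render_spectrogram",
    "render_raw_signal",
    "save_png",
    "load_png",
]

_WINDOWS = {
    "hann": lambda m: np.hanning(m),
    "rectangular": lambda m: np.ones(m),
}


@dataclass(frozen=True)
class StftParams:
    """Sliding-window FFT parameters.

    ``overlap`` defaults to floor(NFFT/2) = 4 ("half of the NFFT", floored
    for the odd default).  ``onesided`` keeps the non-negative frequency
    rows only; the two-sided layout retains all NFFT rows and satisfies a
    Parseval identity under a rectangular window.
    """

    nfft: int = 9
    seglen: int = 9
    overlap: int = 4
    fs: float = 100.0
    window: str = "hann"
    onesided: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < self.seglen:
            raise ValueError("need 0 <= overlap < segment length")
        if self.nfft < self.seglen:
            raise ValueError("NFFT must be >= segment length")
        if self.window not in _WINDOWS:
            raise ValueError(
                f"unknown window {self.window!r}; use one of {sorted(_WINDOWS)}"
            )

    @property
    def step(self) -> int:
        return self.seglen - self.overlap


@dataclass
class SpectrogramMatrix:
    """Non-negative magnitude grid, frequency rows x segment columns."""

    magnitudes: np.ndarray
    freqs: np.ndarray
    n_segments: int
    params: StftParams


def segment_count(length: int, seglen: int, overlap: int) -> int:
    """Number of full sliding windows: floor((L - seglen)/step) + 1."""
    if length < seglen:
        raise ValueError(
            f"input of length {length} is shorter than one {seglen}-sample segment"
        )
    return (length - seglen) // (seglen - overlap) + 1


def stft_matrix(series: np.ndarray, params: StftParams | None = None) -> SpectrogramMatrix:
    """Magnitude STFT: one column per windowed segment."""
    params = params or StftParams()
    series = np.asarray(series, dtype=float)
    n_seg = segment_count(series.size, params.seglen, params.overlap)
    win = _WINDOWS[params.window](params.seglen)
    starts = np.arange(n_seg) * params.step
    frames = np.stack([series[s : s + params.seglen] for s in starts])
    spec = np.fft.fft(frames * win, n=params.nfft, axis=1)
    if params.onesided:
        n_keep = params.nfft // 2 + 1
        spec = spec[:, :n_keep]
        freqs = np.fft.fftfreq(params.nfft, d=1.0 / params.fs)[:n_keep]
    else:
        freqs = np.fft.fftfreq(params.nfft, d=1.0 / params.fs)
    return SpectrogramMatrix(np.abs(spec).T, freqs, n_seg, params)


def _resize_nearest(grid: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    rows = (np.arange(size[0]) * grid.shape[0]) // size[0]
    cols = (np.arange(size[1]) * grid.shape[1]) // size[1]
    return grid[np.ix_(rows, cols)]


def _resize_bilinear(grid: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    img = Image.fromarray(grid.astype(np.float32), mode="F")
    return np.asarray(img.resize((size[1], size[0]), Image.BILINEAR), dtype=float)


def _to_uint8(grid: np.ndarray) -> np.ndarray:
    lo, hi = float(grid.min()), float(grid.max())
    if hi - lo <= 0:
        return np.full(grid.shape, 128, dtype=np.uint8)
    scaled = (grid - lo) / (hi - lo) * 255.0
    return np.clip(np.floor(scaled + 0.5), 0, 255).astype(np.uint8)


def render_spectrogram(
    matrix: SpectrogramMatrix,
    size: tuple[int, int] = (64, 64),
    scale: str = "dB",
    eps: float = 1e-12,
    interpolation: str = "nearest",
) -> np.ndarray:
    """Render a magnitude grid to an 8-bit grayscale image array.

    dB scale (default) maps magnitudes through ``10*log10(m^2 + eps)``.
    The grid is min–max normalized to [0, 255] and resized (nearest
    neighbour by default, for cross-platform determinism).  Low frequencies
    are placed at the bottom row, the plotting convention for spectrograms.
    A constant grid maps to mid-gray 128.
    """
    grid = np.asarray(matrix.magnitudes, dtype=float)
    if grid.size == 0:
        raise ValueError("empty spectrogram matrix")
    if scale == "dB":
        grid = 10.0 * np.log10(grid**2 + eps)
    elif scale != "linear":
        raise ValueError(f"unknown scale {scale!r}")
    grid = grid[::-1]  # frequency increases upward in the image
    resize = _resize_nearest if interpolation == "nearest" else _resize_bilinear
    return _to_uint8(resize(grid, size))


def render_raw_signal(
    series: np.ndarray, size: tuple[int, int] = (64, 64)
) -> np.ndarray:
    """Rasterize an amplitude-versus-index polyline as a grayscale image.

    Dark trace (0) on a light background (255), axes omitted.  Columns span
    the sample index range; rows span the amplitude range.  Consecutive
    samples are joined by vertical spans so the trace is connected; a
    constant series maps to the single centre row.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("cannot render an empty series")
    h, w = size
    img = np.full(size, 255, dtype=np.uint8)
    lo, hi = float(series.min()), float(series.max())
    if hi - lo <= 0:
        rows = np.full(series.size, (h - 1) // 2, dtype=int)
    else:
        frac = (series - lo) / (hi - lo)
        rows = np.clip(np.rint((1.0 - frac) * (h - 1)).astype(int), 0, h - 1)
    if series.size == 1:
        cols = np.array([0])
    else:
        cols = np.rint(np.arange(series.size) * (w - 1) / (series.size - 1)).astype(int)
    img[rows[0], cols[0]] = 0
    for i in range(1, series.size):
        r0, r1 = rows[i - 1], rows[i]
        img[min(r0, r1) : max(r0, r1) + 1, cols[i]] = 0
    return img


def save_png(image: np.ndarray, path: str | Path) -> Path:
    """Write an 8-bit grayscale array as a PNG file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="L").save(path)
    return path


def load_png(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L"), dtype=np.uint8)
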