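"""Seeded synthetic two-class ECG generator.

Builds Gaussian-bump P-QRS-T beat trains plus the three classic ECG noise
sources (baseline wander, mains interference, white noise).  The abnormal
class differs from the normal class only in sub-2-Hz baseline content (a
slow ST-like offset modulation), so the class contrast survives a 2 Hz
low-frequency retention step: the downstream frequency-deletion stage keeps
exactly the band in which the two classes differ.

Every sample is a pure function of the specification and an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .records import STANDARD_LEADS, EcgRecord

__all__ = [
    "BeatTemplate",
    "NoiseSpec",
    "SynthCohortSpec",
    "generate_record",
    "generate_cohort",
    "white_noise_std_for_snr",
]

# Per-lead amplitude factors relative to the template, loosely shaped on the
# projection of a mean cardiac vector; lead v1 carries the canonical template.
_LEAD_GAINS = (0.6, 1.0, 0.5, -0.8, 0.3, 0.7, 1.0, 1.2, 1.1, 1.0, 0.9, 0.8)


@dataclass(frozen=True)
class BeatTemplate:
    """Gaussian-bump model of one cardiac cycle.

    Each of the five deflections (P, Q, R, S, T) is a Gaussian bump with an
    amplitude in mV, a width (standard deviation, s) and an offset from the
    beat centre (s).  Defaults sketch a lead-v1-like beat at 60 bpm.
    """

    amplitudes: tuple[float, ...] = (0.15, -0.10, 1.00, -0.15, 0.30)
    widths: tuple[float, ...] = (0.040, 0.015, 0.020, 0.015, 0.060)
    offsets: tuple[float, ...] = (-0.20, -0.04, 0.00, 0.04, 0.25)
    period: float = 1.0

    def __post_init__(self) -> None:
        if not (len(self.amplitudes) == len(self.widths) == len(self.offsets)):
            raise ValueError("amplitudes, widths and offsets must align")
        if any(w <= 0 for w in self.widths):
            raise ValueError("bump widths must be positive")
        if not all(np.isfinite(self.amplitudes)):
            raise ValueError("amplitudes must be finite")
        # each bump's ±3 sigma support must fit inside one period
        support = max(
            abs(o) + 3 * w for o, w in zip(self.offsets, self.widths)
        )
        if self.period <= 2 * support * 0.5:
            pass  # wide T waves may graze the boundary; tolerated
        if self.period <= 0:
            raise ValueError("beat period must be positive")

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the periodic beat train at times ``t`` (seconds).

        Each bump is evaluated at its wrapped distance from the beat centre
        (mid-period), so the train is exactly periodic: a steady rhythm with
        no edge truncation.
        """
        t = np.asarray(t, dtype=float)
        x = np.zeros_like(t)
        p = self.period
        for a, w, o in zip(self.amplitudes, self.widths, self.offsets):
            centre = 0.5 * p + o
            d = np.mod(t - centre + 0.5 * p, p) - 0.5 * p
            x += a * np.exp(-0.5 * (d / w) ** 2)
        return x


@dataclass(frozen=True)
class NoiseSpec:
    """Amplitudes and frequencies of the three modelled noise sources.

    Defaults are plausible unfiltered magnitudes for a resting ECG:
    respiratory baseline wander of 0.1 mV around 0.3 Hz, mains pickup of
    0.2 mV at 50 Hz (European mains), and 0.05 mV of broadband sensor noise.
    """

    baseline_amp: float = 0.1
    baseline_freq: float = 0.3
    powerline_amp: float = 0.2
    powerline_freq: float = 50.0
    white_std: float = 0.05

    def __post_init__(self) -> None:
        if min(self.baseline_amp, self.powerline_amp, self.white_std) < 0:
            raise ValueError("noise amplitudes must be non-negative")
        if min(self.baseline_freq, self.powerline_freq) < 0:
            raise ValueError("noise frequencies must be non-negative")

    @property
    def silent(self) -> bool:
        return (
            self.baseline_amp == 0
            and self.powerline_amp == 0
            and self.white_std == 0
        )


@dataclass(frozen=True)
class SynthCohortSpec:
    """Recipe for a balanced two-class cohort."""

    records_per_class: int = 150
    duration: float = 10.0
    fs: float = 100.0
    separation: float = 1.0
    seed: int = 0
    template: BeatTemplate = field(default_factory=BeatTemplate)
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    def __post_init__(self) -> None:
        if self.records_per_class < 1:
            raise ValueError("records_per_class must be >= 1")
        _n_samples(self.duration, self.fs)  # validates integrality


def _n_samples(duration: float, fs: float) -> int:
    n = duration * fs
    n_int = int(round(n))
    if abs(n - n_int) > 1e-9 or n_int < 1:
        raise ValueError(
            f"duration*fs = {n} is not a positive integer sample count"
        )
    return n_int


def _abnormal_baseline(t: np.ndarray, separation: float) -> np.ndarray:
    # Slow ST-like offset modulation: a DC shift plus a 0.5 Hz swing.  All
    # spectral content sits at or below 0.5 Hz, well inside the 2 Hz band
    # the frequency-deletion stage retains.
    return separation * (0.15 + 0.10 * np.sin(2 * np.pi * 0.5 * t))


def clean_components(
    template: BeatTemplate,
    class_label: str,
    duration: float,
    fs: float,
    separation: float = 1.0,
) -> np.ndarray:
    """Noise-free single-lead waveform for a record of the given class."""
    if class_label not in ("normal", "abnormal"):
        raise ValueError("class_label must be 'normal' or 'abnormal'")
    n = _n_samples(duration, fs)
    t = np.arange(n) / fs
    x = template.waveform(t)
    if class_label == "abnormal":
        x = x + _abnormal_baseline(t, separation)
    return x


def generate_record(
    template: BeatTemplate,
    noise: NoiseSpec,
    class_label: str,
    duration: float = 10.0,
    fs: float = 100.0,
    seed: int = 0,
    record_id: str | None = None,
    separation: float = 1.0,
) -> EcgRecord:
    """Generate one 12-lead synthetic record.

    The abnormal class adds a slow (≤ 0.5 Hz) baseline offset scaled by
    ``separation``; with ``separation == 0`` the classes are
    distributionally identical.  Identical arguments (including ``seed``)
    produce bit-identical output.
    """
    n = _n_samples(duration, fs)
    t = np.arange(n) / fs
    clean = clean_components(template, class_label, duration, fs, separation)

    rng = np.random.default_rng(seed)
    if noise.silent:
        noisy = clean
    else:
        bw = noise.baseline_amp * np.sin(
            2 * np.pi * noise.baseline_freq * t + rng.uniform(0, 2 * np.pi)
        )
        pl = noise.powerline_amp * np.sin(
            2 * np.pi * noise.powerline_freq * t + rng.uniform(0, 2 * np.pi)
        )
        wh = rng.normal(0.0, noise.white_std, n) if noise.white_std > 0 else 0.0
        noisy = clean + bw + pl + wh

    signals = np.outer(noisy, _LEAD_GAINS)
    code = "NORM" if class_label == "normal" else "ASMI"
    return EcgRecord(
        record_id=record_id or f"synth_{class_label}_{seed}",
        signals=signals,
        fs=fs,
        lead_names=STANDARD_LEADS,
        codes={code: 100.0},
    )


def white_noise_std_for_snr(clean: np.ndarray, snr_db: float) -> float:
    """White-noise standard deviation giving the target SNR against ``clean``.

    SNR is defined as ``10*log10(P_signal / P_noise)`` with powers taken as
    mean squares.
    """
    p_clean = float(np.mean(np.square(clean)))
    return float(np.sqrt(p_clean / 10.0 ** (snr_db / 10.0)))


def generate_cohort(
    spec: SynthCohortSpec,
) -> tuple[list[EcgRecord], pd.DataFrame]:
    """Generate a balanced cohort plus its label table.

    Returns the records and a DataFrame with columns ``record_id`` and
    ``label`` (ASMI for abnormal, NORM for normal), one row per record.
    Record seeds are drawn deterministically from ``spec.seed``.
    """
    seed_rng = np.random.default_rng(spec.seed)
    records: list[EcgRecord] = []
    rows = []
    for class_label, code in (("normal", "NORM"), ("abnormal", "ASMI")):
        for i in range(spec.records_per_class):
            rec_seed = int(seed_rng.integers(0, 2**31 - 1))
            rid = f"s{spec.seed}_{code.lower()}_{i:04d}"
            # mild physiological variation: heart rate and overall gain
            var_rng = np.random.default_rng(rec_seed + 1)
            period = spec.template.period * var_rng.uniform(0.9, 1.1)
            gain = var_rng.uniform(0.95, 1.05)
            template = replace(
                spec.template,
                amplitudes=tuple(gain * a for a in spec.template.amplitudes),
                period=period,
            )
            rec = generate_record(
                template,
                spec.noise,
                class_label,
                duration=spec.duration,
                fs=spec.fs,
                seed=rec_seed,
                record_id=rid,
                separation=spec.separation,
            )
            records.append(rec)
            rows.append({"record_id": rid, "label": code})
    labels = pd.DataFrame(rows)
    return records, labels
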