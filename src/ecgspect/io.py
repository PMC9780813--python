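"""Reading and writing ECG records and label tables.

Implements the WFDB dialect used by 100 Hz clinical ECG corpora: a plain-text
``.hea`` header naming the signal file, sample format, per-lead gain/baseline
and lead names, plus a ``.dat`` file of interleaved little-endian 16-bit
integers (WFDB sample format 16).  Other sample formats are rejected.

Also hosts lead selection, anti-aliased polyphase resampling, and the
metadata-CSV label parser (ASMI-versus-rest binary rule).
"""

from __future__ import annotations

import ast
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

from .records import EcgRecord

__all__ = [
    "read_record",
    "write_record",
    "select_lead",
    "resample_signal",
    "parse_labels",
    "write_labels",
]

DEFAULT_GAIN = 1000.0  # ADC units per mV; PTB-XL's 100 Hz headers use 1000


class FormatError(ValueError):
    """Malformed WFDB header or signal file."""


def write_record(record: EcgRecord, directory: str | Path) -> Path:
    """Write ``record`` as a format-16 ``.hea``/``.dat`` pair.

    Samples are quantized to ``round(value * gain) + baseline`` 16-bit
    integers with gain 1000 /mV and baseline 0, the layout of the 100 Hz
    clinical corpora this package targets.  Returns the header path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = record.record_id
    n_sig = len(record.lead_names)
    adc = np.round(record.signals * DEFAULT_GAIN)
    if np.any(np.abs(adc) > 32767):
        raise ValueError("signal amplitude overflows 16-bit sample format")
    adc = adc.astype("<i2")

    lines = [f"{name} {n_sig} {record.fs:g} {record.n_samples}"]
    for j, lead in enumerate(record.lead_names):
        first = int(adc[0, j]) if record.n_samples else 0
        lines.append(
            f"{name}.dat 16 {DEFAULT_GAIN:g}(0)/mV 16 0 {first} 0 0 {lead}"
        )
    if record.codes:
        lines.append(f"# scp_codes: {record.codes!r}")
    header = directory / f"{name}.hea"
    header.write_text("\n".join(lines) + "\n")
    adc.tofile(directory / f"{name}.dat")
    return header


def _parse_header(header: Path) -> dict:
    lines = [
        ln.strip()
        for ln in header.read_text().splitlines()
        if ln.strip()
    ]
    comments = [ln for ln in lines if ln.startswith("#")]
    lines = [ln for ln in lines if not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{header}: empty header")
    head = lines[0].split()
    if len(head) < 4:
        raise FormatError(
            f"{header}: record line needs 'name n_sig fs n_samples', got {lines[0]!r}"
        )
    try:
        n_sig, fs, n_samples = int(head[1]), float(head[2]), int(head[3])
    except ValueError as e:
        raise FormatError(f"{header}: bad record line field: {e}") from None
    if len(lines) - 1 != n_sig:
        raise FormatError(
            f"{header}: header declares {n_sig} signals but lists {len(lines) - 1}"
        )
    sig_files, gains, baselines, leads = [], [], [], []
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) < 3:
            raise FormatError(f"{header}: short signal line {ln!r}")
        sig_files.append(parts[0])
        if parts[1] != "16":
            raise FormatError(
                f"{header}: unsupported sample format {parts[1]!r}; "
                "only WFDB format 16 is supported"
            )
        gain_spec = parts[2]
        gain_part = gain_spec.split("/")[0]
        if "(" in gain_part:
            g, b = gain_part.split("(")
            gains.append(float(g))
            baselines.append(int(b.rstrip(")")))
        else:
            gains.append(float(gain_part))
            baselines.append(0)
        leads.append(parts[-1])
    codes: dict[str, float] = {}
    for c in comments:
        if "scp_codes:" in c:
            codes = ast.literal_eval(c.split("scp_codes:", 1)[1].strip())
    return dict(
        n_sig=n_sig,
        fs=fs,
        n_samples=n_samples,
        sig_files=sig_files,
        gains=np.array(gains),
        baselines=np.array(baselines),
        leads=leads,
        codes=codes,
    )


def read_record(path: str | Path) -> EcgRecord:
    """Read a format-16 WFDB record; ``path`` may omit the ``.hea`` suffix."""
    path = Path(path)
    header = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not header.exists():
        raise FileNotFoundError(header)
    meta = _parse_header(header)
    if len(set(meta["sig_files"])) != 1:
        raise FormatError(f"{header}: multi-file records are not supported")
    dat = header.parent / meta["sig_files"][0]
    raw = np.fromfile(dat, dtype="<i2")
    expected = meta["n_samples"] * meta["n_sig"]
    if raw.size != expected:
        raise FormatError(
            f"{dat}: contains {raw.size} samples but header declares "
            f"{meta['n_samples']} frames x {meta['n_sig']} signals = {expected}"
        )
    adc = raw.reshape(meta["n_samples"], meta["n_sig"]).astype(float)
    signals = (adc - meta["baselines"]) / meta["gains"]
    return EcgRecord(
        record_id=header.stem,
        signals=signals,
        fs=meta["fs"],
        lead_names=tuple(meta["leads"]),
        codes=meta["codes"],
    )


def select_lead(record: EcgRecord, lead: str = "v1") -> tuple[np.ndarray, float]:
    """Return ``(samples, fs)`` for one lead, unchanged."""
    return record.lead(lead), record.fs


def resample_signal(
    series: np.ndarray, fs_in: float, fs_out: float
) -> np.ndarray:
    """Anti-aliased polyphase resampling from ``fs_in`` to ``fs_out`` Hz.

    Output length is ``round(len(series) * fs_out / fs_in)``.  Edge effects
    are controlled by linear-trend padding, so constants survive exactly
    (to numerical precision).
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("cannot resample an empty series")
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    if fs_in == fs_out:
        return series.copy()
    ratio = Fraction(fs_out / fs_in).limit_denominator(10**6)
    up, down = ratio.numerator, ratio.denominator
    # resampling the mean-removed series keeps DC exact (a constant maps to
    # the zero series, which every linear filter preserves)
    mean = series.mean()
    out = resample_poly(series - mean, up, down, padtype="line") + mean
    n_target = int(round(series.size * fs_out / fs_in))
    if out.size > n_target:
        out = out[:n_target]
    elif out.size < n_target:
        out = np.pad(out, (0, n_target - out.size), mode="edge")
    return out


def parse_labels(
    metadata: str | Path | pd.DataFrame,
    strict_norm: bool = False,
) -> pd.DataFrame:
    """Binary labels from a metadata table with diagnostic-code maps.

    Records whose code set contains ``ASMI`` go to class ASMI; every other
    record goes to NORM ("ASMI versus rest").  With ``strict_norm`` set, only records actually coded ``NORM`` are kept
    in the NORM class and other pathologies are dropped.

    The table needs columns ``record_id`` and ``scp_codes`` (a dict literal
    per row, code -> weight) — or a ``label`` column, which is passed
    through.
    """
    if isinstance(metadata, (str, Path)):
        df = pd.read_csv(metadata)
    else:
        df = metadata.copy()
    if "record_id" not in df.columns:
        raise ValueError("metadata needs a 'record_id' column")
    if "label" in df.columns:
        out = df[["record_id", "label"]].copy()
    elif "scp_codes" in df.columns:
        def classify(cell) -> str:
            codes = cell if isinstance(cell, dict) else ast.literal_eval(str(cell))
            return "ASMI" if "ASMI" in codes else "NORM"

        out = pd.DataFrame(
            {
                "record_id": df["record_id"],
                "label": df["scp_codes"].map(classify),
            }
        )
        if strict_norm:
            def is_norm(cell) -> bool:
                codes = cell if isinstance(cell, dict) else ast.literal_eval(str(cell))
                return "NORM" in codes

            keep = (out["label"] == "ASMI") | df["scp_codes"].map(is_norm)
            out = out[keep].reset_index(drop=True)
    else:
        raise ValueError("metadata needs an 'scp_codes' (or 'label') column")
    if out["record_id"].duplicated().any():
        raise ValueError("record ids must be unique")
    return out


def write_labels(labels: pd.DataFrame, path: str | Path) -> Path:
    """Persist a label table as CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    labels.to_csv(path, index=False)
    return path
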