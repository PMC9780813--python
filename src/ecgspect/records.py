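"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Conventional 12-lead order; the precordial lead "v1" (index 6) is the
#: analysis lead of the pipeline.
STANDARD_LEADS = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "v1", "v2", "v3", "v4", "v5", "v6",
)


@dataclass
class EcgRecord:
    """A multi-lead ECG record.

    Parameters
    ----------
    record_id:
        Unique identifier, used as the WFDB record name on disk.
    signals:
        Array of shape ``(n_samples, n_leads)`` in millivolts.
    fs:
        Sampling rate in Hz.
    lead_names:
        Ordered lead names, one per signal column.
    codes:
        Optional diagnostic-code map (code -> likelihood weight).
    """

    record_id: str
    signals: np.ndarray
    fs: float
    lead_names: tuple[str, ...] = STANDARD_LEADS
    codes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim == 1:
            self.signals = self.signals[:, None]
        self.lead_names = tuple(self.lead_names)
        if self.signals.shape[1] != len(self.lead_names):
            raise ValueError(
                f"{self.signals.shape[1]} signal columns but "
                f"{len(self.lead_names)} lead names"
            )
        if len(set(self.lead_names)) != len(self.lead_names):
            raise ValueError("lead names must be unique")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[0]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        """Return one lead's samples (a view, not a copy)."""
        try:
            idx = self.lead_names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown lead {name!r}; available: {', '.join(self.lead_names)}"
            ) from None
        return self.signals[:, idx]
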