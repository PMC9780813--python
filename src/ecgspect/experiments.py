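"""Experiment grid: learning-rate sweep, sampling-rate sweep,
representation comparison, and on-disk size accounting.

Every experiment varies exactly one factor and holds data, seeds and
architecture fixed, so rows are directly comparable; rerunning any row
standalone reproduces it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
import time
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cnn import ModelSpec, build_model
from .dataset import SplitSpec, save_image_set, split
from .io import resample_signal
from .pipeline import PipelineConfig, build_image_set
from .records import EcgRecord
from .training import EvalMetrics, TrainConfig, train_model

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_LEARNING_RATES",
    "DEFAULT_SAMPLING_RATES",
    "SizeReport",
    "sweep_learning_rates",
    "sweep_sampling_rates",
    "compare_representations",
    "dataset_size_report",
    "write_run_manifest",
]

#: The canonical learning-rate grid.
DEFAULT_LEARNING_RATES = (0.1, 0.01, 0.001, 0.0001, 0.00001)
#: Down- and up-sampling grid around the native 100 Hz.
DEFAULT_SAMPLING_RATES = (25, 50, 100, 200, 400, 600, 800, 1000)


@dataclass
class SizeReport:
    total_bytes: int
    image_count: int

    @property
    def bytes_per_image(self) -> float:
        return self.total_bytes / self.image_count if self.image_count else 0.0


def _train_once(train_items, val_items, model_spec, config, stage=""):
    t0 = time.perf_counter()
    model, _ = build_model(model_spec, seed=config.seed)
    history, metrics = train_model(model, train_items, val_items, config)
    logger.info(
        "stage=%s seed=%d epochs=%d elapsed=%.1fs val_accuracy=%.4f",
        stage or "train", config.seed, config.epochs,
        time.perf_counter() - t0, metrics.accuracy,
    )
    return model, history, metrics


def sweep_learning_rates(
    train_items,
    val_items,
    rates=DEFAULT_LEARNING_RATES,
    model_spec: ModelSpec | None = None,
    config: TrainConfig | None = None,
) -> pd.DataFrame:
    """Train one fresh, identically seeded model per learning rate."""
    if not len(rates):
        raise ValueError("rate list must be non-empty")
    if any(r <= 0 for r in rates):
        raise ValueError("learning rates must be positive")
    model_spec = model_spec or ModelSpec()
    config = config or TrainConfig()
    rows = []
    for rate in rates:
        cfg = replace(config, learning_rate=rate)
        _, history, metrics = _train_once(
            train_items, val_items, model_spec, cfg, stage=f"lr={rate:g}"
        )
        rows.append(
            {
                "learning_rate": rate,
                "val_accuracy": metrics.accuracy,
                "final_loss": float(history["loss"].iloc[-1]),
                "seed": cfg.seed,
            }
        )
    return pd.DataFrame(rows)


def _resample_record(record: EcgRecord, fs_out: float) -> EcgRecord:
    if fs_out == record.fs:
        return record
    resampled = np.column_stack(
        [
            resample_signal(record.signals[:, j], record.fs, fs_out)
            for j in range(record.signals.shape[1])
        ]
    )
    return EcgRecord(
        record_id=record.record_id,
        signals=resampled,
        fs=fs_out,
        lead_names=record.lead_names,
        codes=record.codes,
    )


def sweep_sampling_rates(
    records: list[EcgRecord],
    labels: pd.DataFrame,
    rates=DEFAULT_SAMPLING_RATES,
    pipeline: PipelineConfig | None = None,
    model_spec: ModelSpec | None = None,
    config: TrainConfig | None = None,
    split_spec: SplitSpec | None = None,
) -> pd.DataFrame:
    """Resample, rebuild images, retrain and evaluate at each rate.

    The STFT's sampling-frequency parameter follows the resampled rate
    (records carry their fs through the pipeline).
    """
    if any(r <= 0 for r in rates):
        raise ValueError("sampling rates must be positive")
    pipeline = pipeline or PipelineConfig()
    model_spec = model_spec or ModelSpec()
    config = config or TrainConfig()
    split_spec = split_spec or SplitSpec()
    rows = []
    for rate in rates:
        t0 = time.perf_counter()
        resampled = [_resample_record(r, rate) for r in records]
        items = build_image_set(resampled, labels, pipeline)
        logger.info(
            "stage=fs=%g prepare elapsed=%.1fs n_images=%d",
            rate, time.perf_counter() - t0, len(items),
        )
        train_items, val_items = split(items, split_spec)
        _, history, metrics = _train_once(
            train_items, val_items, model_spec, config, stage=f"fs={rate:g}"
        )
        rows.append(
            {
                "sampling_rate": rate,
                "val_accuracy": metrics.accuracy,
                "final_loss": float(history["loss"].iloc[-1]),
                "seed": config.seed,
            }
        )
    return pd.DataFrame(rows)


def compare_representations(
    records: list[EcgRecord],
    labels: pd.DataFrame,
    out_dir: str | Path,
    pipeline: PipelineConfig | None = None,
    model_spec: ModelSpec | None = None,
    config: TrainConfig | None = None,
    split_spec: SplitSpec | None = None,
) -> dict[str, dict]:
    """Train the same model on spectrogram and raw-signal images.

    Both arms see the identical record set, split and seeds; images for
    each arm are written under ``out_dir/<arm>/`` so their on-disk sizes
    can be compared.  Returns per-arm metrics and size reports.
    """
    pipeline = pipeline or PipelineConfig()
    model_spec = model_spec or ModelSpec()
    config = config or TrainConfig()
    split_spec = split_spec or SplitSpec()
    out_dir = Path(out_dir)
    result: dict[str, dict] = {}
    for arm in ("spectrogram", "raw"):
        arm_pipeline = replace(pipeline, representation=arm)
        t0 = time.perf_counter()
        items = build_image_set(records, labels, arm_pipeline)
        save_image_set(items, out_dir / arm)
        logger.info(
            "stage=compare/%s images elapsed=%.1fs", arm, time.perf_counter() - t0
        )
        train_items, val_items = split(items, split_spec)
        _, history, metrics = _train_once(
            train_items, val_items, model_spec, config, stage=f"compare/{arm}"
        )
        result[arm] = {
            "metrics": metrics,
            "size": dataset_size_report(out_dir / arm),
            "record_ids": sorted({it.record_id for it in items}),
        }
    return result


def dataset_size_report(path: str | Path, pattern: str = "*.png") -> SizeReport:
    """Byte-exact sum of image file sizes under ``path`` (recursive)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    files = sorted(path.rglob(pattern))
    return SizeReport(
        total_bytes=sum(f.stat().st_size for f in files),
        image_count=len(files),
    )


def write_run_manifest(path: str | Path, config: object, seed: int, extra: dict | None = None) -> Path:
    """Record config, seed and library versions for reproducibility."""
    import numpy
    import pandas
    import pywt
    import scipy

    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        return str(obj)

    payload = {
        "seed": seed,
        "config": encode(config),
        "python": platform.python_version(),
        "versions": {
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "pywavelets": pywt.__version__,
        },
        **(extra or {}),
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, default=encode) + "\n")
    return path
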