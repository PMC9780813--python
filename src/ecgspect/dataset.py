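"""Labeled image sets: augmentation, class balancing, train/validation split.

The minority class is brought up to the majority count by, in order:
horizontally flipped copies of its originals, contrast-enhanced copies of
its originals, then seeded-random duplicates.  Augmented copies always
derive from originals, never from other augmented copies, and the majority
class is never touched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .spectrogram import save_png

__all__ = [
    "LabeledImage",
    "SplitSpec",
    "augment_flip",
    "augment_contrast",
    "balance_classes",
    "split",
    "save_image_set",
]


@dataclass(frozen=True)
class LabeledImage:
    """One grayscale image with its class label and provenance."""

    image: np.ndarray
    label: str  # "ASMI" or "NORM"
    record_id: str
    provenance: str = "original"  # original | flip | contrast | duplicate

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "image", np.asarray(self.image, dtype=np.uint8)
        )


@dataclass(frozen=True)
class SplitSpec:
    validation_fraction: float = 0.2
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation fraction must lie in (0, 1)")


def augment_flip(image: np.ndarray) -> np.ndarray:
    """Horizontal flip (column order reversed)."""
    return np.asarray(image)[:, ::-1].copy()


def augment_contrast(image: np.ndarray, factor: float = 1.2) -> np.ndarray:
    """Contrast gain about mid-gray 128 with clipping.

    ``pixel -> clip(128 + factor*(pixel - 128), 0, 255)``, rounded
    half-away-from-zero.  The default 1.2 is deliberately mild so the
    augmented copy stays close to the original.
    """
    if factor <= 0:
        raise ValueError("contrast factor must be positive")
    shifted = 128.0 + factor * (np.asarray(image, dtype=float) - 128.0)
    rounded = np.sign(shifted) * np.floor(np.abs(shifted) + 0.5)
    return np.clip(rounded, 0, 255).astype(np.uint8)


def _counts(items: list[LabeledImage]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for it in items:
        counts[it.label] = counts.get(it.label, 0) + 1
    return counts


def balance_classes(
    items: list[LabeledImage], seed: int = 0, contrast_factor: float = 1.2
) -> list[LabeledImage]:
    """Equalize class counts by augmenting the minority class.

    Fill order: one flipped copy per minority original, then one
    contrast-enhanced copy per original, then duplicates of seeded-random
    originals.  Appended items keep their source record id with a new
    provenance tag.
    """
    counts = _counts(items)
    if len(counts) < 2:
        raise ValueError("both classes must be present to balance")
    minority = min(counts, key=counts.get)
    majority = max(counts, key=counts.get)
    deficit = counts[majority] - counts[minority]
    if deficit == 0:
        return list(items)
    originals = [
        it for it in items if it.label == minority and it.provenance == "original"
    ]
    added: list[LabeledImage] = []
    for op, provenance in (
        (augment_flip, "flip"),
        (lambda im: augment_contrast(im, contrast_factor), "contrast"),
    ):
        for src in originals:
            if len(added) == deficit:
                break
            added.append(
                replace(src, image=op(src.image), provenance=provenance)
            )
    rng = np.random.default_rng(seed)
    while len(added) < deficit:
        src = originals[int(rng.integers(len(originals)))]
        added.append(replace(src, image=src.image.copy(), provenance="duplicate"))
    return list(items) + added


def split(
    items: list[LabeledImage], spec: SplitSpec | None = None
) -> tuple[list[LabeledImage], list[LabeledImage]]:
    """Disjoint train/validation partition, stratified by class by default."""
    spec = spec or SplitSpec()
    if not items:
        raise ValueError("cannot split an empty set")
    rng = np.random.default_rng(spec.seed)
    train_idx: list[int] = []
    val_idx: list[int] = []
    if spec.stratified:
        groups: dict[str, list[int]] = {}
        for i, it in enumerate(items):
            groups.setdefault(it.label, []).append(i)
    else:
        groups = {"all": list(range(len(items)))}
    for _, idxs in sorted(groups.items()):
        idxs = np.array(idxs)
        rng.shuffle(idxs)
        n_val = int(round(len(idxs) * spec.validation_fraction))
        val_idx.extend(idxs[:n_val])
        train_idx.extend(idxs[n_val:])
    train = [items[i] for i in sorted(train_idx)]
    val = [items[i] for i in sorted(val_idx)]
    return train, val


def save_image_set(
    items: list[LabeledImage],
    root: str | Path,
    manifest_name: str = "manifest.csv",
    splits: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Write images under ``<root>/<class>/<id>_<provenance>.png`` + manifest."""
    root = Path(root)
    rows = []
    for it in items:
        rel = Path(it.label) / f"{it.record_id}_{it.provenance}.png"
        save_png(it.image, root / rel)
        rows.append(
            {
                "record_id": it.record_id,
                "label": it.label,
                "provenance": it.provenance,
                "split": (splits or {}).get(it.record_id, ""),
                "path": str(rel),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(root / manifest_name, index=False)
    return manifest
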