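"""Turn reduced signals into the 64x64 grayscale images the classifier eats.

Renders both representations for one record of each class and saves PNGs.
"""

from pathlib import Path

from ecgspect import (
    PipelineConfig,
    SynthCohortSpec,
    generate_cohort,
    record_to_image,
)
from ecgspect.spectrogram import save_png

out = Path("scratch/example_images")
records, labels = generate_cohort(SynthCohortSpec(records_per_class=1, seed=5))
lookup = labels.set_index("record_id")["label"]

for rec in records:
    for representation in ("spectrogram", "raw"):
        img = record_to_image(rec, PipelineConfig(representation=representation))
        path = out / f"{rec.record_id}_{lookup[rec.record_id]}_{representation}.png"
        save_png(img, path)
        print(f"{path.name}: shape {img.shape}, intensity {img.min()}..{img.max()}")
# The spectrogram arm runs denoise -> 2 Hz deletion -> 9-point STFT (5x7
# magnitude grid) -> dB scale -> 64x64; the raw arm rasterizes the denoised
# full-length trace.  The ASMI image is visibly brighter in the low-
# frequency rows -- that offset is what the CNN learns.
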