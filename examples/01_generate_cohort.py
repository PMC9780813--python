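"""Generate a small synthetic two-class ECG cohort and write it as WFDB files.

The abnormal (ASMI) class differs from the normal class only in a slow
(< 0.5 Hz) baseline offset, so the contrast survives the pipeline's 2 Hz
frequency deletion.
"""

from pathlib import Path

import numpy as np

from ecgspect import SynthCohortSpec, generate_cohort, write_record
from ecgspect.io import write_labels

out = Path("scratch/example_cohort")
spec = SynthCohortSpec(records_per_class=5, duration=10.0, fs=100.0, separation=1.0, seed=7)
records, labels = generate_cohort(spec)

for rec in records:
    write_record(rec, out)
write_labels(labels, out / "labels.csv")

v1 = records[0].lead("v1")
print(f"wrote {len(records)} records to {out}")
print(f"first record: {records[0].record_id}, {v1.size} samples at {records[0].fs:g} Hz")
print(f"lead v1 range: {v1.min():.3f} .. {v1.max():.3f} mV")
print(labels.groupby("label").size().to_string())
# Ten 10 s records per run: 5 NORM and 5 ASMI, each a 12-lead beat train
# with baseline wander, 50 Hz mains pickup and white noise.
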