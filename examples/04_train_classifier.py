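"""Train the compact CNN on a synthetic cohort, desk scale.

Builds 80 records, converts them to spectrogram images, splits 3:1 and
trains for 60 epochs.  Takes a few minutes on one CPU core.
"""

from ecgspect import (
    ModelSpec,
    SplitSpec,
    SynthCohortSpec,
    TrainConfig,
    build_image_set,
    build_model,
    generate_cohort,
    split,
    train_model,
)

records, labels = generate_cohort(SynthCohortSpec(records_per_class=40, seed=1))
items = build_image_set(records, labels)
train_items, val_items = split(items, SplitSpec(validation_fraction=0.25, seed=1))

model, n_params = build_model(ModelSpec(), seed=1)
print(f"model parameters: {n_params:,} ({n_params / 1e6:.2f} million)")

config = TrainConfig(learning_rate=0.001, batch_size=32, epochs=60,
                     steps_per_epoch=None, seed=1)
history, metrics = train_model(model, train_items, val_items, config)

print(history.tail(3).to_string(index=False))
print(f"validation accuracy {metrics.accuracy:.3f}, "
      f"sensitivity {metrics.sensitivity}, specificity {metrics.specificity}")
print(f"confusion: TP={metrics.tp} FP={metrics.fp} TN={metrics.tn} FN={metrics.fn}")
# On this separable cohort the validation accuracy reaches 1.0 within the
# 60 epochs; with separation=0 it would hover at chance (~0.5).
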