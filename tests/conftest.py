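"""Shared fixtures: small seeded cohorts and their image sets.

Session-scoped so the synthetic records and pipeline images are built once
and reused by the classifier and experiment tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from ecgspect import (
    BeatTemplate,
    NoiseSpec,
    PipelineConfig,
    SplitSpec,
    SynthCohortSpec,
    build_image_set,
    generate_cohort,
    split,
)


@pytest.fixture(scope="session")
def beat_template():
    return BeatTemplate()


@pytest.fixture(scope="session")
def quiet_noise():
    return NoiseSpec(baseline_amp=0.0, powerline_amp=0.0, white_std=0.0)


@pytest.fixture(scope="session")
def small_cohort():
    """40 records per class, well separated, seed 1."""
    spec = SynthCohortSpec(records_per_class=40, separation=1.0, seed=1)
    records, labels = generate_cohort(spec)
    return spec, records, labels


@pytest.fixture(scope="session")
def small_cohort_images(small_cohort):
    _, records, labels = small_cohort
    return build_image_set(records, labels, PipelineConfig())


@pytest.fixture(scope="session")
def small_cohort_split(small_cohort_images):
    return split(small_cohort_images, SplitSpec(validation_fraction=0.25, seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
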