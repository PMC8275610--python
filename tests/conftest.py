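"""Shared fixtures: small synthetic cohorts and a quickly trained classifier."""

from __future__ import annotations

import numpy as np
import pytest

from gaitscope import model as mdl
from gaitscope import preprocessing as pp
from gaitscope import synthetic as syn

#: Reduced architecture for fast unit tests (same layer kinds as the default).
SMALL_ARCH = (
    ("conv1d", {"filters": 8, "kernel": 9}),
    ("relu", {}),
    ("maxpool1d", {"size": 2}),
    ("conv1d", {"filters": 8, "kernel": 5}),
    ("relu", {}),
    ("maxpool1d", {"size": 2}),
    ("flatten", {}),
    ("dense", {"units": 32}),
    ("relu", {}),
    ("dense", {"units": None}),
    ("softmax", {}),
)


def small_cohort_config(n_per_group: int = 3, tests: int = 2,
                        duration: float = 15.0, seed: int = 7) -> syn.SyntheticConfig:
    return syn.SyntheticConfig(
        n_subjects={g: n_per_group for g in syn.GROUPS},
        tests_per_subject=tests, duration_s=duration, rng_seed=seed)


@pytest.fixture(scope="session")
def cohort_ds() -> pp.EpochDataset:
    """Epochs of a 3-subjects-per-group, 2-tests, 15 s cohort."""
    recs, _ = syn.generate_cohort(small_cohort_config())
    return pp.build_epoch_dataset(recs)


@pytest.fixture(scope="session")
def trained_model(cohort_ds) -> mdl.ModelGraph:
    """A small classifier trained to high accuracy on the session cohort."""
    model = mdl.build_dcnn(cohort_ds.label_space, arch=SMALL_ARCH, rng_seed=0)
    cfg = mdl.TrainConfig(max_epochs=25, patience=6, rng_seed=0)
    model, _ = mdl.train(model, pp.balance_classes(cohort_ds, rng=0), cfg)
    return model
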