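"""End-to-end study workflows on synthetic cohorts.

These functions wire the modules together the way the full analysis runs:
generate a cohort, preprocess it into epochs, train/transfer the classifier,
evaluate subject-wise, and interrogate the result with relevance propagation
and DBA templates. They are used both by the test suite and by the
reproduction script.

Problem sizes default to desk scale (tens of subjects, tens of seconds per
test) so a full experiment runs in minutes on one CPU core; the cohort
structure (groups, repeated tests, m = 10 test resampling) mirrors the full
study conditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluation import evaluate_split
from .model import (ModelGraph, TrainConfig, build_dcnn, predict_proba,
                    train)
from .preprocessing import (EpochDataset, balance_classes,
                            build_epoch_dataset, resample_tests_per_subject)
from .relprop import LrpConfig, lrp_decompose
from .representative import (DbaSelection, dba_average, score_representative,
                             select_epochs)
from .synthetic import (GROUPS, SyntheticConfig, generate_cohort,
                        generate_har_cohort)
from .transfer import TransferPlan, run_transfer_experiment

__all__ = [
    "make_disease_dataset", "make_har_dataset", "split_subjects",
    "class_recovery", "transfer_benefit", "lrp_conservation_study",
    "representative_study",
]


def make_disease_dataset(n_per_group: int = 10, tests_per_subject: int = 4,
                         duration_s: float = 16.0, seed: int = 0,
                         m: int = 10) -> EpochDataset:
    """Synthetic disease cohort -> preprocessed epochs with m tests/subject."""
    cfg = SyntheticConfig(n_subjects={g: n_per_group for g in GROUPS},
                          tests_per_subject=tests_per_subject,
                          duration_s=duration_s, rng_seed=seed)
    recs, _ = generate_cohort(cfg)
    ds = build_epoch_dataset(recs, label_space=GROUPS)
    return resample_tests_per_subject(ds, m=m, rng=seed)


def make_har_dataset(n_subjects: int = 8, tests_per_activity: int = 2,
                     duration_s: float = 12.0, seed: int = 0) -> EpochDataset:
    """Synthetic activity-recognition source domain, epoch-ready."""
    recs, _ = generate_har_cohort(n_subjects=n_subjects,
                                  tests_per_activity=tests_per_activity,
                                  duration_s=duration_s, rng_seed=seed)
    return build_epoch_dataset(recs, placement=None)


def split_subjects(ds: EpochDataset, n_test_per_class: int,
                   seed: int = 0, n_train_per_class: int | None = None
                   ) -> tuple[EpochDataset, EpochDataset]:
    """Deterministic subject-wise train/test split, per class."""
    rng = np.random.default_rng(seed)
    test_subjects, train_subjects = [], []
    for cls in ds.label_space:
        subs = np.unique(ds.subject_ids[ds.labels == cls])
        subs = rng.permutation(subs)
        test_subjects.extend(subs[:n_test_per_class])
        rest = subs[n_test_per_class:]
        if n_train_per_class is not None:
            rest = rest[:n_train_per_class]
        train_subjects.extend(rest)
    test_mask = np.isin(ds.subject_ids, test_subjects)
    train_mask = np.isin(ds.subject_ids, train_subjects)
    return ds.subset(train_mask), ds.subset(test_mask)


def class_recovery(seed: int = 0, n_per_group: int = 10,
                   n_test_per_class: int = 2,
                   tests_per_subject: int = 4, duration_s: float = 16.0,
                   m: int = 10, cfg: TrainConfig | None = None) -> dict:
    """Train the classifier on a synthetic cohort; score held-out subjects.

    Returns epoch-, test- and subject-level macro accuracies plus the trained
    model and the evaluation report.
    """
    cfg = cfg if cfg is not None else TrainConfig(
        max_epochs=20, patience=4, rng_seed=seed)
    ds = make_disease_dataset(n_per_group=n_per_group,
                              tests_per_subject=tests_per_subject,
                              duration_s=duration_s, seed=seed, m=m)
    train_ds, test_ds = split_subjects(ds, n_test_per_class, seed=seed)
    model = build_dcnn(ds.label_space, rng_seed=seed)
    model, history = train(model, balance_classes(train_ds, rng=seed), cfg)
    report = evaluate_split(model, test_ds)
    return {
        "model": model, "report": report, "history": history,
        "dataset": ds, "test_dataset": test_ds,
        "epoch_macro_accuracy": report["epoch"].accuracy,
        "test_macro_accuracy": report["test"].accuracy,
        "subject_macro_accuracy": report["subject"].accuracy,
    }


def transfer_benefit(seed: int = 0, n_target_train_per_class: int = 6,
                     n_target_test_per_class: int = 3,
                     n_per_group: int = 10, duration_s: float = 16.0,
                     tests_per_subject: int = 4, m: int = 4,
                     cfg: TrainConfig | None = None) -> dict:
    """Low-data comparison: fine-tuned transfer vs end-to-end training.

    The target training set is restricted to ``n_target_train_per_class``
    subjects per class; the source model is trained on the synthetic activity
    domain. Returns subject-wise accuracies under both regimes.
    """
    cfg = cfg if cfg is not None else TrainConfig(
        max_epochs=20, patience=4, rng_seed=seed)
    target = make_disease_dataset(n_per_group=n_per_group,
                                  tests_per_subject=tests_per_subject,
                                  duration_s=duration_s, seed=seed, m=m)
    train_ds, test_ds = split_subjects(
        target, n_target_test_per_class, seed=seed,
        n_train_per_class=n_target_train_per_class)
    train_ds = balance_classes(train_ds, rng=seed)
    source = make_har_dataset(seed=seed + 1000)

    _, ft = run_transfer_experiment(source, train_ds, test_ds,
                                    TransferPlan("fine_tune"), cfg)
    _, e2e = run_transfer_experiment(None, train_ds, test_ds,
                                     TransferPlan("end_to_end"), cfg)
    return {
        "fine_tune_subject_accuracy": ft["subject"].accuracy,
        "end_to_end_subject_accuracy": e2e["subject"].accuracy,
        "fine_tune_report": ft, "end_to_end_report": e2e,
    }


def lrp_conservation_study(n_networks: int = 20, n_epochs_each: int = 10,
                           seed: int = 0, input_length: int = 64) -> dict:
    """Conservation of relevance on zero-bias, alpha1beta0-everywhere nets.

    Builds random ReLU conv/dense stacks without biases, explains random
    epochs, and reports the worst relative difference between the input
    relevance sum and the explained logit.
    """
    rng = np.random.default_rng(seed)
    cfg = LrpConfig(rule_map={"conv1d": "alphabeta", "dense": "alphabeta"})
    errors = []
    for i in range(n_networks):
        filters = int(rng.integers(3, 9))
        kernel = int(rng.integers(3, 8))
        arch = (
            ("conv1d", {"filters": filters, "kernel": kernel}),
            ("relu", {}),
            ("maxpool1d", {"size": 2}),
            ("conv1d", {"filters": filters, "kernel": 3}),
            ("relu", {}),
            ("maxpool1d", {"size": 2}),
            ("flatten", {}),
            ("dense", {"units": int(rng.integers(5, 20))}),
            ("relu", {}),
            ("dense", {"units": None}),
            ("softmax", {}),
        )
        model = build_dcnn(("A", "B", "C"), arch=arch,
                           rng_seed=int(rng.integers(2**31)),
                           use_bias=False, input_length=input_length)
        for _ in range(n_epochs_each):
            x = rng.normal(size=(4, input_length))
            rmap = lrp_decompose(model, x, cfg)
            errors.append(rmap.conservation_error())
    return {"max_relative_error": float(np.max(errors)),
            "mean_relative_error": float(np.mean(errors)),
            "n": len(errors)}


def representative_study(model: ModelGraph, ds: EpochDataset,
                         selection: DbaSelection | None = None,
                         seed: int = 0) -> dict:
    """DBA representative epoch per class from out-of-sample predictions."""
    selection = selection if selection is not None else DbaSelection(
        n_epochs=60, rng_seed=seed)
    probs = predict_proba(model, ds.X)
    lut = {lab: i for i, lab in enumerate(model.label_space)}
    frame = pd.DataFrame({
        "index": np.arange(len(ds)),
        "test_id": ds.test_ids,
        "label": ds.labels,
        "pred": [model.label_space[i] for i in probs.argmax(axis=1)],
        "prob": [probs[i, lut[l]] for i, l in enumerate(ds.labels)],
    })
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", UserWarning)
        chosen = select_epochs(frame, selection, rng=seed)
    reps = {}
    for cls, idx in chosen.items():
        rep = dba_average(ds.X[idx], label=cls)
        reps[cls] = score_representative(model, rep)
    return reps
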