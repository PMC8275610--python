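"""Subject-wise cross-validated evaluation with hierarchical majority voting.

Validity hinges on the subject being the unit of partitioning: folds split
subjects, never epochs, so no individual contributes to both training and
testing (the no-leakage property is hard-asserted on every fold). Epoch
predictions are aggregated to a test-level label by majority vote, and test
labels to a subject-level label the same way.

Metrics follow the multi-class conventions: macro accuracy (mean of per-class
recalls), macro-F1 (unweighted mean of per-class F1) and Cohen's kappa with
marginal-product expected agreement. Headline numbers are reported for one
seeded cross-validation run as the pooled subject-wise outcome, with test-wise
median and interquartile range across the folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .model import ModelGraph, TrainConfig, predict_proba, train
from .preprocessing import EpochDataset, balance_classes

__all__ = [
    "FoldSplit", "MetricsReport", "SEVERITY_ORDER",
    "make_folds", "majority_vote", "compute_metrics",
    "evaluate_split", "evaluate_cv", "assert_no_leakage",
]

#: Tie-break severity ranking: later entries are "more severe".
SEVERITY_ORDER = ("HC", "PwMSmild", "PwMSmod")


@dataclass
class FoldSplit:
    fold_id: int
    train_subjects: np.ndarray
    val_subjects: np.ndarray
    test_subjects: np.ndarray

    def __post_init__(self) -> None:
        sets = [set(self.train_subjects), set(self.val_subjects),
                set(self.test_subjects)]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError("fold subject sets overlap")


@dataclass
class MetricsReport:
    """Macro accuracy / Cohen's kappa / macro-F1 at one aggregation level."""

    level: str
    accuracy: float
    kappa: float
    mf1: float
    confusion: np.ndarray
    n: int

    def as_dict(self) -> dict:
        return {"level": self.level, "accuracy": self.accuracy,
                "kappa": self.kappa, "mf1": self.mf1, "n": self.n}


def make_folds(subjects: np.ndarray, groups: np.ndarray, k: int = 5,
               rng: int | np.random.Generator | None = 0,
               val_fraction: float = 0.10) -> list[FoldSplit]:
    """Stratified k-fold partition of subjects (default k = 5).

    Each subject is tested exactly once across folds; within each training
    set, roughly ``val_fraction`` of subjects per class are carved out for
    validation. Falls back to unstratified folds with a warning when a group
    has fewer members than k.
    """
    subjects = np.asarray(subjects)
    groups = np.asarray(groups)
    if len(subjects) != len(groups):
        raise ValueError("subjects and groups length mismatch")
    if len(np.unique(subjects)) != len(subjects):
        raise ValueError("duplicate subject ids")
    if len(subjects) < k:
        raise ValueError(f"{len(subjects)} subjects cannot fill {k} folds")
    seed = rng if isinstance(rng, (int, np.integer)) or rng is None else None
    if seed is None and isinstance(rng, np.random.Generator):
        seed = int(rng.integers(2**31))
    _, counts = np.unique(groups, return_counts=True)
    if counts.min() >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        warnings.warn("a group has fewer subjects than folds; "
                      "falling back to unstratified folds")
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    val_rng = np.random.default_rng(seed)
    folds = []
    for fold_id, (train_idx, test_idx) in enumerate(splitter.split(subjects, groups)):
        train_s, train_g = subjects[train_idx], groups[train_idx]
        val_subjects = []
        for cls in np.unique(train_g):
            cls_subj = train_s[train_g == cls]
            n_val = max(1, int(round(val_fraction * cls_subj.size)))
            n_val = min(n_val, cls_subj.size - 1)
            if n_val > 0:
                val_subjects.extend(
                    val_rng.choice(cls_subj, size=n_val, replace=False))
        val_subjects = np.array(val_subjects)
        folds.append(FoldSplit(
            fold_id=fold_id,
            train_subjects=np.setdiff1d(train_s, val_subjects),
            val_subjects=val_subjects,
            test_subjects=subjects[test_idx]))
    return folds


def majority_vote(labels, probabilities: np.ndarray | None = None,
                  label_space: tuple[str, ...] | None = None,
                  severity_order: tuple[str, ...] = SEVERITY_ORDER) -> str:
    """Modal label with a deterministic tie-break.

    Ties between modal labels are broken by the higher mean predicted
    probability across the tied classes (requires ``probabilities``, one row
    per vote, columns ordered as ``label_space``); a residual tie goes to the
    more severe class (order given by ``severity_order``, falling back to
    lexicographic for labels outside it).
    """
    labels = list(labels)
    if not labels:
        raise ValueError("majority_vote of empty list")
    uniq, counts = np.unique(labels, return_counts=True)
    tied = list(uniq[counts == counts.max()])
    if len(tied) == 1:
        return str(tied[0])
    if probabilities is not None and label_space is not None:
        probs = np.asarray(probabilities, dtype=float)
        means = {c: probs[:, label_space.index(c)].mean() for c in tied}
        top = max(means.values())
        tied = [c for c in tied if means[c] >= top - 1e-12]
        if len(tied) == 1:
            return str(tied[0])

    def severity(c: str) -> tuple:
        return (severity_order.index(c), "") if c in severity_order else (len(severity_order), c)

    return str(max(tied, key=severity))


def compute_metrics(true_labels, pred_labels,
                    label_space: tuple[str, ...] | None = None,
                    level: str = "epoch") -> MetricsReport:
    """Macro accuracy, Cohen's kappa and macro-F1 from label vectors.

    macro accuracy = mean of per-class recalls; MF1 = unweighted mean of
    per-class F1; kappa = (p_o - p_e) / (1 - p_e) with the expected agreement
    p_e from the product of row/column marginals.
    """
    true_labels = np.asarray(true_labels)
    pred_labels = np.asarray(pred_labels)
    if len(true_labels) != len(pred_labels):
        raise ValueError("label vectors differ in length")
    if label_space is None:
        label_space = tuple(sorted(set(true_labels) | set(pred_labels)))
    outside = (set(true_labels) | set(pred_labels)) - set(label_space)
    if outside:
        raise ValueError(f"labels outside label_space: {sorted(outside)}")
    k = len(label_space)
    lut = {lab: i for i, lab in enumerate(label_space)}
    cm = np.zeros((k, k), dtype=int)  # rows = true, cols = predicted
    for t, p in zip(true_labels, pred_labels):
        cm[lut[t], lut[p]] += 1
    n = cm.sum()
    row = cm.sum(axis=1).astype(float)
    col = cm.sum(axis=0).astype(float)
    diag = np.diag(cm).astype(float)

    present = row > 0
    recall = np.divide(diag, row, out=np.zeros(k), where=row > 0)
    precision = np.divide(diag, col, out=np.zeros(k), where=col > 0)
    denom = precision + recall
    f1 = np.divide(2 * precision * recall, denom, out=np.zeros(k),
                   where=denom > 0)
    macro_acc = float(recall[present].mean()) if present.any() else 0.0
    mf1 = float(f1[present].mean()) if present.any() else 0.0

    p_o = float(diag.sum() / n) if n else 0.0
    p_e = float((row * col).sum() / n**2) if n else 0.0
    kappa = 1.0 if p_e >= 1.0 - 1e-15 else (p_o - p_e) / (1.0 - p_e)
    return MetricsReport(level=level, accuracy=macro_acc, kappa=float(kappa),
                         mf1=mf1, confusion=cm, n=int(n))


def assert_no_leakage(folds: list[FoldSplit]) -> None:
    """Hard assertion: train/val/test subject sets never intersect, and every
    subject is tested exactly once across folds."""
    tested: list = []
    for f in folds:
        assert not set(f.train_subjects) & set(f.test_subjects), \
            f"fold {f.fold_id}: train/test subject leakage"
        assert not set(f.val_subjects) & set(f.test_subjects), \
            f"fold {f.fold_id}: val/test subject leakage"
        tested.extend(f.test_subjects)
    assert len(tested) == len(set(tested)), "a subject is tested more than once"


def _aggregate(dataset: EpochDataset, probs: np.ndarray,
               label_space: tuple[str, ...]) -> pd.DataFrame:
    """Epoch probabilities -> one row per (subject, test) with a voted label."""
    pred_idx = probs.argmax(axis=1)
    pred_lab = np.array([label_space[i] for i in pred_idx])
    df = pd.DataFrame({"subject_id": dataset.subject_ids,
                       "test_id": dataset.test_ids,
                       "true": dataset.labels, "pred": pred_lab})
    rows = []
    for (sid, tid), grp in df.groupby(["subject_id", "test_id"], sort=True):
        p = probs[grp.index.to_numpy()]
        rows.append({"subject_id": sid, "test_id": tid,
                     "true": grp["true"].iloc[0],
                     "pred": majority_vote(grp["pred"], p, label_space),
                     "mean_probs": p.mean(axis=0)})
    return pd.DataFrame(rows)


def evaluate_split(model: ModelGraph, test_dataset: EpochDataset) -> dict:
    """Predict a held-out split and report epoch/test/subject-level metrics."""
    label_space = model.label_space
    probs = predict_proba(model, test_dataset.X)
    pred_lab = np.array([label_space[i] for i in probs.argmax(axis=1)])
    epoch_report = compute_metrics(test_dataset.labels, pred_lab,
                                   label_space, level="epoch")
    tests = _aggregate(test_dataset, probs, label_space)
    test_report = compute_metrics(tests["true"], tests["pred"], label_space,
                                  level="test")
    subj_rows = []
    for sid, grp in tests.groupby("subject_id", sort=True):
        p = np.stack(grp["mean_probs"].to_list())
        subj_rows.append({"subject_id": sid, "true": grp["true"].iloc[0],
                          "pred": majority_vote(grp["pred"], p, label_space)})
    subjects = pd.DataFrame(subj_rows)
    subject_report = compute_metrics(subjects["true"], subjects["pred"],
                                     label_space, level="subject")
    return {"epoch": epoch_report, "test": test_report,
            "subject": subject_report, "tests": tests, "subjects": subjects,
            "probs": probs}


def evaluate_cv(model_factory, dataset: EpochDataset,
                folds: list[FoldSplit] | int = 5,
                cfg: TrainConfig = TrainConfig(),
                balance: bool = True,
                rng: int | None = 0) -> dict:
    """Full subject-wise cross-validation of a model factory.

    ``model_factory(label_space, seed)`` must return a fresh ModelGraph.
    Training folds are class-balanced by oversampling (test folds never are).
    Returns pooled subject-wise metrics, per-fold test-wise metrics with their
    median/IQR, and the per-level reports of every fold.
    """
    subj = dataset.subjects
    subj_groups = np.array([dataset.labels[dataset.subject_ids == s][0]
                            for s in subj])
    if isinstance(folds, int):
        folds = make_folds(subj, subj_groups, k=folds, rng=rng)
    assert_no_leakage(folds)

    all_tests, all_subjects = [], []
    fold_reports = []
    for fold in folds:
        train_mask = np.isin(dataset.subject_ids, fold.train_subjects)
        val_mask = np.isin(dataset.subject_ids, fold.val_subjects)
        test_mask = np.isin(dataset.subject_ids, fold.test_subjects)
        train_ds = dataset.subset(train_mask)
        val_ds = dataset.subset(val_mask)
        test_ds = dataset.subset(test_mask)
        if len(test_ds) == 0:
            warnings.warn(f"fold {fold.fold_id}: no test epochs; skipped")
            continue
        if balance:
            train_ds = balance_classes(train_ds, rng=cfg.rng_seed + fold.fold_id)
            if len(val_ds):
                val_ds = balance_classes(val_ds, rng=cfg.rng_seed + fold.fold_id)
        model = model_factory(dataset.label_space, cfg.rng_seed + fold.fold_id)
        model, _ = train(model, train_ds, cfg,
                         val_dataset=val_ds if len(val_ds) else None)
        rep = evaluate_split(model, test_ds)
        fold_reports.append(rep)
        all_tests.append(rep["tests"])
        all_subjects.append(rep["subjects"])

    tests = pd.concat(all_tests, ignore_index=True)
    subjects = pd.concat(all_subjects, ignore_index=True)
    subject_report = compute_metrics(subjects["true"], subjects["pred"],
                                     dataset.label_space, level="subject")
    testwise = pd.DataFrame([{
        "fold": i,
        "accuracy": r["test"].accuracy,
        "kappa": r["test"].kappa,
        "mf1": r["test"].mf1,
    } for i, r in enumerate(fold_reports)])
    summary = {m: {"median": float(testwise[m].median()),
                   "iqr": (float(testwise[m].quantile(0.25)),
                           float(testwise[m].quantile(0.75)))}
               for m in ("accuracy", "kappa", "mf1")}
    return {"subject": subject_report, "testwise": summary,
            "testwise_per_fold": testwise, "folds": fold_reports,
            "tests": tests, "subjects": subjects}
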