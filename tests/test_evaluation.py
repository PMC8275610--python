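"""Fold construction, majority voting, metrics and CV aggregation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import balanced_accuracy_score, cohen_kappa_score, f1_score

from gaitscope import evaluation as ev
from gaitscope import preprocessing as pp


def _subjects(n_per_group=10, groups=("HC", "PwMSmild", "PwMSmod")):
    subs = np.array([f"{g}{i}" for g in groups for i in range(n_per_group)])
    grps = np.array([g for g in groups for _ in range(n_per_group)])
    return subs, grps


class TestFolds:
    def test_stratified_partition_two_per_group_per_fold(self):
        subs, grps = _subjects(10)
        folds = ev.make_folds(subs, grps, k=5, rng=0)
        lut = dict(zip(subs, grps))
        for f in folds:
            counts = pd.Series([lut[s] for s in f.test_subjects]).value_counts()
            assert (counts == 2).all()

    def test_test_folds_partition_all_subjects(self):
        subs, grps = _subjects(7)
        folds = ev.make_folds(subs, grps, k=5, rng=1)
        tested = np.concatenate([f.test_subjects for f in folds])
        assert sorted(tested) == sorted(subs)
        assert len(set(tested)) == len(tested)

    def test_validation_carved_from_training_subjects(self):
        subs, grps = _subjects(10)
        for f in ev.make_folds(subs, grps, k=5, rng=2):
            assert len(f.val_subjects) > 0
            assert not set(f.val_subjects) & set(f.test_subjects)
            assert not set(f.val_subjects) & set(f.train_subjects)

    def test_same_seed_identical_folds(self):
        subs, grps = _subjects(6)
        a = ev.make_folds(subs, grps, k=3, rng=5)
        b = ev.make_folds(subs, grps, k=3, rng=5)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa.test_subjects, fb.test_subjects)
            assert np.array_equal(fa.train_subjects, fb.train_subjects)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            ev.make_folds(np.array(["a", "b"]), np.array(["x", "y"]), k=5)

    def test_small_group_falls_back_with_warning(self):
        subs = np.array([f"s{i}" for i in range(8)])
        grps = np.array(["A"] * 6 + ["B"] * 2)
        with pytest.warns(UserWarning, match="fewer subjects"):
            folds = ev.make_folds(subs, grps, k=4, rng=0)
        assert len(folds) == 4


class TestMajorityVote:
    def test_simple_majority(self):
        assert ev.majority_vote(["A", "A", "B"]) == "A"

    def test_singleton(self):
        assert ev.majority_vote(["A"]) == "A"

    def test_probability_tie_break(self):
        """Rule-branch oracle: tie on counts -> higher mean probability wins."""
        probs = np.array([[0.9, 0.1], [0.2, 0.8]])
        assert ev.majority_vote(["A", "B"], probs, ("A", "B")) == "A"
        probs = np.array([[0.6, 0.4], [0.1, 0.9]])
        assert ev.majority_vote(["A", "B"], probs, ("A", "B")) == "B"

    def test_severity_tie_break_without_probabilities(self):
        assert ev.majority_vote(["HC", "PwMSmod"]) == "PwMSmod"
        assert ev.majority_vote(["HC", "PwMSmild"]) == "PwMSmild"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ev.majority_vote([])

    def test_duplicating_votes_never_changes_outcome(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            labels = list(rng.choice(["HC", "PwMSmild", "PwMSmod"],
                                     size=rng.integers(1, 9)))
            assert ev.majority_vote(labels) == ev.majority_vote(labels * 2)


def _labels_from_cm(cm, label_space):
    true, pred = [], []
    for i, ti in enumerate(label_space):
        for j, pj in enumerate(label_space):
            true.extend([ti] * cm[i][j])
            pred.extend([pj] * cm[i][j])
    return np.array(true), np.array(pred)


class TestMetrics:
    def test_perfect_prediction(self):
        r = ev.compute_metrics(["A", "B", "A"], ["A", "B", "A"])
        assert r.accuracy == r.kappa == r.mf1 == 1.0

    def test_worked_confusion_matrix(self):
        """Direct-formula oracle on [[40,10],[20,30]]: kappa = 0.4,
        MF1 = mean(0.727, 0.667) ~ 0.697."""
        true, pred = _labels_from_cm([[40, 10], [20, 30]], ("A", "B"))
        r = ev.compute_metrics(true, pred, ("A", "B"))
        assert r.kappa == pytest.approx(0.4, abs=1e-12)
        assert r.mf1 == pytest.approx((8 / 11 + 2 / 3) / 2, abs=1e-12)
        assert r.accuracy == pytest.approx(0.7, abs=1e-12)

    def test_matches_sklearn_on_random_confusions(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            k = int(rng.integers(2, 5))
            cm = rng.integers(1, 25, size=(k, k))
            space = tuple(f"c{i}" for i in range(k))
            true, pred = _labels_from_cm(cm, space)
            r = ev.compute_metrics(true, pred, space)
            assert r.kappa == pytest.approx(
                cohen_kappa_score(true, pred, labels=list(space)), abs=1e-9)
            assert r.mf1 == pytest.approx(
                f1_score(true, pred, labels=list(space), average="macro"),
                abs=1e-9)
            assert r.accuracy == pytest.approx(
                balanced_accuracy_score(true, pred), abs=1e-9)

    def test_label_outside_space_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            ev.compute_metrics(["A"], ["Z"], ("A", "B"))


class _OracleModel:
    """Stand-in classifier that reads the class encoded in channel 0 mean."""

    def __init__(self, label_space):
        self.label_space = tuple(label_space)

    def predict_proba(self, X):
        means = X[:, 0, :].mean(axis=1)
        idx = np.clip(np.round(means).astype(int), 0, len(self.label_space) - 1)
        out = np.full((len(X), len(self.label_space)), 1e-6)
        out[np.arange(len(X)), idx] = 1.0
        return out / out.sum(axis=1, keepdims=True)


def _encoded_dataset(n_subj=6, tests=3, epochs_per_test=4,
                     classes=("HC", "PwMSmod")):
    X, labels, sids, tids, starts = [], [], [], [], []
    for ci, cls in enumerate(classes):
        for s in range(n_subj):
            for t in range(tests):
                for e in range(epochs_per_test):
                    x = np.zeros((4, 128))
                    x[0, :] = ci
                    X.append(x)
                    labels.append(cls)
                    sids.append(f"{cls}{s}")
                    tids.append(f"{cls}{s}t{t}")
                    starts.append(64 * e)
    return pp.EpochDataset(np.stack(X), np.array(labels), np.array(sids),
                           np.array(tids), np.array(starts), tuple(classes))


class TestEvaluateSplit:
    def test_ground_truth_oracle_scores_one_at_every_level(self):
        ds = _encoded_dataset()
        rep = ev.evaluate_split(_OracleModel(ds.label_space), ds)
        assert rep["epoch"].accuracy == 1.0
        assert rep["test"].accuracy == 1.0
        assert rep["subject"].accuracy == 1.0

    def test_duplicating_epochs_leaves_votes_unchanged(self):
        ds = _encoded_dataset(n_subj=2)
        doubled = pp.EpochDataset(
            np.concatenate([ds.X, ds.X]),
            np.concatenate([ds.labels, ds.labels]),
            np.concatenate([ds.subject_ids, ds.subject_ids]),
            np.concatenate([ds.test_ids, ds.test_ids]),
            np.concatenate([ds.starts, ds.starts]),
            ds.label_space,
            np.concatenate([ds.draws, ds.draws + 1]))
        a = ev.evaluate_split(_OracleModel(ds.label_space), ds)
        b = ev.evaluate_split(_OracleModel(ds.label_space), doubled)
        pd.testing.assert_frame_equal(
            a["subjects"].reset_index(drop=True),
            b["subjects"].reset_index(drop=True))

    def test_random_classifier_kappa_near_zero(self):
        """Null-simulation oracle: a label-blind classifier has subject-wise
        kappa ~ 0 on balanced two-class data."""
        class RandomModel:
            def __init__(self, label_space, seed):
                self.label_space = tuple(label_space)
                self.rng = np.random.default_rng(seed)

            def predict_proba(self, X):
                p = self.rng.uniform(size=(len(X), 2))
                return p / p.sum(axis=1, keepdims=True)

        ds = _encoded_dataset(n_subj=10)
        kappas = [ev.evaluate_split(RandomModel(ds.label_space, s), ds)
                  ["subject"].kappa for s in range(10)]
        assert abs(np.mean(kappas)) < 0.2

    def test_no_leakage_assertion_fires_on_overlap(self):
        with pytest.raises(ValueError, match="overlap"):
            ev.FoldSplit(0, np.array(["a", "b"]), np.array(["c"]),
                         np.array(["a"]))
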