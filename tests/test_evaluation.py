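"""Fold construction, partition invariants, and pooled metrics vs oracles."""

import numpy as np
import pytest

from skillseq.classifier import PredictionRecord
from skillseq.evaluation import (
    FoldPlan,
    classification_metrics,
    make_folds,
    per_fold_metric,
    regression_metrics,
)
from skillseq.sequences import SequenceDataset, ValidationError
from conftest import make_trial


def labelled_dataset(n_subjects=3, trials_per_subject=5, imbalance=None):
    """Tiny labelled dataset; `imbalance` forces a pass/fail count split."""
    trials = []
    count = 0
    total = n_subjects * trials_per_subject
    n_pass = total // 2 if imbalance is None else imbalance[0]
    for s in range(n_subjects):
        for r in range(trials_per_subject):
            label = "pass" if count < n_pass else "fail"
            trials.append(make_trial(np.zeros((3, 4)) + count,
                                     trial_id=f"s{s}_t{r}", subject_id=f"s{s}",
                                     label=label, score=float(100 - count)))
            count += 1
    return SequenceDataset(trials, ["pass", "fail"])


class TestMakeFolds:
    def test_louo_no_subject_overlap(self):
        ds = labelled_dataset(n_subjects=3)
        plan = make_folds(ds, "louo")
        assert plan.k == 3
        subj = {t.trial_id: t.subject_id for t in ds}
        for train, val, test in plan.folds:
            test_subjects = {subj[i] for i in test}
            assert len(test_subjects) == 1
            assert test_subjects.isdisjoint({subj[i] for i in train + val})

    def test_loso_tests_each_repetition_once(self):
        ds = labelled_dataset(n_subjects=3, trials_per_subject=5)
        plan = make_folds(ds, "loso")
        assert plan.k == 5
        for rep, (train, val, test) in enumerate(plan.folds):
            assert sorted(test) == sorted(f"s{s}_t{rep}" for s in range(3))

    def test_stratified_preserves_class_ratio(self):
        ds = labelled_dataset(n_subjects=10, trials_per_subject=10,
                              imbalance=(90, 10))
        plan = make_folds(ds, "stratified_kfold", k=10, seed=0)
        labels = {t.trial_id: t.label for t in ds}
        for train, val, test in plan.folds:
            test_labels = [labels[i] for i in test]
            assert test_labels.count("pass") == 9
            assert test_labels.count("fail") == 1

    def test_partition_property(self):
        ds = labelled_dataset(n_subjects=4, trials_per_subject=6)
        for scheme in ("stratified_kfold", "loso", "louo"):
            plan = make_folds(ds, scheme, k=4, seed=1)
            all_test = [i for _, _, test in plan.folds for i in test]
            assert sorted(all_test) == sorted(t.trial_id for t in ds)

    def test_validation_carved_from_training(self):
        ds = labelled_dataset(n_subjects=10, trials_per_subject=10)
        plan = make_folds(ds, "stratified_kfold", k=10, seed=0)
        for train, val, test in plan.folds:
            assert len(val) == round(0.1 * (len(train) + len(val)))
            assert set(val).isdisjoint(test) and set(val).isdisjoint(train)

    def test_louo_single_subject_rejected(self):
        ds = labelled_dataset(n_subjects=1, trials_per_subject=6)
        with pytest.raises(ValidationError):
            make_folds(ds, "louo")

    def test_empty_test_fold_rejected(self):
        with pytest.raises(ValidationError):
            FoldPlan(scheme="holdout", folds=[(["a"], ["b"], [])], k=1, seed=0)

    def test_train_test_disjoint_validated(self):
        with pytest.raises(ValidationError):
            FoldPlan(scheme="holdout", folds=[(["a"], ["b"], ["a"])], k=1, seed=0)


def make_records(y_true, y_pred, p_pass, scores=None):
    recs = []
    for i, (t, p, prob) in enumerate(zip(y_true, y_pred, p_pass)):
        recs.append(PredictionRecord(
            trial_id=f"t{i}", true_class=t, predicted_class=p,
            confidence=max(prob, 1 - prob),
            class_probabilities=[prob, 1 - prob],
            class_names=["pass", "fail"],
            true_score=None if scores is None else scores[0][i],
            predicted_score=None if scores is None else scores[1][i],
            fold_id=i % 2,
        ))
    return recs


class TestClassificationMetrics:
    def test_perfect_classifier(self):
        y = ["pass"] * 5 + ["fail"] * 5
        p = [0.9] * 5 + [0.1] * 5
        rep = classification_metrics(make_records(y, y, p))
        assert rep.accuracy == rep.sensitivity == rep.specificity == rep.auc == 1.0

    def test_hand_computed_confusion(self):
        """TP=9, FN=1, TN=8, FP=2 -> sens 0.9, spec 0.8, acc 0.85."""
        y_true = ["pass"] * 10 + ["fail"] * 10
        y_pred = ["pass"] * 9 + ["fail"] + ["pass"] * 2 + ["fail"] * 8
        probs = [0.9 if p == "pass" else 0.1 for p in y_pred]
        rep = classification_metrics(make_records(y_true, y_pred, probs))
        assert rep.sensitivity == pytest.approx(0.9)
        assert rep.specificity == pytest.approx(0.8)
        assert rep.accuracy == pytest.approx(0.85)
        assert rep.confusion.sum() == 20

    def test_auc_equals_pairwise_concordance(self, rng):
        """Pooled AUC equals the brute-force P(score_pos > score_neg) estimate."""
        for _ in range(5):
            n = 40
            y_true = ["pass" if v else "fail" for v in rng.random(n) < 0.5]
            if len(set(y_true)) < 2:
                continue
            p_pass = rng.random(n)
            y_pred = ["pass" if p >= 0.5 else "fail" for p in p_pass]
            rep = classification_metrics(make_records(y_true, y_pred, p_pass))
            pos = [p for p, t in zip(p_pass, y_true) if t == "pass"]
            neg = [p for p, t in zip(p_pass, y_true) if t == "fail"]
            conc = np.mean([(a > b) + 0.5 * (a == b) for a in pos for b in neg])
            assert rep.auc == pytest.approx(conc)

    def test_single_class_pool_rejected(self):
        y = ["pass"] * 4
        with pytest.raises(ValidationError):
            classification_metrics(make_records(y, y, [0.9] * 4))


class TestRegressionMetrics:
    def test_reverse_ranking_rho_minus_one(self):
        true = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0]
        pred = true[::-1]
        rep = regression_metrics(make_records(
            ["pass"] * 10, ["pass"] * 10, [0.9] * 10, scores=(true, pred)))
        assert rep.spearman_rho == pytest.approx(-1.0)

    def test_rho_equals_rank_pearson(self, rng):
        from scipy.stats import rankdata
        true = rng.normal(size=30)
        pred = 0.6 * true + rng.normal(size=30)
        rep = regression_metrics(make_records(
            ["pass"] * 30, ["pass"] * 30, [0.9] * 30, scores=(true, pred)))
        ref = np.corrcoef(rankdata(true), rankdata(pred))[0, 1]
        assert rep.spearman_rho == pytest.approx(ref)


class TestPerFoldMetric:
    def test_fold_accuracy_split(self):
        y_true = ["pass", "fail"] * 4
        y_pred = ["pass", "pass"] * 4  # fold 0 records all correct, fold 1 all wrong
        recs = make_records(y_true, y_pred, [0.9] * 8)
        acc = per_fold_metric(recs, "accuracy")
        assert acc.tolist() == [1.0, 0.0]
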