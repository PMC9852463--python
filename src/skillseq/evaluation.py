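"""Cross-validation planning, the full training pipeline, and pooled metrics.

Three fold schemes mirror standard practice in skill-assessment studies:
stratified k-fold (class ratio preserved per fold), leave-one-supertrial-out
(LOSO: fold *i* tests the *i*-th repetition of every subject) and
leave-one-user-out (LOUO: each fold tests all trials of one subject, so the
model must generalize to unseen people).  A validation split for early
stopping is carved from each fold's training trials.

:func:`run_cv` executes the whole pipeline per fold — normalization fit on
the fold's training split only, DAE training, encoding, classifier or
regressor training, test-set prediction — and pools the predictions across
folds; repeating it for several sessions with fresh seeds yields the
mean +/- sd breakdown.  Metrics come from the pooled confusion matrix
(accuracy, sensitivity, specificity), the pooled ROC (AUC) and the Spearman
rank correlation of true vs predicted scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import stats as sq_stats
from .classifier import (
    CLASSIFICATION,
    REGRESSION,
    ClassifierModel,
    PredictionRecord,
    ResidualBlockConfig,
    TrainConfig,
    build_classifier,
    predict,
    train_classifier,
)
from .embedding import DAEConfig, DAEModel, build_dae, encode, train_dae
from .sequences import (
    SequenceDataset,
    ValidationError,
    apply_normalization,
    encode_targets,
    fit_normalization,
)

SCHEMES = ("holdout", "stratified_kfold", "loso", "louo")


@dataclass
class FoldPlan:
    """Ordered train/validation/test trial-id splits for one CV scheme."""

    scheme: str
    folds: list[tuple[list[str], list[str], list[str]]]
    k: int
    seed: int

    def __post_init__(self) -> None:
        for train_ids, val_ids, test_ids in self.folds:
            overlap = (set(train_ids) | set(val_ids)) & set(test_ids)
            if overlap:
                raise ValidationError(f"trials in both train and test: {sorted(overlap)}")
            if not test_ids:
                raise ValidationError("empty test fold")


@dataclass
class MetricReport:
    n: int
    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    auc: float | None = None
    spearman_rho: float | None = None
    spearman_p: float | None = None
    confusion: np.ndarray | None = None

    def as_dict(self) -> dict:
        out = {"n": self.n}
        for name in ("accuracy", "sensitivity", "specificity", "auc",
                     "spearman_rho", "spearman_p"):
            value = getattr(self, name)
            if value is not None:
                out[name] = float(value)
        if self.confusion is not None:
            out["confusion"] = self.confusion.tolist()
        return out


def _carve_validation(
    train_ids: list[str],
    labels: dict[str, str | None],
    val_fraction: float,
    seed: int,
) -> tuple[list[str], list[str]]:
    """Split early-stopping validation trials out of a fold's training ids."""
    if len(train_ids) < 2:
        raise ValidationError("training split too small to carve validation from")
    n_val = max(1, int(round(val_fraction * len(train_ids))))
    y = [labels[i] for i in train_ids]
    strat = y if (None not in y and len(set(y)) > 1
                  and min(y.count(c) for c in set(y)) >= 2
                  and n_val >= len(set(y))) else None
    tr, va = train_test_split(train_ids, test_size=n_val, random_state=seed,
                              shuffle=True, stratify=strat)
    return list(tr), list(va)


def make_folds(
    ds: SequenceDataset,
    scheme: str,
    k: int = 10,
    seed: int = 0,
    val_fraction: float = 0.1,
) -> FoldPlan:
    """Build a cross-validation plan over the dataset's trial ids."""
    if scheme not in SCHEMES:
        raise ValidationError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    ids = [t.trial_id for t in ds]
    labels = {t.trial_id: t.label for t in ds}
    folds: list[tuple[list[str], list[str], list[str]]] = []

    if scheme == "stratified_kfold":
        y = [labels[i] for i in ids]
        if None in y:
            raise ValidationError("stratified folds require labels on every trial")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        raw = [([ids[i] for i in tr], [ids[i] for i in te])
               for tr, te in splitter.split(ids, y)]
    elif scheme == "loso":
        by_subject: dict[str, list[str]] = {}
        for t in ds:
            by_subject.setdefault(t.subject_id, []).append(t.trial_id)
        n_reps = max(len(v) for v in by_subject.values())
        raw = []
        for rep in range(n_reps):
            test = [v[rep] for v in by_subject.values() if rep < len(v)]
            train = [i for i in ids if i not in set(test)]
            raw.append((train, test))
    elif scheme == "louo":
        subjects = ds.subject_ids()
        if len(subjects) < 2:
            raise ValidationError("LOUO requires at least two subjects")
        raw = []
        for s in subjects:
            test = [t.trial_id for t in ds if t.subject_id == s]
            train = [t.trial_id for t in ds if t.subject_id != s]
            raw.append((train, test))
    else:  # holdout
        y = [labels[i] for i in ids]
        strat = y if None not in y else None
        train, test = train_test_split(ids, test_size=0.1, random_state=seed,
                                       shuffle=True, stratify=strat)
        raw = [(list(train), list(test))]

    for fold_idx, (train_ids, test_ids) in enumerate(raw):
        tr, va = _carve_validation(train_ids, labels, val_fraction,
                                   seed=seed * 1000 + fold_idx)
        folds.append((tr, va, list(test_ids)))
    return FoldPlan(scheme=scheme, folds=folds, k=len(folds), seed=seed)


def _onehot(ds: SequenceDataset, class_names: list[str]) -> np.ndarray:
    index = {c: i for i, c in enumerate(class_names)}
    out = np.zeros((ds.n_trials, len(class_names)))
    for row, t in enumerate(ds):
        if t.label is None:
            raise ValidationError(f"trial {t.trial_id} is unlabelled")
        out[row, index[t.label]] = 1.0
    return out


def _fold_seed(base_seed: int, session: int, fold: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), int(session), int(fold)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class FoldArtifacts:
    """Trained models and split bookkeeping for one fold of one session."""

    fold_id: int
    dae: DAEModel
    model: ClassifierModel
    stats: object
    test_ids: list[str] = field(default_factory=list)


def run_fold(
    ds: SequenceDataset,
    fold_id: int,
    split: tuple[list[str], list[str], list[str]],
    task: str,
    dae_cfg: DAEConfig,
    block_cfg: ResidualBlockConfig,
    train_cfg: TrainConfig,
    seed: int,
    reuse: FoldArtifacts | None = None,
    norm_override=None,
) -> tuple[list[PredictionRecord], FoldArtifacts]:
    """Train the DAE + head on one fold and predict its test trials.

    ``reuse`` supplies an already-trained DAE (and its normalization
    stats) from a previous run over the same fold: the embedding is
    unsupervised, so the classification and regression heads can share it.
    """
    train_ids, val_ids, test_ids = split
    if not test_ids:
        raise ValidationError("empty test fold")
    train_ds, val_ds, test_ds = (ds.subset(s) for s in (train_ids, val_ids, test_ids))

    if reuse is not None:
        norm = reuse.stats
    elif norm_override is not None:
        norm = norm_override
    else:
        norm = fit_normalization(train_ds)
    train_n = apply_normalization(train_ds, norm)
    val_n = apply_normalization(val_ds, norm)
    test_n = apply_normalization(test_ds, norm)

    if reuse is not None:
        dae = reuse.dae
    else:
        dae = build_dae(dc_replace(dae_cfg, seed=seed))
        dae, _ = train_dae(dae, train_n, val_n)
    emb_train = encode(dae, train_n)
    emb_val = encode(dae, val_n)
    emb_test = encode(dae, test_n)

    if task == CLASSIFICATION:
        _, class_weights = encode_targets(train_ds)
        y_train = _onehot(train_n, ds.class_names)
        y_val = _onehot(val_n, ds.class_names)
    else:
        class_weights = None
        y_train = np.array([t.score for t in train_n], dtype=float)
        y_val = np.array([t.score for t in val_n], dtype=float)
        if np.any(np.isnan(y_train)) or np.any(np.isnan(y_val)):
            raise ValidationError("regression requires a score on every trial")

    model = build_classifier(
        block_cfg, task=task, n_classes=max(2, len(ds.class_names)),
        d_in=dae_cfg.d_e, class_names=ds.class_names, seed=seed + 1,
    )
    model, _ = train_classifier(
        model, emb_train, y_train, emb_val, y_val,
        class_weights=class_weights, cfg=dc_replace(train_cfg, seed=seed + 2),
    )

    records = []
    for emb, trial in zip(emb_test, test_ds):
        records.append(predict(
            model, emb, stats=norm,
            true_class=trial.label if task == CLASSIFICATION else None,
            true_score=trial.score, fold_id=fold_id,
        ))
    artifacts = FoldArtifacts(fold_id=fold_id, dae=dae, model=model,
                              stats=norm, test_ids=list(test_ids))
    return records, artifacts


def run_cv(
    ds: SequenceDataset,
    plan: FoldPlan,
    task: str = CLASSIFICATION,
    dae_cfg: DAEConfig | None = None,
    block_cfg: ResidualBlockConfig | None = None,
    train_cfg: TrainConfig | None = None,
    sessions: int = 1,
    base_seed: int = 0,
    return_artifacts: bool = False,
    artifacts_in: list[FoldArtifacts] | None = None,
    normalization_scope: str = "fold_train",
):
    """Run the full pipeline over every fold, for one or more sessions.

    Returns a list (one entry per session) of pooled prediction-record
    lists; with ``return_artifacts`` each session also carries its per-fold
    trained models, which the saliency analysis re-uses.  ``artifacts_in``
    (single session only) re-uses previously trained per-fold DAEs and
    normalization stats, so a second head can be trained on the same
    embeddings without repeating the unsupervised stage.
    """
    if artifacts_in is not None and sessions != 1:
        raise ValidationError("artifacts_in requires sessions=1")
    if normalization_scope not in ("fold_train", "global"):
        raise ValidationError("normalization_scope must be 'fold_train' or 'global'")
    # "global" fits min-max/score stats on the full dataset once (the
    # leakage-prone but sometimes-reported variant); default refits per fold
    norm_override = fit_normalization(ds) if normalization_scope == "global" else None
    if task not in (CLASSIFICATION, REGRESSION):
        raise ValidationError(f"unknown task {task!r}")
    dae_cfg = dae_cfg or DAEConfig()
    block_cfg = block_cfg or ResidualBlockConfig()
    train_cfg = train_cfg or TrainConfig()
    session_records: list[list[PredictionRecord]] = []
    session_artifacts: list[list[FoldArtifacts]] = []
    for session in range(sessions):
        pooled: list[PredictionRecord] = []
        artifacts: list[FoldArtifacts] = []
        for fold_id, split in enumerate(plan.folds):
            seed = _fold_seed(base_seed, session, fold_id)
            reuse = artifacts_in[fold_id] if artifacts_in is not None else None
            records, art = run_fold(ds, fold_id, split, task,
                                    dae_cfg, block_cfg, train_cfg, seed,
                                    reuse=reuse, norm_override=norm_override)
            pooled.extend(records)
            artifacts.append(art)
        session_records.append(pooled)
        session_artifacts.append(artifacts)
    if return_artifacts:
        return session_records, session_artifacts
    return session_records


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def classification_metrics(
    records: list[PredictionRecord],
    positive_class: str = "pass",
) -> MetricReport:
    """Pooled confusion-matrix metrics plus ROC AUC.

    Sensitivity is the recall of ``positive_class``; specificity the recall
    of the complement.  AUC uses the pooled probability assigned to the
    positive class and requires both classes in the pool.
    """
    if len(records) < 2:
        raise ValidationError("need at least two prediction records")
    y_true = [r.true_class for r in records]
    y_pred = [r.predicted_class for r in records]
    if None in y_true or None in y_pred:
        raise ValidationError("classification metrics need class predictions")
    classes = sorted(set(y_true) | set(y_pred))
    if positive_class not in classes:
        raise ValidationError(f"positive_class {positive_class!r} not present")
    negatives = [c for c in classes if c != positive_class]
    order = [positive_class] + negatives
    cm = confusion_matrix(y_true, y_pred, labels=order)
    accuracy = float(np.trace(cm) / cm.sum())
    tp = cm[0, 0]
    fn = cm[0, 1:].sum()
    fp = cm[1:, 0].sum()
    tn = cm[1:, 1:].sum()
    sensitivity = float(tp / (tp + fn)) if tp + fn else np.nan
    specificity = float(tn / (tn + fp)) if tn + fp else np.nan
    if len(set(y_true)) < 2:
        raise ValidationError("AUC undefined: only one true class in the pool")
    pos_prob = []
    for r in records:
        if r.class_probabilities is None or r.class_names is None:
            raise ValidationError("records lack class probabilities")
        pos_prob.append(float(r.class_probabilities[r.class_names.index(positive_class)]))
    auc = float(roc_auc_score([c == positive_class for c in y_true], pos_prob))
    return MetricReport(n=len(records), accuracy=accuracy, sensitivity=sensitivity,
                        specificity=specificity, auc=auc, confusion=cm)


def regression_metrics(records: list[PredictionRecord]) -> MetricReport:
    """Spearman rank correlation of true vs predicted scores."""
    if len(records) < 2:
        raise ValidationError("need at least two prediction records")
    true = [r.true_score for r in records]
    pred = [r.predicted_score for r in records]
    if None in true or None in pred:
        raise ValidationError("regression metrics need scores on every record")
    rho, p = sq_stats.spearman(np.array(true), np.array(pred))
    return MetricReport(n=len(records), spearman_rho=rho, spearman_p=p)


def per_fold_metric(
    records: list[PredictionRecord],
    metric: str = "accuracy",
    positive_class: str = "pass",
) -> np.ndarray:
    """One metric value per fold, in fold order (for paired comparisons)."""
    folds = sorted({r.fold_id for r in records})
    if None in folds:
        raise ValidationError("records lack fold ids")
    values = []
    for f in folds:
        sub = [r for r in records if r.fold_id == f]
        if metric == "accuracy":
            values.append(float(np.mean([r.correct for r in sub])))
        else:
            report = classification_metrics(sub, positive_class=positive_class)
            values.append(float(getattr(report, metric)))
    return np.array(values)


def aggregate_reports(reports: list[MetricReport]) -> dict:
    """Mean +/- sd of each metric across sessions (or folds)."""
    out: dict[str, dict[str, float]] = {}
    for name in ("accuracy", "sensitivity", "specificity", "auc",
                 "spearman_rho", "spearman_p"):
        values = [getattr(r, name) for r in reports if getattr(r, name) is not None]
        if values:
            out[name] = {"mean": float(np.mean(values)), "sd": float(np.std(values))}
    return out
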