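"""Attention-residual classifier / score regressor over embedded sequences.

A single dilated attention-residual block produces per-timestamp feature
maps ``f_k(i)``; global average pooling collapses time (so trials of any
length share one model) and a fully connected head outputs either skill
class probabilities (two nodes, softmax) or a continuous performance score
(one node, no activation).  The pre-softmax head weights ``w_k^c`` are the
quantities the class-activation maps re-use, so the model keeps the block
activations of its last forward pass accessible.

Training uses batch size one, class-weighted cross-entropy (classification)
or mean squared error on z-normalized scores (regression), and early
stopping on validation loss with the best parameters restored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .embedding import EmbeddedSequence
from .sequences import NormalizationStats, ValidationError, denormalize_score

CLASSIFICATION = "classification"
REGRESSION = "regression"


@dataclass
class ResidualBlockConfig:
    """Shape of the classifier's attention-residual stage.

    ``n_blocks`` stacked blocks share the same width; depth lets the
    network compose local differences with positions (e.g. tangential
    displacement around a cutting path), which one block cannot express.
    """

    filters: int = 12
    kernel_size: int = 5
    dilation: int = 2
    scse_reduction: int = 2
    n_blocks: int = 2

    def __post_init__(self) -> None:
        if self.filters < 1:
            raise ValidationError("filters must be >= 1")
        if self.dilation < 1:
            raise ValidationError("dilation must be >= 1")
        if self.n_blocks < 1:
            raise ValidationError("n_blocks must be >= 1")


@dataclass
class TrainConfig:
    """Head-training settings.

    Batch-1 training of the attention-residual head occasionally collapses
    into a no-signal minimum (clearly visible as a high validation loss);
    ``restarts`` independent initializations are trained and the best by
    validation loss is kept.  With ``ensemble`` the restarts whose
    validation loss is within ``ensemble_tol`` of the best are averaged in
    probability space at prediction time.
    """

    max_epochs: int = 60
    patience: int = 20
    learning_rate: float = 2e-3
    seed: int = 0
    restarts: int = 3
    max_restarts: int = 6
    collapse_val_loss: float | None = None  # default set per task
    ensemble: bool = True
    ensemble_tol: float = 1.5
    # sd of Gaussian noise added to embedded inputs during training
    # (re-drawn each epoch); 0 disables the augmentation
    input_noise: float = 0.0


@dataclass
class PredictionRecord:
    """Per-trial outcome: truth, prediction and softmax confidence.

    For regression the class fields are ``None`` and the score fields are
    populated instead; ``confidence`` is the softmax probability of the
    predicted class, the quantity the trust metrics consume.
    """

    trial_id: str
    true_class: str | None = None
    predicted_class: str | None = None
    confidence: float | None = None
    class_probabilities: np.ndarray | None = None
    true_score: float | None = None
    predicted_score: float | None = None
    fold_id: int | None = None
    class_names: list[str] | None = None

    def __post_init__(self) -> None:
        if self.class_probabilities is not None:
            p = np.asarray(self.class_probabilities, dtype=float)
            if abs(p.sum() - 1.0) > 1e-6:
                raise ValidationError("class probabilities must sum to 1")
            self.class_probabilities = p
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValidationError("confidence must lie in [0, 1]")

    @property
    def correct(self) -> bool:
        return self.true_class is not None and self.true_class == self.predicted_class


@dataclass
class ClassifierModel:
    blocks: nn.Sequential
    gap: nn.GlobalAveragePool
    head: nn.Dense
    task: str
    class_names: list[str] = field(default_factory=list)
    d_in: int = 8
    trained: bool = False
    # committee of validation-selected restarts; first member is the lead
    # model (best validation loss), whose activations also provide the CAM
    members: list["ClassifierModel"] | None = None

    def params(self) -> list[nn.Param]:
        return self.blocks.params() + self.head.params()

    def forward_features(self, x: np.ndarray) -> np.ndarray:
        """Per-timestamp activations feeding GAP (used for activation maps)."""
        if x.shape[1] != self.d_in:
            raise ValidationError(
                f"input has {x.shape[1]} features, model expects {self.d_in}"
            )
        return self.blocks.forward(x)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Raw head output: logits (classification) or a length-1 score."""
        return self.head.forward(self.gap.forward(self.forward_features(x)))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.blocks.backward(self.gap.backward(self.head.backward(dy)))

    @property
    def head_weights(self) -> np.ndarray:
        """Pre-softmax weights ``w_k^c`` of shape (filters, n_outputs)."""
        return self.head.W.value


def build_classifier(
    block: ResidualBlockConfig,
    task: str = CLASSIFICATION,
    n_classes: int = 2,
    d_in: int = 8,
    class_names: list[str] | None = None,
    seed: int = 0,
) -> ClassifierModel:
    """Seeded construction of the block + GAP + head model."""
    if task not in (CLASSIFICATION, REGRESSION):
        raise ValidationError(f"unknown task {task!r}")
    if task == CLASSIFICATION and n_classes < 2:
        raise ValidationError("classification needs at least 2 classes")
    rng = np.random.default_rng(seed)
    n_out = n_classes if task == CLASSIFICATION else 1
    stages: list[nn.Layer] = [nn.TemporalDifference()]
    c_in = 2 * d_in
    for _ in range(block.n_blocks):
        stages.append(nn.ResidualBlock(c_in, block.filters, block.kernel_size, rng,
                                       dilation=block.dilation,
                                       reduction=block.scse_reduction))
        c_in = block.filters
    model = ClassifierModel(
        blocks=nn.Sequential(stages),
        gap=nn.GlobalAveragePool(),
        head=nn.Dense(block.filters, n_out, rng),
        task=task,
        class_names=list(class_names) if class_names else [str(i) for i in range(n_out)],
        d_in=d_in,
    )
    model._block_cfg = block
    return model


def _train_single(model, train_items, val_items, class_weights, cfg, seed):
    def loss_and_grad(m, item):
        x, target = item
        out = m.forward(x)
        if m.task == CLASSIFICATION:
            return nn.weighted_ce_loss(out, target, class_weights)
        return nn.mse_loss(out, np.atleast_1d(target))

    corrupt = None
    if cfg.input_noise > 0:
        def corrupt(item, rng_):
            x, target = item
            return (x + rng_.normal(0.0, cfg.input_noise, size=x.shape), target)

    history = nn.train_sgd(
        model, train_items, val_items, loss_and_grad,
        max_epochs=cfg.max_epochs, patience=cfg.patience,
        learning_rate=cfg.learning_rate, rng=np.random.default_rng(seed),
        corrupt=corrupt,
    )
    model.trained = True
    return model, history


def train_classifier(
    model: ClassifierModel,
    train_embedded: list[EmbeddedSequence],
    train_targets: np.ndarray,
    val_embedded: list[EmbeddedSequence],
    val_targets: np.ndarray,
    class_weights: np.ndarray | None = None,
    cfg: TrainConfig | None = None,
) -> tuple[ClassifierModel, dict]:
    """Train with early stopping, restart selection and optional ensembling.

    ``train_targets`` is the one-hot label matrix (classification) or the
    vector of z-normalized scores (regression), row-aligned with the
    embedded sequences.  ``cfg.restarts`` independent initializations are
    trained; the one with the lowest validation loss becomes the lead
    model (and supplies the saliency activations), and with
    ``cfg.ensemble`` the restarts within ``ensemble_tol`` of the best
    validation loss form a committee averaged at prediction time.
    """
    cfg = cfg or TrainConfig()
    if model.task == CLASSIFICATION:
        if class_weights is None:
            raise ValidationError("class_weights are required for classification")
        class_weights = np.asarray(class_weights, dtype=float)

    train_targets = np.asarray(train_targets, dtype=float)
    val_targets = np.asarray(val_targets, dtype=float)
    train_items = list(zip([e.features for e in train_embedded], train_targets))
    val_items = list(zip([e.features for e in val_embedded], val_targets))

    block_cfg = getattr(model, "_block_cfg", None)
    # a collapsed run plateaus at chance-level validation loss; such runs
    # stop early and are cheap, so keep restarting until a sound run exists
    collapse_cut = cfg.collapse_val_loss
    if collapse_cut is None:
        collapse_cut = 0.55 if model.task == CLASSIFICATION else 0.6
    candidates: list[tuple[float, ClassifierModel, dict]] = []
    r = 0
    while True:
        if r == 0:
            m = model
        else:
            m = build_classifier(
                block_cfg or ResidualBlockConfig(), task=model.task,
                n_classes=len(model.class_names) if model.task == CLASSIFICATION else 2,
                d_in=model.d_in, class_names=model.class_names,
                seed=_restart_seed(cfg.seed, r))
        m, history = _train_single(m, train_items, val_items, class_weights,
                                   cfg, _restart_seed(cfg.seed, r) + 1)
        candidates.append((min(history["val_loss"]), m, history))
        r += 1
        best_so_far = min(v for v, _, _ in candidates)
        if r >= max(1, cfg.restarts) and best_so_far <= collapse_cut:
            break
        if r >= max(cfg.restarts, cfg.max_restarts):
            break

    candidates.sort(key=lambda c: c[0])
    best_val, best_model, best_history = candidates[0]
    if cfg.ensemble and len(candidates) > 1:
        cut = best_val * cfg.ensemble_tol if best_val > 0 else best_val
        members = [m for v, m, _ in candidates if v <= cut]
        best_model.members = members if len(members) > 1 else None
    best_history = dict(best_history)
    best_history["restart_val_losses"] = [v for v, _, _ in candidates]
    return best_model, best_history


def _restart_seed(seed: int, r: int) -> int:
    return int((seed + r * 7919) % (2 ** 31))


def predict(
    model: ClassifierModel,
    embedded: EmbeddedSequence,
    stats: NormalizationStats | None = None,
    true_class: str | None = None,
    true_score: float | None = None,
    fold_id: int | None = None,
) -> PredictionRecord:
    """Deterministic inference for one trial.

    Classification records the full probability vector, the argmax class
    (ties break to the lowest index) and its probability as confidence.
    Regression de-normalizes the head output back to the score scale when
    ``stats`` are provided.
    """
    members = model.members or [model]
    if model.task == CLASSIFICATION:
        probs = np.mean([nn.softmax(m.forward(embedded.features)) for m in members],
                        axis=0)
        pred = int(np.argmax(probs))
        return PredictionRecord(
            trial_id=embedded.trial_id,
            true_class=true_class,
            predicted_class=model.class_names[pred],
            confidence=float(probs[pred]),
            class_probabilities=probs,
            true_score=true_score,
            fold_id=fold_id,
            class_names=list(model.class_names),
        )
    raw = float(np.mean([m.forward(embedded.features)[0] for m in members]))
    score = denormalize_score(raw, stats) if stats is not None else raw
    return PredictionRecord(
        trial_id=embedded.trial_id,
        true_score=true_score,
        predicted_score=score,
        fold_id=fold_id,
    )
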