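"""Denoising-autoencoder embedding of preprocessed tool-motion sequences.

The encoder maps a normalized ``T x D`` trial to a ``T x D_e`` matrix of
salient features; the decoder reconstructs the clean input from them.
During training the input is corrupted with additive zero-mean Gaussian
noise of scale ``noise_alpha`` (re-drawn every epoch per trial) while the
reconstruction target stays clean, which pushes the embedding towards
noise-robust structure.  Inference is noise-free and deterministic.

Both encoder and decoder are built from the same attention-residual block
as the classifier, without dilation, followed by a linear 1x1 projection
to the target channel count; same-padded convolutions preserve the
temporal length, so trials of any duration embed without cropping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .sequences import SequenceDataset, ValidationError


@dataclass
class EmbeddedSequence:
    """Encoder output for one trial: a ``T x D_e`` salient-feature matrix."""

    trial_id: str
    features: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValidationError("features must be 2-D (time x features)")
        if np.any(~np.isfinite(self.features)):
            raise ValidationError("embedded features contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.features.shape[0]

    @property
    def d_e(self) -> int:
        return self.features.shape[1]


@dataclass
class DAEConfig:
    """Hyperparameters of the denoising autoencoder.

    ``noise_alpha`` is the standard deviation of the additive Gaussian
    corruption applied to (min-max normalized) inputs.  ``patience`` counts
    epochs without validation-loss improvement before stopping.
    """

    d_in: int = 4
    d_e: int = 8
    residual_filters: int = 16
    kernel_size: int = 5
    noise_alpha: float = 0.001
    max_epochs: int = 80
    patience: int = 4
    learning_rate: float = 1e-3
    seed: int = 0
    scse_reduction: int = 2

    def __post_init__(self) -> None:
        if self.d_in < 1 or self.d_e < 1 or self.residual_filters < 1:
            raise ValidationError("dimensions must be positive")
        if self.noise_alpha < 0:
            raise ValidationError("noise_alpha must be >= 0")
        if self.patience < 1:
            raise ValidationError("patience must be >= 1")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")


@dataclass
class DAEModel:
    """Encoder/decoder pair; ``encoder`` maps ``T x D -> T x D_e``."""

    encoder: nn.Sequential
    decoder: nn.Sequential
    cfg: DAEConfig
    trained: bool = False
    history: dict = field(default_factory=dict)

    def params(self) -> list[nn.Param]:
        return self.encoder.params() + self.decoder.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.decoder.forward(self.encoder.forward(x))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.encoder.backward(self.decoder.backward(dy))


def build_dae(cfg: DAEConfig) -> DAEModel:
    """Construct a seeded, untrained DAE from its configuration."""
    rng = np.random.default_rng(cfg.seed)
    encoder = nn.Sequential([
        nn.ResidualBlock(cfg.d_in, cfg.residual_filters, cfg.kernel_size, rng,
                         dilation=1, reduction=cfg.scse_reduction),
        nn.Conv1d(cfg.residual_filters, cfg.d_e, 1, rng),
    ])
    decoder = nn.Sequential([
        nn.ResidualBlock(cfg.d_e, cfg.residual_filters, cfg.kernel_size, rng,
                         dilation=1, reduction=cfg.scse_reduction),
        nn.Conv1d(cfg.residual_filters, cfg.d_in, 1, rng),
    ])
    return DAEModel(encoder=encoder, decoder=decoder, cfg=cfg)


def train_dae(
    model: DAEModel,
    train: SequenceDataset,
    val: SequenceDataset,
    cfg: DAEConfig | None = None,
) -> tuple[DAEModel, dict]:
    """Train with noisy-input / clean-target MSE reconstruction.

    Batch size is one (variable trial lengths).  Early stopping monitors
    the validation reconstruction loss and the best-epoch parameters are
    restored before returning.
    """
    cfg = cfg or model.cfg
    if val.n_trials == 0:
        raise ValidationError("validation set must be non-empty")
    for t in list(train) + list(val):
        if t.n_features != cfg.d_in:
            raise ValidationError(
                f"trial {t.trial_id} has {t.n_features} features, expected {cfg.d_in}"
            )
    train_items = [(t.coords, t.coords) for t in train]
    val_items = [(t.coords, t.coords) for t in val]
    rng = np.random.default_rng(cfg.seed)

    def corrupt(item, rng_):
        x, target = item
        if cfg.noise_alpha == 0:
            return item
        return (x + rng_.normal(0.0, cfg.noise_alpha, size=x.shape), target)

    def loss_and_grad(m, item):
        x, target = item
        recon = m.forward(x)
        loss, grad = nn.mse_loss(recon, target)
        return loss, grad

    history = nn.train_sgd(
        model, train_items, val_items, loss_and_grad,
        max_epochs=cfg.max_epochs, patience=cfg.patience,
        learning_rate=cfg.learning_rate, rng=rng, corrupt=corrupt,
    )
    model.trained = True
    model.history = history
    return model, history


def encode(model: DAEModel, ds: SequenceDataset) -> list[EmbeddedSequence]:
    """Deterministically embed every trial (no noise at inference)."""
    if not model.trained:
        raise ValidationError("encode() requires a trained model")
    out = []
    for t in ds:
        if t.n_features != model.cfg.d_in:
            raise ValidationError(
                f"trial {t.trial_id} has {t.n_features} features, "
                f"model expects {model.cfg.d_in}"
            )
        out.append(EmbeddedSequence(t.trial_id, model.encoder.forward(t.coords)))
    return out


def reconstruction_error(model: DAEModel, ds: SequenceDataset) -> float:
    """Mean squared reconstruction error over a dataset (noise-free)."""
    total = 0.0
    for t in ds:
        loss, _ = nn.mse_loss(model.forward(t.coords), t.coords)
        total += loss
    return total / ds.n_trials


def save_dae(model: DAEModel, path) -> None:
    """Single-file checkpoint: parameters + config."""
    values = nn.snapshot(model.params())
    arrays = {f"p{i}": v for i, v in enumerate(values)}
    np.savez(path, n_params=len(values), trained=int(model.trained),
             **arrays, **{f"cfg_{k}": v for k, v in asdict(model.cfg).items()})


def load_dae(path) -> DAEModel:
    with np.load(path) as data:
        cfg = DAEConfig(**{
            k[4:]: (float(data[k]) if k in ("cfg_noise_alpha", "cfg_learning_rate")
                    else int(data[k]))
            for k in data.files if k.startswith("cfg_")
        })
        model = build_dae(cfg)
        nn.restore(model.params(), [data[f"p{i}"] for i in range(int(data["n_params"]))])
        model.trained = bool(int(data["trained"]))
    return model
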