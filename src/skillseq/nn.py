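"""Minimal 1-D convolutional network primitives with manual gradients.

The assessment models are small sequence networks — a denoising
autoencoder and an attention-residual classifier — trained one trial at a
time because trials have different temporal lengths.  This module provides
exactly the layers those models need, written directly on numpy arrays of
shape ``(T, C)`` (time x channels):

* :class:`Conv1d` — stride-1, same-padded, optionally dilated convolution;
* :class:`SCSE` — concurrent spatial & channel squeeze-and-excitation,
  combined by element-wise maximum;
* :class:`ResidualBlock` — conv -> scSE -> conv with an identity shortcut,
  the sum re-calibrated by a second scSE;
* :class:`GlobalAveragePool` and :class:`Dense` heads;
* :class:`Adam` and :class:`EarlyStopper` for the training loop.

Every layer caches its forward activations and implements ``backward``
returning the input gradient while accumulating parameter gradients; the
layers are verified against central finite differences in the test suite.
All randomness flows through an explicit ``numpy.random.Generator`` so a
seed fully determines initialization and training.
"""

from __future__ import annotations

import copy

import numpy as np
from scipy.special import expit as _sigmoid


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv1d(Layer):
    """Same-padded stride-1 1-D convolution over ``(T, C_in) -> (T, C_out)``.

    ``kernel_size`` must be odd so the padding is symmetric; ``dilation``
    spreads the taps without changing the output length.  He-normal init.
    """

    def __init__(self, c_in: int, c_out: int, kernel_size: int, rng: np.random.Generator,
                 dilation: int = 1):
        if c_in < 1 or c_out < 1:
            raise ValueError("channel counts must be positive")
        if kernel_size < 1 or kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and positive")
        if dilation < 1:
            raise ValueError("dilation must be >= 1")
        self.c_in, self.c_out = c_in, c_out
        self.k, self.dilation = kernel_size, dilation
        self.pad = dilation * (kernel_size - 1) // 2
        scale = np.sqrt(2.0 / (kernel_size * c_in))
        self.W = Param(rng.normal(0.0, scale, size=(kernel_size * c_in, c_out)))
        self.b = Param(np.zeros(c_out))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        T = x.shape[0]
        xp = np.zeros((T + 2 * self.pad, self.c_in))
        xp[self.pad:self.pad + T] = x
        self._xp = xp
        self._T = T
        W = self.W.value.reshape(self.k, self.c_in, self.c_out)
        y = np.tile(self.b.value, (T, 1))
        for i in range(self.k):
            start = i * self.dilation
            y += xp[start:start + T] @ W[i]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        T, xp = self._T, self._xp
        W = self.W.value.reshape(self.k, self.c_in, self.c_out)
        dW = self.W.grad.reshape(self.k, self.c_in, self.c_out)
        self.b.grad += dy.sum(axis=0)
        dxp = np.zeros_like(xp)
        for i in range(self.k):
            start = i * self.dilation
            dW[i] += xp[start:start + T].T @ dy
            dxp[start:start + T] += dy @ W[i].T
        return dxp[self.pad:self.pad + T]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class SCSE(Layer):
    """Concurrent spatial and channel squeeze-and-excitation.

    Channel branch: global temporal average -> bottleneck (ratio
    ``reduction``) -> sigmoid channel gates.  Spatial branch: 1x1
    convolution to a sigmoid per-timestep gate.  The two recalibrated maps
    are combined element-wise by maximum, highlighting whichever branch
    considers each activation more salient.
    """

    def __init__(self, channels: int, rng: np.random.Generator, reduction: int = 2):
        if channels < 1:
            raise ValueError("channels must be positive")
        hidden = max(1, channels // max(1, reduction))
        s1 = np.sqrt(2.0 / channels)
        s2 = np.sqrt(1.0 / hidden)
        self.W1 = Param(rng.normal(0.0, s1, size=(channels, hidden)))
        self.b1 = Param(np.zeros(hidden))
        self.W2 = Param(rng.normal(0.0, s2, size=(hidden, channels)))
        self.b2 = Param(np.zeros(channels))
        self.Wsp = Param(rng.normal(0.0, np.sqrt(1.0 / channels), size=(channels, 1)))
        self.bsp = Param(np.zeros(1))

    def params(self) -> list[Param]:
        return [self.W1, self.b1, self.W2, self.b2, self.Wsp, self.bsp]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        T = x.shape[0]
        # channel excitation
        z = x.mean(axis=0)
        self._h_pre = z @ self.W1.value + self.b1.value
        self._h = np.maximum(self._h_pre, 0.0)
        self._s = _sigmoid(self._h @ self.W2.value + self.b2.value)
        cse = x * self._s
        # spatial excitation
        self._q = _sigmoid(x @ self.Wsp.value + self.bsp.value)  # (T, 1)
        sse = x * self._q
        self._use_c = cse >= sse  # ties go to the channel branch
        self._T = T
        return np.where(self._use_c, cse, sse)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, s, q = self._x, self._s, self._q
        dcse = dy * self._use_c
        dsse = dy - dcse
        dx = dcse * s + dsse * q
        # channel branch
        ds = (dcse * x).sum(axis=0)
        dpre2 = ds * s * (1.0 - s)
        self.W2.grad += np.outer(self._h, dpre2)
        self.b2.grad += dpre2
        dh = dpre2 @ self.W2.value.T
        dpre1 = np.where(self._h_pre > 0, dh, 0.0)
        z = x.mean(axis=0)
        self.W1.grad += np.outer(z, dpre1)
        self.b1.grad += dpre1
        dz = dpre1 @ self.W1.value.T
        dx += dz[None, :] / self._T
        # spatial branch
        dq = (dsse * x).sum(axis=1, keepdims=True)
        dpre_sp = dq * q * (1.0 - q)
        self.Wsp.grad += x.T @ dpre_sp
        self.bsp.grad += dpre_sp.sum(axis=0)
        dx += dpre_sp @ self.Wsp.value.T
        return dx


class ResidualBlock(Layer):
    """Attention-residual block: conv -> scSE -> conv (+ shortcut) -> scSE.

    Two identical same-padded convolutions with a ReLU after the first; an
    scSE recalibration between them and a second scSE after the shortcut
    addition.  The shortcut is the identity when channel counts match and a
    1x1 projection otherwise.  With all convolution weights zeroed the block
    degenerates to an scSE-gated identity, so gradients always have a short
    path through it.
    """

    def __init__(self, c_in: int, filters: int, kernel_size: int,
                 rng: np.random.Generator, dilation: int = 1, reduction: int = 2):
        if filters < 1:
            raise ValueError("filters must be >= 1")
        if dilation < 1:
            raise ValueError("dilation must be >= 1")
        self.conv1 = Conv1d(c_in, filters, kernel_size, rng, dilation)
        self.relu1 = ReLU()
        self.scse1 = SCSE(filters, rng, reduction)
        self.conv2 = Conv1d(filters, filters, kernel_size, rng, dilation)
        self.proj = Conv1d(c_in, filters, 1, rng) if c_in != filters else None
        self.scse2 = SCSE(filters, rng, reduction)

    def params(self) -> list[Param]:
        out = self.conv1.params() + self.scse1.params() + self.conv2.params()
        if self.proj is not None:
            out += self.proj.params()
        return out + self.scse2.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.conv2.forward(self.scse1.forward(self.relu1.forward(self.conv1.forward(x))))
        shortcut = x if self.proj is None else self.proj.forward(x)
        return self.scse2.forward(h + shortcut)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dsum = self.scse2.backward(dy)
        dx = dsum if self.proj is None else self.proj.backward(dsum)
        dh = self.conv1.backward(
            self.relu1.backward(self.scse1.backward(self.conv2.backward(dsum)))
        )
        return dx + dh


class TemporalDifference(Layer):
    """Fixed (non-trainable) position + velocity view: ``(T, C) -> (T, 2C)``.

    Output channels are the input followed by its first temporal
    difference (zero-padded at the first frame).  Motion dynamics carry
    most of the skill signal but have far smaller amplitude than absolute
    positions; exposing them as explicit channels is the standard
    kinematic inductive bias and removes a slow-to-learn differencing
    stage from the convolutions.
    """

    def forward(self, x: np.ndarray) -> np.ndarray:
        T, C = x.shape
        out = np.empty((T, 2 * C))
        out[:, :C] = x
        out[0, C:] = 0.0
        out[1:, C:] = x[1:] - x[:-1]
        self._C = C
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        C = self._C
        dx = dy[:, :C].copy()
        dd = dy[:, C:]
        dx[1:] += dd[1:]
        dx[:-1] -= dd[1:]
        return dx


class GlobalAveragePool(Layer):
    """Temporal mean, ``(T, C) -> (C,)``; makes the model length-agnostic."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._T = x.shape[0]
        return x.mean(axis=0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.broadcast_to(dy / self._T, (self._T, dy.shape[0]))


class Dense(Layer):
    """Affine map on a vector, ``(C_in,) -> (C_out,)``."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.W = Param(rng.normal(0.0, np.sqrt(1.0 / c_in), size=(c_in, c_out)))
        self.b = Param(np.zeros(c_out))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += np.outer(self._x, dy)
        self.b.grad += dy
        return dy @ self.W.value.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    e = np.exp(logits - logits.max())
    return e / e.sum()


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all elements; returns (loss, dL/dpred)."""
    diff = pred - target
    return float(np.mean(diff ** 2)), 2.0 * diff / diff.size


def weighted_ce_loss(
    logits: np.ndarray, onehot: np.ndarray, class_weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Class-weighted cross-entropy on a single sample; grad w.r.t. logits."""
    p = softmax(logits)
    c = int(np.argmax(onehot))
    w = float(class_weights[c])
    loss = -w * float(np.log(max(p[c], 1e-12)))
    return loss, w * (p - onehot)


# ---------------------------------------------------------------------------
# Optimization and early stopping
# ---------------------------------------------------------------------------

class Adam:
    """Adam over a consolidated parameter vector.

    On construction the parameters are repacked into one contiguous buffer
    (their ``value``/``grad`` arrays become views into it), so each update
    is a handful of vectorized operations regardless of layer count —
    batch-size-1 training takes one optimizer step per trial, which makes
    per-step overhead the dominant cost.
    """

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        sizes = [p.value.size for p in params]
        total = int(np.sum(sizes))
        self.flat_value = np.empty(total)
        self.flat_grad = np.zeros(total)
        offset = 0
        for p, size in zip(params, sizes):
            shape = p.value.shape
            self.flat_value[offset:offset + size] = p.value.ravel()
            p.value = self.flat_value[offset:offset + size].reshape(shape)
            p.grad = self.flat_grad[offset:offset + size].reshape(shape)
            offset += size
        self.m = np.zeros(total)
        self.v = np.zeros(total)
        self.t = 0

    def zero_grad(self) -> None:
        self.flat_grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1.0 - self.b2 ** self.t) / (1.0 - self.b1 ** self.t)
        g = self.flat_grad
        self.m *= self.b1
        self.m += (1.0 - self.b1) * g
        self.v *= self.b2
        self.v += (1.0 - self.b2) * g ** 2
        self.flat_value -= lr_t * self.m / (np.sqrt(self.v) + self.eps)


class EarlyStopper:
    """Stop when validation loss has not strictly improved for ``patience`` epochs.

    Tracks the best epoch's parameter snapshot so training can restore it.
    """

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best = np.inf
        self.best_epoch = -1
        self.wait = 0

    def update(self, val_loss: float, epoch: int) -> bool:
        """Record an epoch's validation loss; return True to stop."""
        if val_loss < self.best:
            self.best = val_loss
            self.best_epoch = epoch
            self.wait = 0
            return False
        self.wait += 1
        return self.wait >= self.patience


def snapshot(params: list[Param]) -> list[np.ndarray]:
    return [p.value.copy() for p in params]


def restore(params: list[Param], saved: list[np.ndarray]) -> None:
    for p, s in zip(params, saved):
        p.value[...] = s


def train_sgd(
    model: Layer,
    train_items: list,
    val_items: list,
    loss_and_grad,
    *,
    max_epochs: int,
    patience: int,
    learning_rate: float,
    rng: np.random.Generator,
    corrupt=None,
) -> dict:
    """Generic batch-size-1 training loop with early stopping.

    ``loss_and_grad(model, item) -> (loss, upstream_grad_or_None)`` runs
    the forward pass and returns the gradient at the model output (None
    skips the backward/step, used for validation).  ``corrupt(item, rng)``
    optionally perturbs a training item (e.g. additive input noise),
    re-drawn every epoch.  Restores the best-validation parameters before
    returning the history.
    """
    if not val_items:
        raise ValueError("validation set must be non-empty")
    params = model.params()
    opt = Adam(params, lr=learning_rate)
    stopper = EarlyStopper(patience)
    history = {"train_loss": [], "val_loss": []}
    best_params = snapshot(params)

    def val_loss() -> float:
        total = 0.0
        for item in val_items:
            loss, _ = loss_and_grad(model, item)
            total += loss
        return total / len(val_items)

    for epoch in range(max_epochs):
        order = rng.permutation(len(train_items))
        total = 0.0
        for i in order:
            item = train_items[i]
            if corrupt is not None:
                item = corrupt(item, rng)
            loss, grad = loss_and_grad(model, item)
            total += loss
            if grad is not None:
                opt.zero_grad()
                model.backward(grad)
                opt.step()
        history["train_loss"].append(total / len(train_items))
        v = val_loss()
        history["val_loss"].append(v)
        improved = v < stopper.best
        stop = stopper.update(v, epoch)
        if improved:
            best_params = snapshot(params)
        if stop:
            break
    restore(params, best_params)
    history["best_epoch"] = stopper.best_epoch
    return history


def clone_params(model: Layer) -> list[np.ndarray]:
    """Deep copy of a model's parameter values (for reproducibility checks)."""
    return copy.deepcopy(snapshot(model.params()))
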