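"""1D convolutional classifier for fixed-length multichannel inputs.

Architecture (fixed layer sequence, sizes configurable via :class:`CNNConfig`)::

    conv(128,5,1) -> batchnorm -> relu -> maxpool(3)
    -> conv(128,5,1) -> batchnorm -> relu
    -> conv(128,5,1) -> batchnorm -> relu
    -> global average pooling -> dropout(0.4) -> dense(n_classes) -> softmax

trained with Adam on categorical cross-entropy.

No deep-learning framework is assumed: layers, backpropagation and the
optimizer are implemented on NumPy (float32, im2col-based convolutions), which
keeps training fully deterministic for a given seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.model_selection import train_test_split

__all__ = [
    "CNNConfig",
    "SplitSpec",
    "CNN1D",
    "build_model",
    "split_dataset",
    "train",
    "predict",
    "cross_entropy",
    "save_model",
    "load_model",
]

_EPS = 1e-7


@dataclass(frozen=True)
class CNNConfig:
    """Architecture and training hyperparameters."""

    n_filters: int = 128
    kernel_size: int = 5
    conv_stride: int = 1
    n_conv_blocks: int = 3
    maxpool_size: int = 3  # applied after block 1 only
    dropout_rate: float = 0.4
    n_classes: int = 16
    input_len: int = 3000
    n_channels: int = 7
    batch_size: int = 32
    epochs: int = 100
    learning_rate: float = 2e-4
    early_stopping_patience: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")


@dataclass(frozen=True)
class SplitSpec:
    """Two-stage split: 9:1 test hold-out, then 8:2 train/validation on the
    remainder, i.e. 72% / 18% / 10% of the whole; shuffled and class-stratified."""

    test_fraction: float = 0.1
    validation_fraction: float = 0.2  # of the non-test remainder
    shuffle: bool = True
    seed: int = 0


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class _Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


class _Conv1D:
    """Same-padded 1D convolution over (batch, length, channels)."""

    def __init__(self, in_ch: int, filters: int, kernel: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (in_ch * kernel))
        self.w = _Param(rng.normal(0.0, scale, size=(in_ch * kernel, filters)))
        self.b = _Param(np.zeros(filters))
        self.kernel = kernel
        self.in_ch = in_ch
        self.params = [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        k = self.kernel
        pad_l = (k - 1) // 2
        pad_r = k - 1 - pad_l
        xp = np.pad(x, ((0, 0), (pad_l, pad_r), (0, 0)))
        cols = sliding_window_view(xp, k, axis=1)  # (B, L, C, K)
        b, l = cols.shape[:2]
        self._cols = np.ascontiguousarray(cols).reshape(b * l, self.in_ch * k)
        self._shape = (b, l, pad_l, pad_r)
        out = self._cols @ self.w.value + self.b.value
        return out.reshape(b, l, -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, l, pad_l, pad_r = self._shape
        g = grad.reshape(b * l, -1).astype(np.float32)
        self.w.grad += self._cols.T @ g
        self.b.grad += g.sum(axis=0)
        gcols = (g @ self.w.value.T).reshape(b, l, self.in_ch, self.kernel)
        gx = np.zeros((b, l + self.kernel - 1, self.in_ch), dtype=np.float32)
        for k in range(self.kernel):
            gx[:, k : k + l, :] += gcols[:, :, :, k]
        return gx[:, pad_l : gx.shape[1] - pad_r, :]


class _BatchNorm:
    def __init__(self, n_features: int, momentum: float = 0.9):
        self.gamma = _Param(np.ones(n_features))
        self.beta = _Param(np.zeros(n_features))
        self.running_mean = np.zeros(n_features, dtype=np.float32)
        self.running_var = np.ones(n_features, dtype=np.float32)
        self.momentum = momentum
        self.params = [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + _EPS).astype(np.float32)
        self._xhat = (x - mean) / self._std
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n = grad.shape[0] * grad.shape[1]
        self.gamma.grad += (grad * self._xhat).sum(axis=(0, 1))
        self.beta.grad += grad.sum(axis=(0, 1))
        gxhat = grad * self.gamma.value
        return (
            gxhat - gxhat.mean(axis=(0, 1)) - self._xhat * (gxhat * self._xhat).mean(axis=(0, 1))
        ) / self._std


class _ReLU:
    params: list = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class _MaxPool:
    params: list = []

    def __init__(self, size: int):
        self.size = size

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, l, c = x.shape
        lp = (l // self.size) * self.size
        self._in_len = l
        xr = x[:, :lp, :].reshape(b, lp // self.size, self.size, c)
        out = xr.max(axis=2)
        self._mask = xr == out[:, :, None, :]
        # break ties: keep only the first maximal element per pool
        first = np.cumsum(self._mask, axis=2) == 1
        self._mask &= first
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, lo, c = grad.shape
        gx = np.zeros((b, self._in_len, c), dtype=np.float32)
        gr = self._mask * grad[:, :, None, :]
        gx[:, : lo * self.size, :] = gr.reshape(b, lo * self.size, c)
        return gx


class _GlobalAvgPool:
    params: list = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._len = x.shape[1]
        return x.mean(axis=1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.repeat(grad[:, None, :], self._len, axis=1) / np.float32(self._len)


class _Dropout:
    params: list = []

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / np.float32(keep)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class _Dense:
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / in_dim)
        self.w = _Param(rng.normal(0.0, scale, size=(in_dim, out_dim)))
        self.b = _Param(np.zeros(out_dim))
        self.params = [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Per-sample categorical cross-entropy ``-sum_i t_i log p_i``.

    *targets* may be one-hot rows or integer class labels.
    """
    probs = np.asarray(probs, dtype=np.float64)
    targets = np.asarray(targets)
    p = np.clip(probs, _EPS, 1.0)
    if targets.ndim == 1:
        return -np.log(p[np.arange(len(p)), targets.astype(int)])
    return -(targets * np.log(p)).sum(axis=-1)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class CNN1D:
    """The fixed-architecture network; see module docstring."""

    def __init__(self, config: CNNConfig):
        if config.input_len < config.kernel_size * config.maxpool_size:
            raise ValueError(
                f"input_len {config.input_len} too short for the receptive field "
                f"(need >= {config.kernel_size * config.maxpool_size})"
            )
        self.config = config
        rng = np.random.default_rng(config.seed)
        f, k = config.n_filters, config.kernel_size
        layers: list = []
        in_ch = config.n_channels
        for block in range(config.n_conv_blocks):
            layers.append(_Conv1D(in_ch, f, k, rng))
            layers.append(_BatchNorm(f))
            layers.append(_ReLU())
            if block == 0:
                layers.append(_MaxPool(config.maxpool_size))
            in_ch = f
        layers.append(_GlobalAvgPool())
        layers.append(_Dropout(config.dropout_rate, rng))
        layers.append(_Dense(f, config.n_classes, rng))
        self.layers = layers
        self.params: list[_Param] = [p for lay in layers for p in lay.params]
        self._adam_t = 0

    # -- forward / backward ------------------------------------------------

    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.asarray(x, dtype=np.float32)
        for lay in self.layers:
            out = lay.forward(out, training)
        return out

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 3 or x.shape[1] != self.config.input_len or x.shape[2] != self.config.n_channels:
            raise ValueError(
                f"expected inputs of shape (n, {self.config.input_len}, "
                f"{self.config.n_channels}), got {x.shape}"
            )
        chunks = [
            _softmax(self.forward_logits(x[i : i + batch_size], training=False))
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(chunks, axis=0)

    def _train_step(self, xb: np.ndarray, yb: np.ndarray, lr: float) -> float:
        logits = self.forward_logits(xb, training=True)
        probs = _softmax(logits)
        n = len(xb)
        loss = float(cross_entropy(probs, yb).mean())
        grad = probs.astype(np.float32)
        grad[np.arange(n), yb] -= 1.0
        grad /= np.float32(n)
        for p in self.params:
            p.grad[...] = 0.0
        for lay in reversed(self.layers):
            grad = lay.backward(grad)
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = self._adam_t
        for p in self.params:
            p.m = b1 * p.m + (1 - b1) * p.grad
            p.v = b2 * p.v + (1 - b2) * p.grad**2
            mhat = p.m / (1 - b1**t)
            vhat = p.v / (1 - b2**t)
            p.value -= lr * mhat / (np.sqrt(vhat) + eps)
        return loss

    # -- introspection / persistence --------------------------------------

    @property
    def n_parameters(self) -> int:
        """Number of trainable scalars (conv/dense weights+biases, BN gamma/beta)."""
        return int(sum(p.value.size for p in self.params))

    def state_dict(self) -> dict:
        state = {}
        for i, lay in enumerate(self.layers):
            for j, p in enumerate(lay.params):
                state[f"layer{i}_param{j}"] = p.value
            if isinstance(lay, _BatchNorm):
                state[f"layer{i}_running_mean"] = lay.running_mean
                state[f"layer{i}_running_var"] = lay.running_var
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, lay in enumerate(self.layers):
            for j, p in enumerate(lay.params):
                p.value = np.array(state[f"layer{i}_param{j}"], dtype=np.float32)
            if isinstance(lay, _BatchNorm):
                lay.running_mean = np.array(state[f"layer{i}_running_mean"], dtype=np.float32)
                lay.running_var = np.array(state[f"layer{i}_running_var"], dtype=np.float32)


def build_model(config: CNNConfig) -> CNN1D:
    """Construct the (untrained) network for *config*."""
    return CNN1D(config)


# ---------------------------------------------------------------------------
# splitting, training, prediction
# ---------------------------------------------------------------------------

def split_dataset(
    y: Sequence[int], spec: Optional[SplitSpec] = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (train, validation, test) index arrays over ``range(len(y))``.

    Stratified by class where every class allows it; falls back to a plain
    shuffled split when some class is too small to stratify.
    """
    if spec is None:
        spec = SplitSpec()
    y = np.asarray(y)
    n = len(y)
    if n < 10:
        raise ValueError(f"dataset of size {n} too small to split (need >= 10)")
    idx = np.arange(n)

    def _split(indices, fraction, seed_offset):
        labels = y[indices]
        try:
            keep, held = train_test_split(
                indices,
                test_size=fraction,
                shuffle=spec.shuffle,
                stratify=labels if spec.shuffle else None,
                random_state=spec.seed + seed_offset,
            )
        except ValueError:  # class with < 2 members: cannot stratify
            keep, held = train_test_split(
                indices,
                test_size=fraction,
                shuffle=spec.shuffle,
                random_state=spec.seed + seed_offset,
            )
        return keep, held

    rest, test = _split(idx, spec.test_fraction, 0)
    train_idx, val = _split(rest, spec.validation_fraction, 1)
    return np.sort(train_idx), np.sort(val), np.sort(test)


def train(
    model: CNN1D,
    train_data: tuple[np.ndarray, np.ndarray],
    validation_data: tuple[np.ndarray, np.ndarray],
    config: Optional[CNNConfig] = None,
) -> dict:
    """Train *model* in place; returns the per-epoch history dict with keys
    ``train_loss``, ``train_acc``, ``val_loss``, ``val_acc``.

    Minimizes categorical cross-entropy with Adam.  Raises on empty sets and
    aborts with a diagnostic if the loss becomes non-finite.  Optional early
    stopping (patience on validation loss) restores the best weights.
    """
    if config is None:
        config = model.config
    x_tr, y_tr = train_data
    x_va, y_va = validation_data
    if len(x_tr) == 0 or len(x_va) == 0:
        raise ValueError("training and validation sets must be non-empty")
    x_tr = np.asarray(x_tr, dtype=np.float32)
    y_tr = np.asarray(y_tr, dtype=np.int64)
    rng = np.random.default_rng(config.seed + 1)
    history: dict[str, list[float]] = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    best_val = np.inf
    best_state = None
    bad_epochs = 0

    for epoch in range(config.epochs):
        order = rng.permutation(len(x_tr))
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            loss = model._train_step(x_tr[batch], y_tr[batch], config.learning_rate)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch}, batch {start // config.batch_size}")
            losses.append(loss)

        tr_probs = model.predict_proba(x_tr)
        va_probs = model.predict_proba(x_va)
        history["train_loss"].append(float(cross_entropy(tr_probs, y_tr).mean()))
        history["train_acc"].append(float((tr_probs.argmax(axis=1) == y_tr).mean()))
        val_loss = float(cross_entropy(va_probs, np.asarray(y_va)).mean())
        history["val_loss"].append(val_loss)
        history["val_acc"].append(float((va_probs.argmax(axis=1) == np.asarray(y_va)).mean()))

        if config.early_stopping_patience is not None:
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_state = {k: v.copy() for k, v in model.state_dict().items()}
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs > config.early_stopping_patience:
                    break
    if best_state is not None:
        model.load_state_dict(best_state)
    return history


def predict(model: CNN1D, inputs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and argmax labels (ties -> lowest class code)."""
    probs = model.predict_proba(inputs)
    return probs, probs.argmax(axis=1)


def save_model(model: CNN1D, path: Union[str, Path]) -> None:
    """Save weights (npz) plus a plain-text hyperparameter sidecar (json)."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.state_dict())
    path.with_suffix(".json").write_text(json.dumps(asdict(model.config), indent=2))


def load_model(path: Union[str, Path]) -> CNN1D:
    path = Path(path)
    config = CNNConfig(**json.loads(path.with_suffix(".json").read_text()))
    model = CNN1D(config)
    with np.load(path.with_suffix(".npz")) as state:
        model.load_state_dict(dict(state))
    return model
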