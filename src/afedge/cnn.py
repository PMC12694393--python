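"""A compact 1D convolutional network for RR-sequence rhythm classification.

The architecture is two convolution blocks (Conv1D -> BatchNorm -> ReLU ->
AveragePooling -> Dropout) followed by a dense head (Flatten -> Dense(64) ->
ReLU -> Dropout -> Dense(2) -> Softmax), sized for microcontroller
deployment: with valid padding the N = 25 variant has 10,210 parameters.
Inputs are raw RR intervals in seconds with a single feature channel; no
normalization is applied (the first BatchNorm layer adapts the scale).

Everything — forward pass, backpropagation, Adam, early stopping with
best-weight restoration — is implemented on NumPy arrays so that inference
is bit-reproducible and the INT8 conversion in :mod:`afedge.quantize` can
operate directly on the layer graph.
"""

from __future__ import annotations

import copy
import json
import struct
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

_EPS_PROB = 1e-7  # probability clip for cross-entropy
_MAGIC = b"AFEDGE1\n"


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``n`` is the RR-window length; the remaining defaults define the
    deployed network: 16 then 32 conv filters of kernel 3, average pooling
    of 2, dropout 0.25 / 0.1, a 64-unit dense layer and a 2-class softmax.
    """

    n: int = 25
    channels: int = 1
    block1_filters: int = 16
    block2_filters: int = 32
    kernel: int = 3
    pool: int = 2
    dropout1: float = 0.25
    dropout2: float = 0.1
    dense_units: int = 64
    n_classes: int = 2
    padding: str = "valid"  # or "same"

    def conv_out(self, length: int) -> int:
        if self.padding == "same":
            return length
        return length - self.kernel + 1

    def layer_lengths(self) -> tuple[int, int, int, int, int]:
        """Sequence lengths after each conv/pool stage (input first)."""
        l0 = self.n
        l1 = self.conv_out(l0)
        l2 = l1 // self.pool
        l3 = self.conv_out(l2)
        l4 = l3 // self.pool
        return l0, l1, l2, l3, l4

    @property
    def flat_features(self) -> int:
        return self.layer_lengths()[-1] * self.block2_filters


@dataclass(frozen=True)
class TrainConfig:
    """Optimization recipe: Adam(0.0009, 0.9, 0.999), categorical
    cross-entropy, batch 32, at most 100 epochs, early stopping on
    validation loss with patience 5 and best-weight restoration."""

    learning_rate: float = 0.0009
    beta1: float = 0.9
    beta2: float = 0.999
    max_epochs: int = 100
    batch_size: int = 32
    early_stop_patience: int = 5
    restore_best: bool = True
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


class Layer:
    """Base layer: trainable ``params``/``grads`` plus optional state."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def state_arrays(self) -> list[np.ndarray]:
        """Non-trainable arrays that must survive serialization (BN stats)."""
        return []

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator | None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    def __init__(self, c_in: int, filters: int, kernel: int, padding: str, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (kernel * c_in + kernel * filters))
        self.w = rng.uniform(-limit, limit, size=(kernel, c_in, filters))
        self.b = np.zeros(filters)
        self.padding = padding
        self.kernel = kernel
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def _pad(self, x):
        if self.padding == "same":
            left = (self.kernel - 1) // 2
            right = self.kernel - 1 - left
            return np.pad(x, ((0, 0), (left, right), (0, 0)))
        return x

    def forward(self, x, training, rng):
        xp = self._pad(x)
        # (B, L_out, C, k) view of all kernel-sized patches
        self._patches = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=1)
        self._in_shape = x.shape
        return np.einsum("blck,kcf->blf", self._patches, self.w) + self.b

    def backward(self, dout):
        self.dw[...] = np.einsum("blck,blf->kcf", self._patches, dout)
        self.db[...] = dout.sum(axis=(0, 1))
        b, l_in, c = self._in_shape
        pad_left = (self.kernel - 1) // 2 if self.padding == "same" else 0
        l_pad = l_in + (self.kernel - 1 if self.padding == "same" else 0)
        dx = np.zeros((b, l_pad, c))
        l_out = dout.shape[1]
        for i in range(self.kernel):
            dx[:, i : i + l_out, :] += np.einsum("blf,cf->blc", dout, self.w[i])
        return dx[:, pad_left : pad_left + l_in, :]


class BatchNorm(Layer):
    """Per-channel batch normalization (channels-last).

    Moving statistics use momentum 0.9 so they converge within a couple of
    epochs at the few dozen update steps per epoch these datasets produce;
    a slower decay would leave inference statistics stale at the point
    where early stopping evaluates validation loss.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-3):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.moving_mean = np.zeros(channels)
        self.moving_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def state_arrays(self):
        return [self.moving_mean, self.moving_var]

    def forward(self, x, training, rng):
        axes = tuple(range(x.ndim - 1))
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.moving_mean[...] = self.momentum * self.moving_mean + (1 - self.momentum) * mu
            self.moving_var[...] = self.momentum * self.moving_var + (1 - self.momentum) * var
            self._axes = axes
            self._m = x.size // x.shape[-1]
            self._xc = x - mu
            self._inv_std = 1.0 / np.sqrt(var + self.eps)
            self._xhat = self._xc * self._inv_std
            return self.gamma * self._xhat + self.beta
        xhat = (x - self.moving_mean) / np.sqrt(self.moving_var + self.eps)
        return self.gamma * xhat + self.beta

    def backward(self, dout):
        axes, m = self._axes, self._m
        self.dgamma[...] = (dout * self._xhat).sum(axis=axes)
        self.dbeta[...] = dout.sum(axis=axes)
        dxhat = dout * self.gamma
        dvar = (dxhat * self._xc).sum(axis=axes) * (-0.5) * self._inv_std**3
        dmu = -(dxhat.sum(axis=axes)) * self._inv_std - 2.0 * dvar * self._xc.mean(axis=axes)
        return dxhat * self._inv_std + 2.0 * dvar * self._xc / m + dmu / m


class ReLU(Layer):
    def forward(self, x, training, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class AvgPool1D(Layer):
    def __init__(self, pool: int = 2):
        self.pool = pool

    def forward(self, x, training, rng):
        b, l, c = x.shape
        l_out = l // self.pool
        self._in_len = l
        return x[:, : l_out * self.pool, :].reshape(b, l_out, self.pool, c).mean(axis=2)

    def backward(self, dout):
        b, l_out, c = dout.shape
        dx = np.zeros((b, self._in_len, c))
        expanded = np.repeat(dout / self.pool, self.pool, axis=1)
        dx[:, : l_out * self.pool, :] = expanded
        return dx


class Dropout(Layer):
    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, x, training, rng):
        if not training or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.w = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x, training, rng):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.dw[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.w.T


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


class CNN1D:
    """The layer graph; softmax is applied on top of the final dense logits."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        lengths = config.layer_lengths()
        if min(lengths) < 1 or config.flat_features < 1:
            raise ValueError(
                f"input length {config.n} too small for two conv+pool stages "
                f"(layer lengths {lengths})"
            )
        if config.padding not in ("valid", "same"):
            raise ValueError(f"unknown padding mode {config.padding!r}")
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        self.layers: list[Layer] = [
            Conv1D(c.channels, c.block1_filters, c.kernel, c.padding, rng),
            BatchNorm(c.block1_filters),
            ReLU(),
            AvgPool1D(c.pool),
            Dropout(c.dropout1),
            Conv1D(c.block1_filters, c.block2_filters, c.kernel, c.padding, rng),
            BatchNorm(c.block2_filters),
            ReLU(),
            AvgPool1D(c.pool),
            Flatten(),
            Dense(c.flat_features, c.dense_units, rng),
            ReLU(),
            Dropout(c.dropout2),
            Dense(c.dense_units, c.n_classes, rng),
        ]

    # -- forward / backward --------------------------------------------------

    def _as_input(self, windows: np.ndarray) -> np.ndarray:
        x = np.asarray(windows, dtype=float)
        if x.ndim == 2:
            x = x[:, :, None]
        if x.shape[1] != self.config.n or x.shape[2] != self.config.channels:
            raise ValueError(
                f"expected windows of shape (*, {self.config.n}, {self.config.channels}), "
                f"got {x.shape}"
            )
        return x

    def forward_logits(self, x: np.ndarray, training: bool = False,
                       rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def predict_proba(self, windows: np.ndarray) -> np.ndarray:
        """Class probabilities (rows sum to 1) in inference mode."""
        x = self._as_input(windows)
        return _softmax(self.forward_logits(x, training=False))

    def predict(self, windows: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(windows), axis=1)

    def backward_from_probs(self, probs: np.ndarray, onehot: np.ndarray) -> None:
        dout = (probs - onehot) / probs.shape[0]
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    # -- weights -------------------------------------------------------------

    def all_arrays(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend(layer.params())
            out.extend(layer.state_arrays())
        return out

    def get_weights(self) -> list[np.ndarray]:
        return [a.copy() for a in self.all_arrays()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        arrays = self.all_arrays()
        if len(arrays) != len(weights):
            raise ValueError("weight list does not match the architecture")
        for dst, src in zip(arrays, weights):
            dst[...] = np.asarray(src, dtype=dst.dtype).reshape(dst.shape)


@dataclass
class TrainedModel:
    """A trained network plus its configs and per-epoch history."""

    model: CNN1D
    model_config: ModelConfig
    train_config: TrainConfig
    history: dict[str, list[float]] = field(default_factory=dict)
    stopped_epoch: int = 0

    def predict_proba(self, windows: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(windows)

    def predict(self, windows: np.ndarray) -> np.ndarray:
        return self.model.predict(windows)


def build_model(cfg: ModelConfig, seed: int = 0) -> CNN1D:
    """Instantiate the network with seeded Glorot-uniform initialization."""
    return CNN1D(cfg, seed=seed)


def count_parameters(model: CNN1D) -> int:
    """Total parameter count, trainable plus BatchNorm moving statistics."""
    return int(sum(a.size for a in model.all_arrays()))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def split_train_val(
    x: np.ndarray,
    y: np.ndarray,
    val_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Seeded, label-stratified train/validation split.

    Every class contributes ``round(val_fraction * n_class)`` samples
    (at least one, leaving at least one for training) to the validation
    side, so balanced input stays balanced on both sides.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present for a stratified split")
    rng = np.random.default_rng(seed)
    val_idx = []
    for cls in classes:
        idx = np.flatnonzero(y == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls} has fewer than 2 samples")
        n_val = int(round(val_fraction * len(idx)))
        n_val = min(max(n_val, 1), len(idx) - 1)
        val_idx.append(rng.permutation(idx)[:n_val])
    val_idx = np.sort(np.concatenate(val_idx))
    mask = np.zeros(len(y), dtype=bool)
    mask[val_idx] = True
    x = np.asarray(x)
    return x[~mask], y[~mask], x[mask], y[mask]


def _one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(y), n_classes))
    out[np.arange(len(y)), y] = 1.0
    return out


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    """Mean categorical cross-entropy with probability clipping."""
    p = np.clip(probs[np.arange(len(y)), y], _EPS_PROB, 1.0)
    return float(-np.mean(np.log(p)))


class _Adam:
    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray], tc: TrainConfig):
        self.params = params
        self.grads = grads
        self.lr, self.b1, self.b2 = tc.learning_rate, tc.beta1, tc.beta2
        self.eps = 1e-7
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def train(
    model: CNN1D,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    tc: TrainConfig | None = None,
) -> TrainedModel:
    """Fit the network with Adam and early stopping on validation loss.

    ``train_set``/``val_set`` are ``(windows, integer_labels)`` pairs.  The
    best-validation-loss weights are restored at the end (when enabled) and
    the per-epoch history (loss/accuracy for both sets) is recorded.
    """
    tc = tc or TrainConfig()
    x_tr, y_tr = train_set
    x_va, y_va = val_set
    if len(x_tr) == 0 or len(x_va) == 0:
        raise ValueError("training and validation sets must be non-empty")
    x_tr = model._as_input(x_tr)
    x_va = model._as_input(x_va)
    y_tr = np.asarray(y_tr, dtype=int)
    y_va = np.asarray(y_va, dtype=int)
    n_classes = model.config.n_classes
    onehot_tr = _one_hot(y_tr, n_classes)

    rng = np.random.default_rng(tc.seed)
    params, grads = [], []
    for layer in model.layers:
        params.extend(layer.params())
        grads.extend(layer.grads())
    opt = _Adam(params, grads, tc)

    history: dict[str, list[float]] = {
        "loss": [], "accuracy": [], "val_loss": [], "val_accuracy": []
    }
    best_loss = np.inf
    best_weights: list[np.ndarray] | None = None
    wait = 0
    stopped_epoch = 0

    for epoch in range(1, tc.max_epochs + 1):
        perm = rng.permutation(len(x_tr))
        batch_losses, batch_accs = [], []
        for start in range(0, len(perm), tc.batch_size):
            idx = perm[start : start + tc.batch_size]
            logits = model.forward_logits(x_tr[idx], training=True, rng=rng)
            probs = _softmax(logits)
            loss = cross_entropy(probs, y_tr[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch} "
                    f"(lr={tc.learning_rate}, batch={tc.batch_size})"
                )
            model.backward_from_probs(probs, onehot_tr[idx])
            opt.step()
            batch_losses.append(loss)
            batch_accs.append(float(np.mean(np.argmax(probs, axis=1) == y_tr[idx])))

        val_probs = _softmax(model.forward_logits(x_va, training=False))
        val_loss = cross_entropy(val_probs, y_va)
        history["loss"].append(float(np.mean(batch_losses)))
        history["accuracy"].append(float(np.mean(batch_accs)))
        history["val_loss"].append(val_loss)
        history["val_accuracy"].append(float(np.mean(np.argmax(val_probs, axis=1) == y_va)))
        stopped_epoch = epoch

        if val_loss < best_loss:
            best_loss = val_loss
            best_weights = model.get_weights()
            wait = 0
        else:
            wait += 1
            if wait >= tc.early_stop_patience:
                break

    if tc.restore_best and best_weights is not None:
        model.set_weights(best_weights)

    return TrainedModel(model, model.config, tc, history, stopped_epoch)


# ---------------------------------------------------------------------------
# Serialization (deterministic container: JSON header + raw array bytes)
# ---------------------------------------------------------------------------


def _write_container(path: str | Path, header: dict, arrays: list[np.ndarray]) -> None:
    specs = [
        {"shape": list(a.shape), "dtype": str(a.dtype)} for a in arrays
    ]
    header = dict(header, arrays=specs)
    blob = json.dumps(header, sort_keys=True).encode()
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<Q", len(blob)))
        fh.write(blob)
        for a in arrays:
            fh.write(np.ascontiguousarray(a).tobytes())


def _read_container(path: str | Path) -> tuple[dict, list[np.ndarray]]:
    with open(path, "rb") as fh:
        if fh.read(len(_MAGIC)) != _MAGIC:
            raise ValueError(f"{path}: not a model container")
        (n,) = struct.unpack("<Q", fh.read(8))
        header = json.loads(fh.read(n))
        arrays = []
        for spec in header["arrays"]:
            dt = np.dtype(spec["dtype"])
            count = int(np.prod(spec["shape"])) if spec["shape"] else 1
            data = fh.read(count * dt.itemsize)
            arrays.append(np.frombuffer(data, dtype=dt).reshape(spec["shape"]).copy())
    return header, arrays


def save_model(tm: TrainedModel, path: str | Path) -> None:
    """Serialize a trained model; weights are stored as float32."""
    header = {
        "format": "afedge-model",
        "kind": "float32",
        "model_config": asdict(tm.model_config),
        "train_config": asdict(tm.train_config),
        "stopped_epoch": tm.stopped_epoch,
        "history": tm.history,
    }
    arrays = [a.astype(np.float32) for a in tm.model.all_arrays()]
    _write_container(path, header, arrays)


def load_model(path: str | Path) -> TrainedModel:
    """Rebuild a trained model from its serialized container."""
    header, arrays = _read_container(path)
    if header.get("kind") != "float32":
        raise ValueError(f"{path}: container holds a {header.get('kind')} model")
    cfg = ModelConfig(**header["model_config"])
    tc = TrainConfig(**header["train_config"])
    model = CNN1D(cfg, seed=0)
    model.set_weights([np.asarray(a, dtype=float) for a in arrays])
    return TrainedModel(model, cfg, tc, header.get("history", {}), header.get("stopped_epoch", 0))


def model_file_size(path: str | Path) -> int:
    return Path(path).stat().st_size


def predict_proba(model: CNN1D | TrainedModel, windows: np.ndarray) -> np.ndarray:
    """Module-level convenience wrapper around ``predict_proba``."""
    return model.predict_proba(windows)
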