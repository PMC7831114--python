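"""The scalogram + RR-interval fusion CNN, in NumPy with manual backprop.

Architecture (shapes for a 100x100x1 scalogram input):

    conv 7x7x16 (no bias) -> BN -> ReLU -> maxpool 5/5   94x94x16 -> 18x18x16
    conv 3x3x32 (no bias) -> BN -> ReLU -> maxpool 3/3   16x16x32 -> 5x5x32
    conv 3x3x64 (no bias) -> BN -> ReLU -> global maxpool 3x3x64 -> 64
    concat 4 RR features -> 68 -> dense 32 -> ReLU -> dense 4

Convolutions are valid (padding 0, stride 1) and carry no bias — the
following batch-norm shift makes one redundant; dense layers carry bias.
Pooling windows use floor division (94 -> 18 at 5/5, 16 -> 5 at 3/3).
Training: softmax cross-entropy, Adam, He-initialized weights, learning
rate 1e-3 decayed x0.1 every 5 epochs, batch size 1024, up to 30 epochs.

Everything runs on CPU and is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "HeartbeatCNN",
    "LayerSummary",
    "build_model",
    "count_parameters",
    "train",
    "predict",
    "learning_rate_at",
    "save_model",
    "load_model",
]

CLASS_ORDER = ("N", "SVEB", "VEB", "F")


@dataclass
class ModelConfig:
    input_shape: tuple[int, int] = (100, 100)
    n_rr_features: int = 4
    n_classes: int = 4
    conv_channels: tuple[int, int, int] = (16, 32, 64)
    conv_kernels: tuple[int, int, int] = (7, 3, 3)
    pool_sizes: tuple[int, int] = (5, 3)
    dense_hidden: int = 32


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    lr_decay: float = 0.1
    lr_step_epochs: int = 5
    batch_size: int = 1024
    max_epochs: int = 30
    seed: int = 0
    class_weights: tuple[float, ...] | None = None  # off by default
    bn_momentum: float = 0.1


def learning_rate_at(epoch: int, cfg: TrainConfig) -> float:
    """Step-decay schedule: lr * decay^floor(epoch / step) (0-based epoch)."""
    return cfg.learning_rate * cfg.lr_decay ** (epoch // cfg.lr_step_epochs)


class Param:
    """A trainable array with its gradient and Adam moments."""

    __slots__ = ("v", "g", "m", "s")

    def __init__(self, value: np.ndarray):
        self.v = value
        self.g = np.zeros_like(value)
        self.m = np.zeros_like(value)
        self.s = np.zeros_like(value)


class _Conv2D:
    """Valid convolution, stride 1, no bias (im2col + matrix multiply)."""

    def __init__(
        self, c_in: int, c_out: int, k: int, rng: np.random.Generator, dtype=np.float32
    ):
        std = np.sqrt(2.0 / (c_in * k * k))  # He initialization
        self.W = Param(rng.normal(0.0, std, size=(c_out, c_in, k, k)).astype(dtype))
        self.k = k

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        k = self.k
        ho, wo = h - k + 1, w - k + 1
        win = sliding_window_view(x, (k, k), axis=(2, 3))  # (b,c,ho,wo,k,k)
        self._col = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            b * ho * wo, c * k * k
        )
        self._x_shape = x.shape
        co = self.W.v.shape[0]
        out = self._col @ self.W.v.reshape(co, -1).T
        return out.reshape(b, ho, wo, co).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, co, ho, wo = dout.shape
        k = self.k
        c = self._x_shape[1]
        dmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, co)
        self.W.g += (dmat.T @ self._col).reshape(self.W.v.shape)
        dcol = dmat @ self.W.v.reshape(co, -1)  # (b*ho*wo, c*k*k)
        dcol = np.ascontiguousarray(
            dcol.reshape(b, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        )
        dx = np.zeros(self._x_shape, dtype=dout.dtype)
        for i in range(k):  # col2im scatter-add
            for j in range(k):
                dx[:, :, i : i + ho, j : j + wo] += dcol[..., i, j]
        return dx

    def params(self) -> list[Param]:
        return [self.W]

    def n_parameters(self) -> int:
        return self.W.v.size  # weight only: conv layers carry no bias


class _BatchNorm2D:
    """Per-channel batch normalization with learnable scale/shift."""

    def __init__(
        self, channels: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32
    ):
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        self.inv_std = 1.0 / np.sqrt(var + self.eps)
        self.xhat = (x - mean[None, :, None, None]) * self.inv_std[None, :, None, None]
        return (
            self.gamma.v[None, :, None, None] * self.xhat
            + self.beta.v[None, :, None, None]
        )

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.gamma.g += (dout * self.xhat).sum(axis=(0, 2, 3))
        self.beta.g += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.v[None, :, None, None]
        sum_dxhat = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        sum_dxhat_xhat = (dxhat * self.xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (
            self.inv_std[None, :, None, None]
            / n
            * (n * dxhat - sum_dxhat - self.xhat * sum_dxhat_xhat)
        )

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def n_parameters(self) -> int:
        # scale + shift + the two tracked statistics: 4 per channel
        return 4 * self.gamma.v.size


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self.mask = x > 0
        return np.where(self.mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self.mask


class _MaxPool2D:
    """k x k window, stride k, floor division on the spatial extent."""

    def __init__(self, k: int):
        self.k = k

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        k = self.k
        ho, wo = (h - k) // k + 1, (w - k) // k + 1
        self.x_shape = x.shape
        win = (
            x[:, :, : ho * k, : wo * k]
            .reshape(b, c, ho, k, wo, k)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(b, c, ho, wo, k * k)
        )
        self.idx = win.argmax(axis=-1)
        return np.take_along_axis(win, self.idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, ho, wo = dout.shape
        k = self.k
        g = np.zeros((b, c, ho, wo, k * k), dtype=dout.dtype)
        np.put_along_axis(g, self.idx[..., None], dout[..., None], axis=-1)
        g = (
            g.reshape(b, c, ho, wo, k, k)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(b, c, ho * k, wo * k)
        )
        dx = np.zeros(self.x_shape, dtype=dout.dtype)
        dx[:, :, : ho * k, : wo * k] = g
        return dx


class _GlobalMaxPool:
    """Max over the full spatial extent, yielding one value per channel."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        flat = x.reshape(b, c, h * w)
        self.idx = flat.argmax(axis=-1)
        self.x_shape = x.shape
        return np.take_along_axis(flat, self.idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, h, w = self.x_shape
        g = np.zeros((b, c, h * w), dtype=dout.dtype)
        np.put_along_axis(g, self.idx[..., None], dout[..., None], axis=-1)
        return g.reshape(self.x_shape)


class _Dense:
    """Affine layer with bias."""

    def __init__(
        self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32
    ):
        std = np.sqrt(2.0 / n_in)
        self.W = Param(rng.normal(0.0, std, size=(n_in, n_out)).astype(dtype))
        self.b = Param(np.zeros(n_out, dtype=dtype))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x = x
        return x @ self.W.v + self.b.v

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.g += self.x.T @ dout
        self.b.g += dout.sum(axis=0)
        return dout @ self.W.v.T

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def n_parameters(self) -> int:
        return self.W.v.size + self.b.v.size


@dataclass
class LayerSummary:
    name: str
    output_shape: tuple[int, ...]
    n_parameters: int


class HeartbeatCNN:
    """Two-input classifier: 100x100 scalogram plus 4 RR-interval features."""

    def __init__(
        self, config: ModelConfig | None = None, seed: int = 0, dtype=np.float32
    ):
        self.config = config or ModelConfig()
        self.dtype = np.dtype(dtype)
        cfg = self.config
        rng = np.random.default_rng(seed)
        c1, c2, c3 = cfg.conv_channels
        k1, k2, k3 = cfg.conv_kernels
        p1, p2 = cfg.pool_sizes
        self.conv1 = _Conv2D(1, c1, k1, rng, dtype)
        self.bn1 = _BatchNorm2D(c1, dtype=dtype)
        self.relu1 = _ReLU()
        self.pool1 = _MaxPool2D(p1)
        self.conv2 = _Conv2D(c1, c2, k2, rng, dtype)
        self.bn2 = _BatchNorm2D(c2, dtype=dtype)
        self.relu2 = _ReLU()
        self.pool2 = _MaxPool2D(p2)
        self.conv3 = _Conv2D(c2, c3, k3, rng, dtype)
        self.bn3 = _BatchNorm2D(c3, dtype=dtype)
        self.relu3 = _ReLU()
        self.global_pool = _GlobalMaxPool()
        self.dense1 = _Dense(c3 + cfg.n_rr_features, cfg.dense_hidden, rng, dtype)
        self.relu4 = _ReLU()
        self.dense2 = _Dense(cfg.dense_hidden, cfg.n_classes, rng, dtype)
        self._check_shapes()

    # -- construction-time shape audit -------------------------------------
    def _check_shapes(self) -> None:
        h, w = self.config.input_shape
        for name, k, p in zip(
            ("conv1", "conv2", "conv3"),
            self.config.conv_kernels,
            (*self.config.pool_sizes, None),
        ):
            h, w = h - k + 1, w - k + 1
            if h <= 0 or w <= 0:
                raise ValueError(f"{name}: spatial extent collapsed to {h}x{w}")
            if p is not None:
                h, w = (h - p) // p + 1, (w - p) // p + 1

    # -- forward / backward -------------------------------------------------
    def forward(
        self, x: np.ndarray, rr: np.ndarray, training: bool = False
    ) -> np.ndarray:
        """Raw class scores for a batch: x (B,1,H,W), rr (B,4) -> (B,4)."""
        x = np.asarray(x, dtype=self.dtype)
        rr = np.asarray(rr, dtype=self.dtype)
        h = self.pool1.forward(
            self.relu1.forward(self.bn1.forward(self.conv1.forward(x), training))
        )
        h = self.pool2.forward(
            self.relu2.forward(self.bn2.forward(self.conv2.forward(h), training))
        )
        h = self.global_pool.forward(
            self.relu3.forward(self.bn3.forward(self.conv3.forward(h), training))
        )
        z = np.concatenate([h, rr], axis=1)
        self._n_features = h.shape[1]
        return self.dense2.forward(self.relu4.forward(self.dense1.forward(z)))

    def backward(self, dlogits: np.ndarray) -> None:
        dz = self.dense1.backward(self.relu4.backward(self.dense2.backward(dlogits)))
        dh = dz[:, : self._n_features]
        dh = self.conv3.backward(
            self.bn3.backward(self.relu3.backward(self.global_pool.backward(dh)))
        )
        dh = self.pool2.backward(dh)
        dh = self.conv2.backward(self.bn2.backward(self.relu2.backward(dh)))
        dh = self.pool1.backward(dh)
        self.conv1.backward(self.bn1.backward(self.relu1.backward(dh)))

    # -- introspection -------------------------------------------------------
    def _param_layers(self):
        return {
            "conv1": self.conv1,
            "bn1": self.bn1,
            "conv2": self.conv2,
            "bn2": self.bn2,
            "conv3": self.conv3,
            "bn3": self.bn3,
            "dense1": self.dense1,
            "dense2": self.dense2,
        }

    def parameters(self) -> list[Param]:
        out: list[Param] = []
        for layer in self._param_layers().values():
            out.extend(layer.params())
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.g[:] = 0.0

    def layer_summary(self) -> list[LayerSummary]:
        """Output shape and parameter count of every layer, in forward order.

        Shapes are reported channels-last (H, W, C) as is conventional for
        architecture tables; parameter counts follow the convention of
        weight-only convolutions, 4 values per batch-norm channel, and
        dense weights plus bias.
        """
        h, w = self.config.input_shape
        x = np.zeros((1, 1, h, w))
        rr = np.zeros((1, self.config.n_rr_features))
        rows: list[LayerSummary] = [LayerSummary("input_scalogram", (h, w, 1), 0)]

        def chw(t: np.ndarray) -> tuple[int, ...]:
            return (t.shape[2], t.shape[3], t.shape[1]) if t.ndim == 4 else t.shape[1:]

        t = self.conv1.forward(x)
        rows.append(LayerSummary("conv1", chw(t), self.conv1.n_parameters()))
        t = self.bn1.forward(t, training=False)
        rows.append(LayerSummary("bn1", chw(t), self.bn1.n_parameters()))
        t = self.relu1.forward(t)
        rows.append(LayerSummary("relu1", chw(t), 0))
        t = self.pool1.forward(t)
        rows.append(LayerSummary("pool1", chw(t), 0))
        t = self.conv2.forward(t)
        rows.append(LayerSummary("conv2", chw(t), self.conv2.n_parameters()))
        t = self.bn2.forward(t, training=False)
        rows.append(LayerSummary("bn2", chw(t), self.bn2.n_parameters()))
        t = self.relu2.forward(t)
        rows.append(LayerSummary("relu2", chw(t), 0))
        t = self.pool2.forward(t)
        rows.append(LayerSummary("pool2", chw(t), 0))
        t = self.conv3.forward(t)
        rows.append(LayerSummary("conv3", chw(t), self.conv3.n_parameters()))
        t = self.bn3.forward(t, training=False)
        rows.append(LayerSummary("bn3", chw(t), self.bn3.n_parameters()))
        t = self.relu3.forward(t)
        rows.append(LayerSummary("relu3", chw(t), 0))
        t = self.global_pool.forward(t)
        rows.append(LayerSummary("global_pool", (1, 1, t.shape[1]), 0))
        rows.append(LayerSummary("flatten", (t.shape[1],), 0))
        rows.append(LayerSummary("input_rr", (rr.shape[1],), 0))
        z = np.concatenate([t, rr], axis=1)
        rows.append(LayerSummary("concat", (z.shape[1],), 0))
        z = self.dense1.forward(z)
        rows.append(LayerSummary("dense1", (z.shape[1],), self.dense1.n_parameters()))
        z = self.relu4.forward(z)
        z = self.dense2.forward(z)
        rows.append(LayerSummary("dense2", (z.shape[1],), self.dense2.n_parameters()))
        return rows

    def total_parameters(self) -> int:
        return sum(row.n_parameters for row in self.layer_summary())

    # -- serialization -------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, layer in self._param_layers().items():
            if isinstance(layer, _Conv2D):
                state[f"{name}.W"] = layer.W.v
            elif isinstance(layer, _Dense):
                state[f"{name}.W"] = layer.W.v
                state[f"{name}.b"] = layer.b.v
            elif isinstance(layer, _BatchNorm2D):
                state[f"{name}.gamma"] = layer.gamma.v
                state[f"{name}.beta"] = layer.beta.v
                state[f"{name}.running_mean"] = layer.running_mean
                state[f"{name}.running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, layer in self._param_layers().items():
            if isinstance(layer, _Conv2D):
                layer.W.v[:] = state[f"{name}.W"]
            elif isinstance(layer, _Dense):
                layer.W.v[:] = state[f"{name}.W"]
                layer.b.v[:] = state[f"{name}.b"]
            elif isinstance(layer, _BatchNorm2D):
                layer.gamma.v[:] = state[f"{name}.gamma"]
                layer.beta.v[:] = state[f"{name}.beta"]
                layer.running_mean[:] = state[f"{name}.running_mean"]
                layer.running_var[:] = state[f"{name}.running_var"]


def build_model(config: ModelConfig | None = None, seed: int = 0) -> HeartbeatCNN:
    return HeartbeatCNN(config, seed=seed)


def count_parameters(model: HeartbeatCNN, layer_name: str) -> int:
    """Parameter count of one named layer (see ``layer_summary`` names)."""
    for row in model.layer_summary():
        if row.name == layer_name:
            return row.n_parameters
    raise KeyError(f"unknown layer {layer_name!r}")


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(
    logits: np.ndarray, labels: np.ndarray, weights: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    probs = _softmax(logits)
    n = logits.shape[0]
    picked = probs[np.arange(n), labels]
    w = np.ones(n) if weights is None else weights[labels]
    loss = float(-(w * np.log(np.clip(picked, 1e-12, None))).sum() / w.sum())
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    grad *= (w / w.sum())[:, None]
    return loss, grad


class _Adam:
    def __init__(self, params: list[Param], beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for p in self.params:
            p.m = self.beta1 * p.m + (1 - self.beta1) * p.g
            p.s = self.beta2 * p.s + (1 - self.beta2) * p.g**2
            p.v -= lr * (p.m / b1c) / (np.sqrt(p.s / b2c) + self.eps)


def train(
    model: HeartbeatCNN,
    x: np.ndarray,
    rr: np.ndarray,
    labels: np.ndarray,
    cfg: TrainConfig | None = None,
    *,
    log_fn=None,
) -> list[dict]:
    """Train in place; returns the per-epoch log [{epoch, lr, loss}, ...].

    Deterministic for a fixed ``cfg.seed``: the shuffle order and all
    arithmetic depend only on the seed and the data.
    """
    cfg = cfg or TrainConfig()
    x = np.asarray(x, dtype=np.float64)
    rr = np.asarray(rr, dtype=np.float64)
    labels = np.asarray(labels)
    if x.shape[0] == 0:
        raise ValueError("empty training set")
    if labels.min() < 0 or labels.max() >= model.config.n_classes:
        raise ValueError("labels must be integer class indices")
    weights = (
        np.asarray(cfg.class_weights, dtype=np.float64)
        if cfg.class_weights is not None
        else None
    )
    rng = np.random.default_rng(cfg.seed)
    optimizer = _Adam(model.parameters())
    log: list[dict] = []
    n = x.shape[0]
    for epoch in range(cfg.max_epochs):
        lr = learning_rate_at(epoch, cfg)
        order = rng.permutation(n)
        total_loss, n_batches = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = model.forward(x[idx], rr[idx], training=True)
            loss, dlogits = cross_entropy(logits, labels[idx], weights)
            model.zero_grad()
            model.backward(dlogits)
            optimizer.step(lr)
            total_loss += loss
            n_batches += 1
        entry = {"epoch": epoch, "lr": lr, "loss": total_loss / n_batches}
        log.append(entry)
        if log_fn is not None:
            log_fn(entry)
    return log


def predict(
    model: HeartbeatCNN, x: np.ndarray, rr: np.ndarray, batch_size: int = 256
) -> np.ndarray:
    """Predicted class indices: argmax over raw scores, ties to the lowest
    index (class order N < SVEB < VEB < F)."""
    x = np.asarray(x, dtype=np.float64)
    rr = np.asarray(rr, dtype=np.float64)
    if x.ndim != 4 or x.shape[1] != 1:
        raise ValueError(f"expected scalograms of shape (B, 1, H, W), got {x.shape}")
    if rr.shape != (x.shape[0], model.config.n_rr_features):
        raise ValueError(
            f"RR features shape {rr.shape} does not match batch {x.shape[0]}"
        )
    out = np.empty(x.shape[0], dtype=np.int64)
    for start in range(0, x.shape[0], batch_size):
        sl = slice(start, start + batch_size)
        logits = model.forward(x[sl], rr[sl], training=False)
        out[sl] = logits.argmax(axis=1)
    return out


def predict_proba(
    model: HeartbeatCNN, x: np.ndarray, rr: np.ndarray, batch_size: int = 256
) -> np.ndarray:
    """Softmax class probabilities (inference only)."""
    x = np.asarray(x, dtype=np.float64)
    rr = np.asarray(rr, dtype=np.float64)
    out = np.empty((x.shape[0], model.config.n_classes))
    for start in range(0, x.shape[0], batch_size):
        sl = slice(start, start + batch_size)
        out[sl] = _softmax(model.forward(x[sl], rr[sl], training=False))
    return out


def save_model(model: HeartbeatCNN, path: str | Path) -> None:
    path = Path(path)
    np.savez_compressed(
        path,
        __config__=json.dumps(asdict(model.config)),
        **model.state_dict(),
    )


def load_model(path: str | Path) -> HeartbeatCNN:
    with np.load(Path(path), allow_pickle=False) as data:
        raw = json.loads(str(data["__config__"]))
        for key in ("input_shape", "conv_channels", "conv_kernels", "pool_sizes"):
            raw[key] = tuple(raw[key])
        model = HeartbeatCNN(ModelConfig(**raw))
        model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return model
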