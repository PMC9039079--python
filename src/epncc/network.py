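"""Small 1-D convolutional network with manual backprop.

Two parallel branches — one per feature stream (scattering time-domain,
EPNCC frequency-domain) — each a cascade of conv modules
(valid convolution -> ReLU -> max pooling), flattened, concatenated and
fed to a fully connected softmax layer over the clinical classes.
Optimization is minibatch stochastic gradient descent with momentum
(v <- m v - lr g; theta <- theta + v) and a step learning-rate schedule.

Everything is plain numpy with seeded initialization, so training is
bit-deterministic for a fixed seed and dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError, TrainingError


@dataclass(frozen=True)
class ConvModuleConfig:
    """One conv module: valid conv -> ReLU -> max pool."""

    kernel_length: int
    stride: int
    n_filters: int
    pool_length: int
    pool_stride: int


# the two stacked modules applied inside every branch
CONV_MODULES_DEFAULT = (
    ConvModuleConfig(kernel_length=5, stride=2, n_filters=32,
                     pool_length=3, pool_stride=2),
    ConvModuleConfig(kernel_length=3, stride=1, n_filters=64,
                     pool_length=3, pool_stride=1),
)


@dataclass(frozen=True)
class TrainConfig:
    momentum: float = 0.9
    initial_lr: float = 0.01
    lr_drop_factor: float = 0.7
    lr_drop_period_epochs: int = 10
    max_epochs: int = 50
    batch_size: int = 32
    split_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.split_fraction < 1):
            raise ParameterError("split_fraction must lie in (0, 1)")
        if not (0 <= self.momentum < 1):
            raise ParameterError("momentum must lie in [0, 1)")

    def lr_at_epoch(self, epoch: int) -> float:
        """Learning rate for a 1-indexed epoch (multiplicative drops)."""
        if epoch < 1:
            raise ParameterError("epochs are 1-indexed")
        drops = (epoch - 1) // self.lr_drop_period_epochs
        return self.initial_lr * self.lr_drop_factor ** drops


def conv_output_length(l_in: int, kernel: int, stride: int) -> int:
    """Valid (no-padding) output length: floor((L - k)/stride) + 1."""
    if l_in < kernel:
        raise ParameterError(f"input length {l_in} shorter than kernel {kernel}")
    return (l_in - kernel) // stride + 1


def _sliding(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(N, L, C) -> (N, L_out, k, C) strided windows."""
    w = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)
    return np.ascontiguousarray(w[:, ::stride].transpose(0, 1, 3, 2))


class _Conv1D:
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        fan_in = kernel * c_in
        bound = 1.0 / np.sqrt(fan_in)
        self.w = rng.uniform(-bound, bound, size=(fan_in, c_out))
        self.b = np.zeros(c_out)
        self.kernel, self.stride = kernel, stride
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        cols = _sliding(x, self.kernel, self.stride)
        self._cols = cols.reshape(x.shape[0], cols.shape[1], -1)
        return self._cols @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, l_out, _ = dy.shape
        self.dw = np.einsum("nlf,nlo->fo", self._cols, dy)
        self.db = dy.sum(axis=(0, 1))
        dx = np.zeros(self._x_shape)
        wk = self.w.reshape(self.kernel, self.c_in, self.c_out)
        for t in range(self.kernel):
            dx[:, t:t + self.stride * l_out:self.stride, :] += dy @ wk[t].T
        return dx

    def params(self):
        return [("w", self), ("b", self)]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask

    def params(self):
        return []


class _MaxPool1D:
    def __init__(self, length: int, stride: int):
        self.length, self.stride = length, stride

    def forward(self, x):
        self._x_shape = x.shape
        w = _sliding(x, self.length, self.stride)  # (N, L_out, k, C)
        self._arg = np.argmax(w, axis=2)
        return np.max(w, axis=2)

    def backward(self, dy):
        n, l_out, c = dy.shape
        dx = np.zeros(self._x_shape)
        ni, ci = np.ogrid[:n, :c]
        for i in range(l_out):
            pos = i * self.stride + self._arg[:, i, :]
            np.add.at(dx, (ni, pos, ci), dy[:, i, :])
        return dx

    def params(self):
        return []


class _Branch:
    """Conv-module cascade over one feature stream."""

    def __init__(self, input_len: int, modules: tuple[ConvModuleConfig, ...],
                 rng: np.random.Generator):
        self.layers = []
        l, c = input_len, 1
        for m in modules:
            self.layers.append(_Conv1D(c, m.n_filters, m.kernel_length,
                                       m.stride, rng))
            l = conv_output_length(l, m.kernel_length, m.stride)
            self.layers.append(_ReLU())
            self.layers.append(_MaxPool1D(m.pool_length, m.pool_stride))
            l = conv_output_length(l, m.pool_length, m.pool_stride)
            c = m.n_filters
        self.output_dim = l * c

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = x[:, :, None]  # single input channel
        for layer in self.layers:
            h = layer.forward(h)
        self._h_shape = h.shape
        return h.reshape(h.shape[0], -1)

    def backward(self, dflat: np.ndarray) -> None:
        dh = dflat.reshape(self._h_shape)
        for layer in reversed(self.layers):
            dh = layer.backward(dh)


def conv_branch_forward(x: np.ndarray,
                        modules: tuple[ConvModuleConfig, ...] = CONV_MODULES_DEFAULT,
                        seed: int = 0,
                        branch: "_Branch | None" = None) -> np.ndarray:
    """Run one vector through a conv-module cascade; returns (length,
    channels).  Under the default modules a 450-sample window maps
    450 -conv(5,s2)-> 223 -pool(3,s2)-> 111 -conv(3,s1)-> 109
    -pool(3,s1)-> 107 positions of 64 channels.

    A fresh seeded branch is built unless one is supplied."""
    x = np.asarray(x, dtype=float).reshape(1, -1)
    if branch is None:
        branch = _Branch(x.shape[1], modules, np.random.default_rng(seed))
    flat = branch.forward(x)
    return flat.reshape(branch._h_shape)[0]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(pred: np.ndarray, label: np.ndarray,
                  eps: float = 1e-12) -> float:
    """Categorical cross-entropy -sum y log yhat for one probability vector."""
    pred = np.asarray(pred, dtype=float)
    label = np.asarray(label, dtype=float)
    if abs(pred.sum() - 1.0) > 1e-6 or np.any(pred < 0):
        raise ParameterError("pred must be a probability vector")
    return float(-np.sum(label * np.log(np.clip(pred, eps, 1.0))))


class ClassifierModel:
    """Two-branch conv network + fully connected softmax head."""

    def __init__(self, input_lens: list[int], n_classes: int = 3,
                 modules: tuple[ConvModuleConfig, ...] = CONV_MODULES_DEFAULT,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.modules = modules
        self.n_classes = n_classes
        self.input_lens = list(input_lens)
        self.branches = [_Branch(l, modules, rng) for l in input_lens]
        d = sum(b.output_dim for b in self.branches)
        bound = 1.0 / np.sqrt(d)
        self.fc_w = rng.uniform(-bound, bound, size=(d, n_classes))
        self.fc_b = np.zeros(n_classes)
        self.history: dict = {"epoch_loss": [], "lr": []}

    # ---- forward / backward -------------------------------------------
    def forward_logits(self, streams: list[np.ndarray]) -> np.ndarray:
        if len(streams) != len(self.branches):
            raise ParameterError("one input stream per branch is required")
        feats = [b.forward(s) for b, s in zip(self.branches, streams)]
        self._concat = np.concatenate(feats, axis=1)
        self._dims = [f.shape[1] for f in feats]
        return self._concat @ self.fc_w + self.fc_b

    def predict_proba(self, streams: list[np.ndarray]) -> np.ndarray:
        return softmax(self.forward_logits(streams))

    def predict(self, streams: list[np.ndarray]) -> np.ndarray:
        return np.argmax(self.predict_proba(streams), axis=1)

    def _backward(self, dlogits: np.ndarray) -> None:
        self.dfc_w = self._concat.T @ dlogits
        self.dfc_b = dlogits.sum(axis=0)
        dconcat = dlogits @ self.fc_w.T
        offset = 0
        for b, d in zip(self.branches, self._dims):
            b.backward(dconcat[:, offset:offset + d])
            offset += d

    # ---- parameter plumbing -------------------------------------------
    def _param_refs(self):
        refs = [(self, "fc_w", "dfc_w"), (self, "fc_b", "dfc_b")]
        for b in self.branches:
            for layer in b.layers:
                if isinstance(layer, _Conv1D):
                    refs.append((layer, "w", "dw"))
                    refs.append((layer, "b", "db"))
        return refs

    def get_weights(self) -> dict[str, np.ndarray]:
        return {f"p{i}": getattr(o, n).copy()
                for i, (o, n, _) in enumerate(self._param_refs())}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for i, (o, n, _) in enumerate(self._param_refs()):
            setattr(o, n, np.asarray(weights[f"p{i}"], dtype=float).copy())


def train(model: ClassifierModel, streams: list[np.ndarray],
          labels: np.ndarray, config: TrainConfig) -> ClassifierModel:
    """SGDM training loop over minibatches (in place; returns the model).

    Raises :class:`TrainingError` with diagnostics if the loss turns
    non-finite.  Per-epoch mean loss and learning rate are recorded in
    ``model.history``.
    """
    n = labels.shape[0]
    rng = np.random.default_rng(config.seed)
    refs = model._param_refs()
    velocity = [np.zeros_like(getattr(o, name)) for o, name, _ in refs]

    for epoch in range(1, config.max_epochs + 1):
        lr = config.lr_at_epoch(epoch)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = [s[idx] for s in streams]
            y = labels[idx]
            logits = model.forward_logits(batch)
            probs = softmax(logits)
            loss = float(-np.mean(
                np.sum(y * np.log(np.clip(probs, 1e-12, 1.0)), axis=1)))
            if not np.isfinite(loss):
                raise TrainingError(
                    "non-finite training loss",
                    {"epoch": epoch, "batch_start": start, "lr": lr})
            losses.append(loss)
            model._backward((probs - y) / idx.size)
            for v, (o, name, gname) in zip(velocity, refs):
                v *= config.momentum
                v -= lr * getattr(o, gname)
                setattr(o, name, getattr(o, name) + v)
        model.history["epoch_loss"].append(float(np.mean(losses)))
        model.history["lr"].append(lr)
    return model


def sgdm_step(theta: np.ndarray, grad: np.ndarray, velocity: np.ndarray,
              lr: float, momentum: float) -> tuple[np.ndarray, np.ndarray]:
    """One momentum update: v <- m v - lr g; theta <- theta + v."""
    v = momentum * velocity - lr * grad
    return theta + v, v
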