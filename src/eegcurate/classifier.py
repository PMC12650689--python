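"""Small 1-D convolutional classifiers over DE feature vectors.

Three architecture variants share a Conv1D front end (64 filters, kernel 3,
ReLU) over the feature vector treated as a length-``input_dim``,
single-channel sequence:

* variant 1: conv -> max-pool(2) -> dropout(0.5) -> flatten -> output
* variant 2: conv -> dropout(0.25) -> max-pool(2) -> flatten ->
  dense(128, ReLU) -> dropout(0.25) -> output
* variant 3: variant 2 with both dropout rates at 0.5

The output layer is a single logistic unit for binary targets and a softmax
over ``n_classes`` units otherwise; training minimizes the matching
cross-entropy with Adam (learning rate 1e-4) for 50 epochs by default.

The layers, backpropagation and the Adam optimizer are implemented here in
numpy.  Everything is deterministic given the seeds: weight initialization
(Glorot uniform), mini-batch shuffling and dropout masks all flow from
explicit generators.  Batch size (32) and the initializer are choices of
this package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["ModelSpec", "TrainConfig", "build_model", "train", "predict", "Network"]

log = logging.getLogger(__name__)

_DTYPE = np.float32


@dataclass(frozen=True)
class ModelSpec:
    variant: int = 1
    n_classes: int = 2
    input_dim: int = 310

    def __post_init__(self) -> None:
        if self.variant not in (1, 2, 3):
            raise ValueError(f"unknown model variant {self.variant}; expected 1, 2 or 3")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.input_dim < 4:
            raise ValueError("input_dim must be >= 4")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    learning_rate: float = 1e-4
    batch_size: int = 32
    seed: int = 0


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(_DTYPE)


class _Layer:
    params: list[np.ndarray] = []
    grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def describe(self) -> tuple: # pragma: no cover
        raise NotImplementedError


class Conv1D(_Layer):
    """Valid-mode 1-D convolution with ReLU, via an im2col matmul."""

    def __init__(self, rng, filters: int, kernel: int, in_channels: int = 1):
        self.filters, self.kernel, self.in_channels = filters, kernel, in_channels
        self.W = _glorot(rng, kernel * in_channels, filters, (kernel * in_channels, filters))
        self.b = np.zeros(filters, dtype=_DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, training):
        # x: (n, L, cin); im2col over a 2-D view (cin == 1 throughout)
        n, L, cin = x.shape
        if cin != 1:  # pragma: no cover - single-channel sequences only
            raise ValueError("Conv1D supports single-channel input sequences")
        Lo = L - self.kernel + 1
        cols = np.lib.stride_tricks.sliding_window_view(x[:, :, 0], self.kernel, axis=1)
        self._cols = cols.reshape(-1, self.kernel)
        z = (self._cols @ self.W).reshape(n, Lo, self.filters) + self.b
        self._mask = z > 0
        return np.maximum(z, 0)

    def backward(self, grad):
        grad = grad * self._mask
        n, Lo, f = grad.shape
        g2 = grad.reshape(-1, f)
        self.grads[0][...] = self._cols.T @ g2
        self.grads[1][...] = g2.sum(axis=0)
        gw = g2 @ self.W.T  # (n*Lo, kernel)
        gw = gw.reshape(n, Lo, self.kernel)
        dx = np.zeros((n, Lo + self.kernel - 1, 1), dtype=grad.dtype)
        for k in range(self.kernel):
            dx[:, k : k + Lo, 0] += gw[:, :, k]
        return dx

    def describe(self):
        return ("conv1d", self.filters, self.kernel, "relu")


class MaxPool1D(_Layer):
    def __init__(self, pool: int = 2):
        self.pool = pool

    def forward(self, x, training):
        n, L, c = x.shape
        Lo = L // self.pool
        self._in_shape = x.shape
        xr = x[:, : Lo * self.pool, :].reshape(n, Lo, self.pool, c)
        if self.pool == 2:  # fast path: pairwise max (ties go to the first)
            a, b = xr[:, :, 0, :], xr[:, :, 1, :]
            self._first = a >= b
            return np.maximum(a, b)
        self._argmax = xr.argmax(axis=2)
        return np.take_along_axis(xr, self._argmax[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, grad):
        n, Lo, c = grad.shape
        dxr = np.zeros((n, Lo, self.pool, c), dtype=grad.dtype)
        if self.pool == 2:
            dxr[:, :, 0, :] = grad * self._first
            dxr[:, :, 1, :] = grad - dxr[:, :, 0, :]
        else:
            np.put_along_axis(dxr, self._argmax[:, :, None, :], grad[:, :, None, :], axis=2)
        dx = np.zeros(self._in_shape, dtype=grad.dtype)
        dx[:, : Lo * self.pool, :] = dxr.reshape(n, Lo * self.pool, c)
        return dx

    def describe(self):
        return ("maxpool1d", self.pool)


class Dropout(_Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        mask = self.rng.random(x.shape, dtype=np.float32) < keep
        self._mask = mask.astype(x.dtype)
        self._mask /= keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask

    def describe(self):
        return ("dropout", self.rate)


class Flatten(_Layer):
    def forward(self, x, training):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._in_shape)

    def describe(self):
        return ("flatten",)


class Dense(_Layer):
    def __init__(self, rng, n_in: int, n_out: int, activation: str):
        self.activation = activation
        self.W = _glorot(rng, n_in, n_out, (n_in, n_out))
        self.b = np.zeros(n_out, dtype=_DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, training):
        self._x = x
        z = x @ self.W + self.b
        if self.activation == "relu":
            self._mask = z > 0
            return np.maximum(z, 0)
        if self.activation == "sigmoid":
            return 1.0 / (1.0 + np.exp(-z))
        if self.activation == "softmax":
            z = z - z.max(axis=1, keepdims=True)
            e = np.exp(z)
            return e / e.sum(axis=1, keepdims=True)
        return z

    def backward(self, grad):
        # for the output layer, *grad* is already d(loss)/d(pre-activation)
        if self.activation == "relu":
            grad = grad * self._mask
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T

    def describe(self):
        return ("dense", self.W.shape[1], self.activation)


class Network:
    """A sequential stack with Adam; probabilities out, labels via argmax."""

    def __init__(self, spec: ModelSpec, layers: list[_Layer], rng: np.random.Generator):
        self.spec = spec
        self.layers = layers
        self.rng = rng

    # -- introspection ------------------------------------------------------
    def describe(self) -> list[tuple]:
        return [layer.describe() for layer in self.layers]

    def n_parameters(self) -> int:
        return sum(int(p.size) for layer in self.layers for p in layer.params)

    # -- forward/backward ---------------------------------------------------
    def forward(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        h = np.asarray(X, dtype=_DTYPE)[:, :, None]  # (n, L, 1)
        for layer in self.layers:
            h = layer.forward(h, training)
        return h

    def backward(self, d_preact: np.ndarray) -> None:
        g = d_preact
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def parameters(self):
        for layer in self.layers:
            yield from zip(layer.params, layer.grads)

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        arrays = {
            f"p{i:03d}": p for i, (p, _) in enumerate(self.parameters())
        }
        np.savez(
            path,
            variant=self.spec.variant,
            n_classes=self.spec.n_classes,
            input_dim=self.spec.input_dim,
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "Network":
        data = np.load(path)
        spec = ModelSpec(
            variant=int(data["variant"]),
            n_classes=int(data["n_classes"]),
            input_dim=int(data["input_dim"]),
        )
        net = build_model(spec)
        for i, (p, _) in enumerate(net.parameters()):
            p[...] = data[f"p{i:03d}"]
        return net


def build_model(spec: ModelSpec, seed: int = 0) -> Network:
    """Construct one of the three variants with seeded initialization."""
    rng = np.random.default_rng(seed)
    L_conv = spec.input_dim - 3 + 1
    L_pool = L_conv // 2
    flat = L_pool * 64
    out_units = 1 if spec.n_classes == 2 else spec.n_classes
    out_act = "sigmoid" if spec.n_classes == 2 else "softmax"

    if spec.variant == 1:
        layers = [
            Conv1D(rng, 64, 3),
            MaxPool1D(2),
            Dropout(0.5, rng),
            Flatten(),
            Dense(rng, flat, out_units, out_act),
        ]
    else:
        rate = 0.25 if spec.variant == 2 else 0.5
        layers = [
            Conv1D(rng, 64, 3),
            Dropout(rate, rng),
            MaxPool1D(2),
            Flatten(),
            Dense(rng, flat, 128, "relu"),
            Dropout(rate, rng),
            Dense(rng, 128, out_units, out_act),
        ]
    return Network(spec, layers, rng)


class _Adam:
    def __init__(self, params_grads, lr: float, beta1=0.9, beta2=0.999, eps=1e-7):
        self.pg = list(params_grads)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.pg]
        self.v = [np.zeros_like(p) for p, _ in self.pg]
        self.t = 0

    def step(self):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for (p, g), m, v in zip(self.pg, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


def train(
    model: Network,
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig = TrainConfig(),
) -> list[float]:
    """Fit *model* in place; returns the per-epoch mean loss history.

    ``y`` holds integer class indices (binary: 1 = positive class).
    Cross-entropy matches the output head.  A class absent from ``y`` in a
    multiclass setting (possible after aggressive cleaning) is logged at
    warning level, not an error.
    """
    X = np.asarray(X, dtype=_DTYPE)
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X rows and y length differ")
    if y.min(initial=0) < 0 or y.max(initial=0) >= model.spec.n_classes:
        raise ValueError("labels outside the scheme's class range")
    if model.spec.n_classes > 2:
        missing = set(range(model.spec.n_classes)) - set(np.unique(y).tolist())
        if missing:
            log.warning("classes %s absent from the training labels", sorted(missing))

    n = X.shape[0]
    rng = np.random.default_rng(cfg.seed)
    opt = _Adam(model.parameters(), cfg.learning_rate)
    binary = model.spec.n_classes == 2
    if binary:
        targets = y.astype(_DTYPE)[:, None]
    else:
        targets = np.zeros((n, model.spec.n_classes), dtype=_DTYPE)
        targets[np.arange(n), y] = 1.0

    eps = 1e-7
    history: list[float] = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, tb = X[idx], targets[idx]
            p = model.forward(xb, training=True)
            if binary:
                loss = -np.mean(tb * np.log(p + eps) + (1 - tb) * np.log(1 - p + eps))
            else:
                loss = -np.mean(np.sum(tb * np.log(p + eps), axis=1))
            # d(loss)/d(pre-activation) for sigmoid-BCE and softmax-CE alike
            model.backward((p - tb) / len(idx))
            opt.step()
            total += float(loss) * len(idx)
        history.append(total / n)
    return history


def predict(model: Network, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predicted class indices and per-class probabilities.

    Binary: probability >= 0.5 predicts the positive class (index 1; ties go
    positive).  Multiclass: argmax (lowest index wins exact ties).
    """
    X = np.asarray(X, dtype=_DTYPE)
    if X.ndim != 2 or X.shape[1] != model.spec.input_dim:
        raise ValueError(
            f"expected (n, {model.spec.input_dim}) inputs, got {X.shape}"
        )
    p = model.forward(X, training=False)
    if model.spec.n_classes == 2:
        proba = np.hstack([1.0 - p, p])
        return (p[:, 0] >= 0.5).astype(int), proba
    return p.argmax(axis=1), p
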