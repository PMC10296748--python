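"""A compact numpy neural-network engine for recurrent sequence classifiers.

Implements exactly the layer vocabulary the enhancer models need —
bidirectional LSTM (per-position outputs, so layers stack), dropout, batch
normalization, flatten and dense layers — together with RMSProp and Adam
optimizers and the two cross-entropy losses. Forward passes are vectorized
over the batch; backpropagation(-through-time) is written out analytically
and verified against finite differences in the test suite.

The LSTM cell follows the standard gate equations

    i = sigmoid(x W_i + h U_i + b_i)        input gate
    f = sigmoid(x W_f + h U_f + b_f)        forget gate (bias initialized 1)
    g = act(x W_g + h U_g + b_g)            candidate
    o = sigmoid(x W_o + h U_o + b_o)        output gate
    c = f * c_prev + i * g
    h = o * act(c)

where ``act`` is configurable and defaults to SELU (the scaled exponential
linear unit), keeping gate nonlinearities sigmoidal. Output layers use the
numerically fused logit + cross-entropy formulation; sigmoid/softmax are
applied at prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# SELU constants (self-normalizing networks)
_SELU_ALPHA = 1.6732632423543772
_SELU_LAMBDA = 1.0507009873554805


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite during training."""

    def __init__(self, epoch: int, batch: int) -> None:
        super().__init__(f"non-finite loss at epoch {epoch}, batch {batch}")
        self.epoch = epoch
        self.batch = batch


# ------------------------------------------------------------------ activations

def selu(x: np.ndarray) -> np.ndarray:
    neg = np.minimum(x, 0.0)  # keep expm1 off the positive branch
    return _SELU_LAMBDA * np.where(x > 0, x, _SELU_ALPHA * np.expm1(neg))


def selu_grad(x: np.ndarray) -> np.ndarray:
    neg = np.minimum(x, 0.0)
    return _SELU_LAMBDA * np.where(x > 0, 1.0, _SELU_ALPHA * np.exp(neg))


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_grad(x: np.ndarray) -> np.ndarray:
    return (x > 0).astype(float)


def tanh(x: np.ndarray) -> np.ndarray:
    return np.tanh(x)


def tanh_grad(x: np.ndarray) -> np.ndarray:
    return 1.0 - np.tanh(x) ** 2


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


_ACTIVATIONS = {
    "selu": (selu, selu_grad),
    "relu": (relu, relu_grad),
    "tanh": (tanh, tanh_grad),
    "linear": (lambda x: x, lambda x: np.ones_like(x)),
}


# ------------------------------------------------------------------ layers

class Layer:
    """Base class: holds flat lists of parameter and gradient arrays."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def build(self, input_shape: tuple, rng: np.random.Generator) -> tuple:
        """Allocate parameters; return the output shape (without batch dim)."""
        return input_shape

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _orthogonal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    a = rng.standard_normal((max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    return q[:rows, :cols] if q.shape != (rows, cols) else q


class _LSTMCell:
    """One direction of an LSTM; weights packed as [i | f | g | o] blocks.

    The cell state is clipped to ``[-cell_clip, cell_clip]`` after each
    update. With an unbounded candidate activation such as SELU the state
    otherwise drifts without limit over long sequences and saturates the
    gates; clipping (a standard LSTM stabilization) bounds the recurrence
    while leaving in-range dynamics untouched.
    """

    def __init__(self, units: int, activation: str, cell_clip: float = 3.0) -> None:
        self.units = units
        self.cell_clip = cell_clip
        self.act, self.act_grad = _ACTIVATIONS[activation]

    def build(self, input_dim: int, rng: np.random.Generator) -> None:
        H = self.units
        self.W = _glorot(rng, input_dim, 4 * H)
        self.U = np.concatenate(
            [_orthogonal(rng, H, H) for _ in range(4)], axis=1
        )
        self.b = np.zeros(4 * H)
        self.b[H : 2 * H] = 1.0  # forget-gate bias
        self.dW = np.zeros_like(self.W)
        self.dU = np.zeros_like(self.U)
        self.db = np.zeros_like(self.b)

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.U, self.b]

    @property
    def grads(self) -> list[np.ndarray]:
        return [self.dW, self.dU, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, D = x.shape
        H = self.units
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        cache = {k: np.empty((B, T, H)) for k in
                 ("i", "f", "g", "o", "c", "zg", "h_prev", "c_prev", "cmask")}
        hs = np.empty((B, T, H))
        xw = (x.reshape(B * T, D) @ self.W).reshape(B, T, 4 * H) + self.b
        for t in range(T):
            z = xw[:, t] + h @ self.U
            zi, zf, zg, zo = z[:, :H], z[:, H:2*H], z[:, 2*H:3*H], z[:, 3*H:]
            i, f_, o = sigmoid(zi), sigmoid(zf), sigmoid(zo)
            g = self.act(zg)
            cache["h_prev"][:, t] = h
            cache["c_prev"][:, t] = c
            c_raw = f_ * c + i * g
            cache["cmask"][:, t] = (np.abs(c_raw) < self.cell_clip).astype(float)
            c = np.clip(c_raw, -self.cell_clip, self.cell_clip)
            h = o * self.act(c)
            for k, v in (("i", i), ("f", f_), ("g", g), ("o", o), ("c", c), ("zg", zg)):
                cache[k][:, t] = v
            hs[:, t] = h
        self._x = x
        self._cache = cache
        return hs

    def backward(self, dh_out: np.ndarray) -> np.ndarray:
        x, cc = self._x, self._cache
        B, T, D = x.shape
        H = self.units
        dz_all = np.empty((B, T, 4 * H))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            i, f_, g, o, c = (cc[k][:, t] for k in ("i", "f", "g", "o", "c"))
            dh = dh_out[:, t] + dh_next
            do = dh * self.act(c)
            dc = (dh * o * self.act_grad(c) + dc_next) * cc["cmask"][:, t]
            di = dc * g
            df = dc * cc["c_prev"][:, t]
            dg = dc * i
            dc_next = dc * f_
            dz = dz_all[:, t]
            dz[:, :H] = di * i * (1 - i)
            dz[:, H:2*H] = df * f_ * (1 - f_)
            dz[:, 2*H:3*H] = dg * self.act_grad(cc["zg"][:, t])
            dz[:, 3*H:] = do * o * (1 - o)
            dh_next = dz @ self.U.T
        dz_flat = dz_all.reshape(B * T, 4 * H)
        self.dW[...] = x.reshape(B * T, D).T @ dz_flat
        self.dU[...] = cc["h_prev"].reshape(B * T, H).T @ dz_flat
        self.db[...] = dz_flat.sum(axis=0)
        return (dz_flat @ self.W.T).reshape(B, T, D)


class BiLSTM(Layer):
    """Bidirectional LSTM emitting per-position outputs (forward ++ backward)."""

    def __init__(self, units: int, activation: str = "selu") -> None:
        super().__init__()
        self.units = units
        self.fwd = _LSTMCell(units, activation)
        self.bwd = _LSTMCell(units, activation)

    def build(self, input_shape: tuple, rng: np.random.Generator) -> tuple:
        T, D = input_shape
        self.fwd.build(D, rng)
        self.bwd.build(D, rng)
        self.params = self.fwd.params + self.bwd.params
        self.grads = self.fwd.grads + self.bwd.grads
        return (T, 2 * self.units)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        hf = self.fwd.forward(x)
        hb = self.bwd.forward(x[:, ::-1])[:, ::-1]
        return np.concatenate([hf, hb], axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        H = self.units
        dxf = self.fwd.backward(grad[:, :, :H])
        dxb = self.bwd.backward(grad[:, ::-1, H:])[:, ::-1]
        # cell.grads arrays are mutated in place; self.grads stays aliased
        return dxf + dxb


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def build(self, input_shape: tuple, rng: np.random.Generator) -> tuple:
        if self.rng is None:
            self.rng = np.random.default_rng(rng.integers(2**31))
        return input_shape

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class BatchNorm(Layer):
    """Per-feature normalization over the batch (and time) axes."""

    def __init__(self, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum = momentum
        self.eps = eps

    def build(self, input_shape: tuple, rng: np.random.Generator) -> tuple:
        n_feat = input_shape[-1]
        self.gamma = np.ones(n_feat)
        self.beta = np.zeros(n_feat)
        self.dgamma = np.zeros(n_feat)
        self.dbeta = np.zeros(n_feat)
        self.params = [self.gamma, self.beta]
        self.grads = [self.dgamma, self.dbeta]
        self.running_mean = np.zeros(n_feat)
        self.running_var = np.ones(n_feat)
        return input_shape

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._istd
        self._axes = axes
        self._m = np.prod([x.shape[a] for a in axes])
        self._training = training
        return self.gamma * self._xhat + self.beta

    def backward(self, grad: np.ndarray) -> np.ndarray:
        axes, m = self._axes, self._m
        self.dgamma[...] = (grad * self._xhat).sum(axis=axes)
        self.dbeta[...] = grad.sum(axis=axes)
        if not self._training:
            return grad * self.gamma * self._istd
        dxhat = grad * self.gamma
        return (
            self._istd
            / m
            * (m * dxhat - dxhat.sum(axis=axes) - self._xhat * (dxhat * self._xhat).sum(axis=axes))
        )


class Flatten(Layer):
    def build(self, input_shape: tuple, rng: np.random.Generator) -> tuple:
        self._shape = input_shape
        return (int(np.prod(input_shape)),)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._batch = x.shape[0]
        return x.reshape(self._batch, -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape((self._batch,) + self._shape)


class Dense(Layer):
    def __init__(self, units: int, activation: str = "linear") -> None:
        super().__init__()
        self.units = units
        self.activation = activation
        self.act, self.act_grad = _ACTIVATIONS[activation]

    def build(self, input_shape: tuple, rng: np.random.Generator) -> tuple:
        (D,) = input_shape
        self.W = _glorot(rng, D, self.units)
        self.b = np.zeros(self.units)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [self.W, self.b]
        self.grads = [self.dW, self.db]
        return (self.units,)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        self._z = x @ self.W + self.b
        return self.act(self._z)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        dz = grad * self.act_grad(self._z)
        self.dW[...] = self._x.T @ dz
        self.db[...] = dz.sum(axis=0)
        return dz @ self.W.T


# ------------------------------------------------------------------ losses

class BinaryCrossEntropy:
    """Sigmoid + BCE fused on logits. Targets: (B,) floats in {0, 1}."""

    name = "binary_crossentropy"

    def loss_and_grad(self, logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
        z = logits.ravel()
        # log(1 + exp(-|z|)) + max(z, 0) - z*y  (stable form)
        with np.errstate(invalid="ignore"):
            loss = float(np.mean(np.logaddexp(0.0, -np.abs(z)) + np.maximum(z, 0.0) - z * y))
        p = sigmoid(z)
        grad = ((p - y) / z.size).reshape(logits.shape)
        return loss, grad

    def predict(self, logits: np.ndarray) -> np.ndarray:
        return sigmoid(logits.ravel())


class CategoricalCrossEntropy:
    """Softmax + CCE fused on logits. Targets: (B, K) one-hot."""

    name = "categorical_crossentropy"

    def loss_and_grad(self, logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
        p = softmax(logits)
        eps = 1e-12
        loss = float(-np.mean(np.sum(y * np.log(p + eps), axis=1)))
        grad = (p - y) / logits.shape[0]
        return loss, grad

    def predict(self, logits: np.ndarray) -> np.ndarray:
        return softmax(logits)


# ------------------------------------------------------------------ optimizers

class _Optimizer:
    def __init__(self, learning_rate: float, clipnorm: float | None = 5.0) -> None:
        self.lr = learning_rate
        self.clipnorm = clipnorm
        self._state: dict[int, dict] = {}

    def _clip(self, grads: list[np.ndarray]) -> None:
        if self.clipnorm is None:
            return
        total = np.sqrt(sum(float(np.sum(g**2)) for g in grads))
        if total > self.clipnorm:
            scale = self.clipnorm / (total + 1e-12)
            for g in grads:
                g *= scale

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self._clip(grads)
        for idx, (p, g) in enumerate(zip(params, grads)):
            self._update(idx, p, g)

    def _update(self, idx: int, p: np.ndarray, g: np.ndarray) -> None:
        raise NotImplementedError


class RMSProp(_Optimizer):
    def __init__(self, learning_rate: float = 0.001, rho: float = 0.9, eps: float = 1e-7,
                 clipnorm: float | None = 5.0) -> None:
        super().__init__(learning_rate, clipnorm)
        self.rho = rho
        self.eps = eps

    def _update(self, idx: int, p: np.ndarray, g: np.ndarray) -> None:
        s = self._state.setdefault(idx, {"v": np.zeros_like(p)})
        s["v"] = self.rho * s["v"] + (1 - self.rho) * g**2
        p -= self.lr * g / (np.sqrt(s["v"]) + self.eps)


class Adam(_Optimizer):
    def __init__(self, learning_rate: float = 0.001, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7, clipnorm: float | None = 5.0) -> None:
        super().__init__(learning_rate, clipnorm)
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps

    def _update(self, idx: int, p: np.ndarray, g: np.ndarray) -> None:
        s = self._state.setdefault(idx, {"m": np.zeros_like(p), "v": np.zeros_like(p), "t": 0})
        s["t"] += 1
        s["m"] = self.beta1 * s["m"] + (1 - self.beta1) * g
        s["v"] = self.beta2 * s["v"] + (1 - self.beta2) * g**2
        mhat = s["m"] / (1 - self.beta1 ** s["t"])
        vhat = s["v"] / (1 - self.beta2 ** s["t"])
        p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


OPTIMIZERS = {"rmsprop": RMSProp, "adam": Adam}
LOSSES = {"binary_crossentropy": BinaryCrossEntropy, "categorical_crossentropy": CategoricalCrossEntropy}


# ------------------------------------------------------------------ model

@dataclass
class History:
    """Per-epoch training curves."""

    epoch: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)


class Sequential:
    """An ordered layer stack with a fused-logit output loss."""

    def __init__(self, layers: list[Layer], loss: str) -> None:
        self.layers = layers
        self.loss = LOSSES[loss]()
        self.built = False

    def build(self, input_shape: tuple, seed: int) -> "Sequential":
        rng = np.random.default_rng(seed)
        shape = input_shape
        for layer in self.layers:
            shape = layer.build(shape, rng)
        self.output_shape = shape
        self.built = True
        return self

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        outs = [self.loss.predict(self.forward(x[i : i + batch_size], training=False))
                for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0)

    def _accuracy(self, proba: np.ndarray, y: np.ndarray) -> float:
        if proba.ndim == 1:
            return float(np.mean((proba >= 0.5).astype(float) == y))
        return float(np.mean(proba.argmax(axis=1) == y.argmax(axis=1)))

    def evaluate_loss(self, x: np.ndarray, y: np.ndarray, batch_size: int = 256) -> float:
        total, n = 0.0, 0
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i : i + batch_size], training=False)
            loss, _ = self.loss.loss_and_grad(logits, y[i : i + batch_size])
            total += loss * len(x[i : i + batch_size])
            n += len(x[i : i + batch_size])
        return total / max(n, 1)

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int,
        batch_size: int,
        optimizer: _Optimizer,
        validation_data: tuple[np.ndarray, np.ndarray] | None = None,
        seed: int = 0,
        verbose: bool = False,
    ) -> History:
        if not self.built:
            raise RuntimeError("model must be built before fitting")
        rng = np.random.default_rng(seed)
        hist = History()
        n = len(x)
        for epoch in range(1, epochs + 1):
            order = rng.permutation(n)
            epoch_loss, seen, correct = 0.0, 0, 0.0
            for bidx, start in enumerate(range(0, n, batch_size)):
                sel = order[start : start + batch_size]
                xb, yb = x[sel], y[sel]
                logits = self.forward(xb, training=True)
                loss, dlogits = self.loss.loss_and_grad(logits, yb)
                if not np.isfinite(loss):
                    raise TrainingDivergedError(epoch, bidx)
                self.backward(dlogits)
                optimizer.step(self.params, self.grads)
                epoch_loss += loss * len(sel)
                seen += len(sel)
                correct += self._accuracy(self.loss.predict(logits), yb) * len(sel)
            hist.epoch.append(epoch)
            hist.train_loss.append(epoch_loss / seen)
            hist.train_accuracy.append(correct / seen)
            if validation_data is not None:
                xv, yv = validation_data
                hist.val_loss.append(self.evaluate_loss(xv, yv))
                hist.val_accuracy.append(self._accuracy(self.predict_proba(xv), yv))
            if verbose:
                msg = f"epoch {epoch}/{epochs} loss={hist.train_loss[-1]:.4f} acc={hist.train_accuracy[-1]:.4f}"
                if validation_data is not None:
                    msg += f" val_loss={hist.val_loss[-1]:.4f} val_acc={hist.val_accuracy[-1]:.4f}"
                print(msg)
        return hist
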