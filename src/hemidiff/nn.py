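"""Minimal CNN building blocks on numpy with explicit backpropagation.

Layers operate on float32 arrays shaped (batch, time, channel, maps).
Convolutions are valid (no padding), stride 1, realised as an im2col matrix
product; max pooling floor-divides non-divisible extents by truncating the
trailing remainder.  Each layer caches what its backward pass needs, so a
layer instance handles one forward/backward pair at a time; shared-weight
branches therefore use distinct layer instances bound to the same parameter
arrays (see :func:`Conv2D.sharing_copy` etc.).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D", "ReLU", "MaxPool", "BatchNorm", "SpatialDropout",
    "Flatten", "Dense", "Adam", "softmax", "cross_entropy",
]


class Layer:
    """Base: ``params()`` yields (name, value, grad) parameter triples."""

    def params(self):
        return []

    def sharing_copy(self):
        """A new instance sharing parameter/grad arrays but not caches."""
        raise NotImplementedError

    def forward(self, x, train: bool):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(Layer):
    def __init__(self, kernel: tuple[int, int], in_maps: int, out_maps: int,
                 rng: np.random.Generator):
        kt, kc = kernel
        fan_in = kt * kc * in_maps
        self.kernel = kernel
        self.w = (rng.standard_normal((in_maps, kt, kc, out_maps))
                  * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(out_maps, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def sharing_copy(self):
        twin = Conv2D.__new__(Conv2D)
        twin.kernel = self.kernel
        twin.w, twin.b, twin.gw, twin.gb = self.w, self.b, self.gw, self.gb
        return twin

    def params(self):
        return [("w", self.w, self.gw), ("b", self.b, self.gb)]

    def forward(self, x, train: bool):
        kt, kc = self.kernel
        n, t, c, m = x.shape
        to, co = t - kt + 1, c - kc + 1
        if to <= 0 or co <= 0:
            raise ValueError(
                f"kernel {self.kernel} larger than input extent ({t}, {c})")
        win = np.lib.stride_tricks.sliding_window_view(x, (kt, kc), axis=(1, 2))
        # win: (n, to, co, m, kt, kc) -> columns (n*to*co, m*kt*kc)
        cols = np.ascontiguousarray(win).reshape(n * to * co, m * kt * kc)
        wmat = self.w.reshape(-1, self.w.shape[-1])
        out = cols @ wmat + self.b
        self._cache = (cols, x.shape, (to, co))
        return out.reshape(n, to, co, -1)

    def backward(self, grad):
        cols, x_shape, (to, co) = self._cache
        n, t, c, m = x_shape
        kt, kc = self.kernel
        g = grad.reshape(-1, grad.shape[-1])
        wmat = self.w.reshape(-1, self.w.shape[-1])
        self.gw += (cols.T @ g).reshape(self.w.shape)
        self.gb += g.sum(axis=0)
        dcols = (g @ wmat.T).reshape(n, to, co, m, kt, kc)
        dx = np.zeros(x_shape, dtype=grad.dtype)
        for i in range(kt):
            for j in range(kc):
                dx[:, i:i + to, j:j + co, :] += dcols[:, :, :, :, i, j]
        return dx


class ReLU(Layer):
    def sharing_copy(self):
        return ReLU()

    def forward(self, x, train: bool):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool(Layer):
    def __init__(self, pool: tuple[int, int]):
        self.pool = pool

    def sharing_copy(self):
        return MaxPool(self.pool)

    def forward(self, x, train: bool):
        pt, pc = self.pool
        n, t, c, m = x.shape
        to, co = t // pt, c // pc
        if to <= 0 or co <= 0:
            raise ValueError(f"pool {self.pool} larger than input ({t}, {c})")
        xt = x[:, :to * pt, :co * pc, :].reshape(n, to, pt, co, pc, m)
        out = xt.max(axis=(2, 4))
        mask = (xt == out[:, :, None, :, None, :])
        # split gradient across ties to conserve it exactly
        self._cache = (mask / mask.sum(axis=(2, 4), keepdims=True), x.shape)
        return out

    def backward(self, grad):
        mask, x_shape = self._cache
        n, to, pt, co, pc, m = mask.shape
        dx = np.zeros(x_shape, dtype=grad.dtype)
        dx[:, :to * pt, :co * pc, :] = (
            mask * grad[:, :, None, :, None, :]
        ).reshape(n, to * pt, co * pc, m)
        return dx


class BatchNorm(Layer):
    """Per-map batch normalisation over (batch, time, channel)."""

    def __init__(self, n_maps: int, momentum: float = 0.9, eps: float = 1e-5):
        self.momentum = momentum
        self.eps = eps
        self.gamma = np.ones(n_maps, dtype=np.float32)
        self.beta = np.zeros(n_maps, dtype=np.float32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n_maps, dtype=np.float32)
        self.running_var = np.ones(n_maps, dtype=np.float32)

    def sharing_copy(self):
        twin = BatchNorm.__new__(BatchNorm)
        for name in ("momentum", "eps", "gamma", "beta", "ggamma", "gbeta"):
            setattr(twin, name, getattr(self, name))
        # running stats are shared state as well
        twin.running_mean = self.running_mean
        twin.running_var = self.running_var
        return twin

    def params(self):
        return [("gamma", self.gamma, self.ggamma),
                ("beta", self.beta, self.gbeta)]

    def forward(self, x, train: bool):
        axes = (0, 1, 2)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean[:] = (self.momentum * self.running_mean
                                    + (1 - self.momentum) * mean)
            self.running_var[:] = (self.momentum * self.running_var
                                   + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv.astype(x.dtype), train)
        return self.gamma * xhat + self.beta

    def backward(self, grad):
        xhat, inv, train = self._cache
        axes = (0, 1, 2)
        self.ggamma += (grad * xhat).sum(axis=axes)
        self.gbeta += grad.sum(axis=axes)
        if not train:
            return grad * self.gamma * inv
        n = grad.shape[0] * grad.shape[1] * grad.shape[2]
        g = grad * self.gamma
        return (inv / n) * (n * g - g.sum(axis=axes)
                            - xhat * (g * xhat).sum(axis=axes))


class SpatialDropout(Layer):
    """Drops whole feature maps; inverted scaling keeps expectation fixed."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng

    def sharing_copy(self):
        return SpatialDropout(self.rate, self.rng)

    def forward(self, x, train: bool):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = (self.rng.random((x.shape[0], 1, 1, x.shape[3]))
                >= self.rate).astype(x.dtype)
        self._mask = keep / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def sharing_copy(self):
        return Flatten()

    def forward(self, x, train: bool):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = (rng.standard_normal((n_in, n_out))
                  * np.sqrt(2.0 / n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def sharing_copy(self):
        twin = Dense.__new__(Dense)
        twin.w, twin.b, twin.gw, twin.gb = self.w, self.b, self.gw, self.gb
        return twin

    def params(self):
        return [("w", self.w, self.gw), ("b", self.b, self.gb)]

    def forward(self, x, train: bool):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.gw += self._x.T @ grad
        self.gb += grad.sum(axis=0)
        return grad @ self.w.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, onehot: np.ndarray) -> float:
    eps = np.finfo(probs.dtype).tiny
    return float(-(onehot * np.log(probs + eps)).sum(axis=-1).mean())


class Adam:
    """Adaptive-moment gradient descent over a list of parameter triples."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for _, p, _ in self.params]
        self.v = [np.zeros_like(p) for _, p, _ in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for (name, p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)

    def zero_grad(self) -> None:
        for _, _, g in self.params:
            g[...] = 0.0
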