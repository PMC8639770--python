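"""Minimal numpy neural-network engine: layers, manual backprop, Adam.

Float32 throughout; convolution is im2col + matrix multiply.  Layers follow
the usual forward/backward contract: ``forward`` caches what ``backward``
needs, ``backward`` accumulates parameter gradients and returns the input
gradient.  Deterministic given the seeding of the initializers and the data
order (pure numpy, no threading-dependent reductions beyond BLAS).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Layer", "Conv2d", "BatchNorm2d", "ReLU", "MaxPool2d",
    "GlobalAvgPool", "Linear", "Sequential", "BasicBlock",
    "bce_with_logits", "sigmoid", "Adam", "cosine_lr",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=np.float64)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy from logits; returns (loss, dloss/dlogits).

    Uses the stable form max(z,0) - z*y + log(1 + exp(-|z|)).
    """
    z = np.asarray(logits, dtype=np.float64).ravel()
    y = np.asarray(targets, dtype=np.float64).ravel()
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    grad = (sigmoid(z) - y) / z.size
    dtype = logits.dtype if isinstance(logits, np.ndarray) else np.float32
    return loss, grad.astype(dtype)


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-trainable state (e.g. batch-norm running statistics)."""
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    N, C, H, W = x.shape
    Ho = (H + 2 * pad - kh) // stride + 1
    Wo = (W + 2 * pad - kw) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    s0, s1, s2, s3 = xp.strides
    win = np.lib.stride_tricks.as_strided(
        xp, (N, C, kh, kw, Ho, Wo), (s0, s1, s2, s3, s2 * stride, s3 * stride))
    cols = np.ascontiguousarray(win).reshape(N, C * kh * kw, Ho * Wo)
    return cols, Ho, Wo


def _col2im(dcols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    N, C, H, W = x_shape
    Ho = (H + 2 * pad - kh) // stride + 1
    Wo = (W + 2 * pad - kw) // stride + 1
    dxp = np.zeros((N, C, H + 2 * pad, W + 2 * pad), dtype=dcols.dtype)
    d = dcols.reshape(N, C, kh, kw, Ho, Wo)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += d[:, :, i, j]
    return dxp[:, :, pad:pad + H, pad:pad + W] if pad else dxp


class Conv2d(Layer):
    """2-D convolution (cross-correlation), no bias (batch norm follows)."""

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1, pad: int = 0,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, fan_in))
        self.W = Param(w)
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad

    def params(self):
        return [self.W]

    def forward(self, x, training):
        x = x.astype(self.W.value.dtype, copy=False)
        cols, Ho, Wo = _im2col(x, self.k, self.k, self.stride, self.pad)
        self._cols, self._xshape, self._HoWo = cols, x.shape, (Ho, Wo)
        out = np.einsum("of,nfl->nol", self.W.value, cols, optimize=True)
        return out.reshape(x.shape[0], self.cout, Ho, Wo)

    def backward(self, grad):
        N = grad.shape[0]
        g = grad.reshape(N, self.cout, -1).astype(np.float32, copy=False)
        self.W.grad += np.einsum("nol,nfl->of", g, self._cols, optimize=True)
        dcols = np.einsum("of,nol->nfl", self.W.value, g, optimize=True)
        return _col2im(dcols, self._xshape, self.k, self.k, self.stride, self.pad)


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c, dtype=np.float32))
        self.beta = Param(np.zeros(c, dtype=np.float32))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return [self.running_mean, self.running_var]

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._xhat, self._inv, self._training = xhat, inv, training
        self._m = x.shape[0] * x.shape[2] * x.shape[3]
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, grad):
        xhat, inv = self._xhat, self._inv
        self.gamma.grad += np.sum(grad * xhat, axis=(0, 2, 3))
        self.beta.grad += np.sum(grad, axis=(0, 2, 3))
        gh = grad * self.gamma.value[None, :, None, None]
        if not self._training:
            return gh * inv[None, :, None, None]
        m = self._m
        t1 = gh.sum(axis=(0, 2, 3))
        t2 = np.sum(gh * xhat, axis=(0, 2, 3))
        return (inv[None, :, None, None] / m) * (m * gh - t1[None, :, None, None]
                                                 - xhat * t2[None, :, None, None])


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0.0)


class MaxPool2d(Layer):
    def __init__(self, k: int = 3, stride: int = 2, pad: int = 1):
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x, training):
        # pad with -inf so padding never wins the max
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)),
                    constant_values=-np.inf) if self.pad else x
        N, C, H, W = xp.shape
        Ho = (H - self.k) // self.stride + 1
        Wo = (W - self.k) // self.stride + 1
        s0, s1, s2, s3 = xp.strides
        win = np.lib.stride_tricks.as_strided(
            xp, (N, C, self.k, self.k, Ho, Wo),
            (s0, s1, s2, s3, s2 * self.stride, s3 * self.stride))
        win = np.ascontiguousarray(win).reshape(N, C, self.k * self.k, Ho * Wo)
        self._arg = np.argmax(win, axis=2)
        self._xshape_in = x.shape
        self._HoWo = (Ho, Wo)
        out = np.take_along_axis(win, self._arg[:, :, None, :], axis=2)[:, :, 0, :]
        return out.reshape(N, C, Ho, Wo)

    def backward(self, grad):
        N, C, H, W = self._xshape_in
        Ho, Wo = self._HoWo
        g = grad.reshape(N, C, 1, Ho * Wo)
        dwin = np.zeros((N, C, self.k * self.k, Ho * Wo), dtype=grad.dtype)
        np.put_along_axis(dwin, self._arg[:, :, None, :], g, axis=2)
        dcols = dwin.reshape(N, C * self.k * self.k, Ho * Wo)
        return _col2im(dcols, (N, C, H, W), self.k, self.k, self.stride, self.pad)


class GlobalAvgPool(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        N, C, H, W = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (H * W)


class Linear(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / np.sqrt(cin)
        self.W = Param(rng.uniform(-bound, bound, size=(cout, cin)))
        self.b = Param(rng.uniform(-bound, bound, size=(cout,)))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training):
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, grad):
        self.W.grad += grad.T @ self._x
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def buffers(self):
        return [b for l in self.layers for b in l.buffers()]

    def forward(self, x, training):
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class BasicBlock(Layer):
    """Two 3x3 conv-BN pairs with an identity (or 1x1-projected) shortcut."""

    def __init__(self, cin: int, cout: int, stride: int, rng: np.random.Generator):
        self.conv1 = Conv2d(cin, cout, 3, stride, 1, rng)
        self.bn1 = BatchNorm2d(cout)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, 1, 1, rng)
        self.bn2 = BatchNorm2d(cout)
        self.relu2 = ReLU()
        self.down: Sequential | None = None
        if stride != 1 or cin != cout:
            self.down = Sequential(Conv2d(cin, cout, 1, stride, 0, rng), BatchNorm2d(cout))

    def _children(self):
        cs = [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2, self.relu2]
        if self.down is not None:
            cs.append(self.down)
        return cs

    def params(self):
        return [p for c in self._children() for p in c.params()]

    def buffers(self):
        return [b for c in self._children() for b in c.buffers()]

    def forward(self, x, training):
        out = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, training), training), training)
        out = self.bn2.forward(self.conv2.forward(out, training), training)
        sc = x if self.down is None else self.down.forward(x, training)
        return self.relu2.forward(out + sc, training)

    def backward(self, grad):
        g = self.relu2.backward(grad)
        g_main = self.bn2.backward(g)
        g_main = self.conv2.backward(g_main)
        g_main = self.relu1.backward(g_main)
        g_main = self.bn1.backward(g_main)
        g_main = self.conv1.backward(g_main)
        g_sc = g if self.down is None else self.down.backward(g)
        return g_main + g_sc


class Adam:
    """Adam optimizer over a parameter list; learning rate settable per step."""

    def __init__(self, params: list[Param], lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (p.grad * p.grad - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def cosine_lr(epoch: int, epochs: int, lr_init: float, lr_min: float = 0.0) -> float:
    """Cosine annealing over the run: lr_init at epoch 0, lr_min at the last
    epoch, monotone nonincreasing in between."""
    if epochs <= 1:
        return lr_init
    t = epoch / (epochs - 1)
    return lr_min + 0.5 * (lr_init - lr_min) * (1.0 + np.cos(np.pi * t))
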