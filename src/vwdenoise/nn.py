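"""Small NumPy convolutional-network engine.

Implements exactly the layers the denoising networks need — 2-D convolution,
2x2 transposed convolution, 2x2 max pooling, batch/instance normalisation and
(leaky) ReLU — with explicit ``forward``/``backward`` passes and an Adam
optimiser.  Convolutions are evaluated as matrix products on im2col buffers so
that the heavy lifting happens inside BLAS.

All computation is float32 by default and fully deterministic given a seeded
``numpy.random.Generator`` for the parameter initialisation.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    """A learnable tensor and its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


class Layer:
    """Base class: stateless layers may keep the defaults."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> dict:
        return {}

    def buffers(self) -> dict:
        """Non-learnable state that must survive serialisation."""
        return {}

    def load_buffers(self, state: dict) -> None:
        for k, v in self.buffers().items():
            v[...] = state[k]


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DTYPE)


class Conv2d(Layer):
    """2-D convolution (cross-correlation) with zero padding.

    Weight layout ``(c_out, c_in, k, k)``.  ``pad`` defaults to "same" for
    stride 1 and to ``(k - stride) // 2`` otherwise.
    """

    def __init__(self, c_in, c_out, k=3, stride=1, pad=None, bias=True, *, rng):
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        self.weight = Param(_he_init(rng, (c_out, c_in, k, k), c_in * k * k))
        self.bias = Param(np.zeros(c_out)) if bias else None
        self._cache = None

    def params(self):
        p = {"weight": self.weight}
        if self.bias is not None:
            p["bias"] = self.bias
        return p

    def forward(self, x, train=True):
        k, s, p = self.k, self.stride, self.pad
        N, C, H, W = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        Hp, Wp = xp.shape[2:]
        Ho, Wo = (Hp - k) // s + 1, (Wp - k) // s + 1
        cols = np.empty((C, k, k, N, Ho, Wo), dtype=DTYPE)
        for di in range(k):
            for dj in range(k):
                cols[:, di, dj] = xp[:, :, di : di + s * Ho : s, dj : dj + s * Wo : s].transpose(1, 0, 2, 3)
        cols = cols.reshape(C * k * k, N * Ho * Wo)
        y = self.weight.value.reshape(self.c_out, -1) @ cols
        if self.bias is not None:
            y += self.bias.value[:, None]
        y = y.reshape(self.c_out, N, Ho, Wo).transpose(1, 0, 2, 3)
        self._cache = (cols, x.shape, (Ho, Wo))
        return np.ascontiguousarray(y)

    def backward(self, dy):
        cols, xshape, (Ho, Wo) = self._cache
        k, s, p = self.k, self.stride, self.pad
        N, C, H, W = xshape
        dym = dy.transpose(1, 0, 2, 3).reshape(self.c_out, -1)
        self.weight.grad += (dym @ cols.T).reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += dym.sum(axis=1)
        dcols = (self.weight.value.reshape(self.c_out, -1).T @ dym).reshape(C, k, k, N, Ho, Wo)
        dxp = np.zeros((N, C, H + 2 * p, W + 2 * p), dtype=DTYPE)
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di : di + s * Ho : s, dj : dj + s * Wo : s] += dcols[:, di, dj].transpose(1, 0, 2, 3)
        return dxp[:, :, p : p + H, p : p + W] if p else dxp


class ConvTranspose2x2(Layer):
    """2x2 stride-2 transposed convolution (the U-Net up-sampler).

    Each input pixel paints one 2x2 output block, so the op is a tensordot
    followed by a block interleave; no overlap handling is needed.
    """

    def __init__(self, c_in, c_out, bias=True, *, rng):
        self.c_in, self.c_out = c_in, c_out
        self.weight = Param(_he_init(rng, (c_in, c_out, 2, 2), c_in * 4))
        self.bias = Param(np.zeros(c_out)) if bias else None
        self._x = None

    def params(self):
        p = {"weight": self.weight}
        if self.bias is not None:
            p["bias"] = self.bias
        return p

    def forward(self, x, train=True):
        N, C, H, W = x.shape
        t = np.tensordot(x, self.weight.value, axes=([1], [0]))  # N,H,W,cout,2,2
        y = t.transpose(0, 3, 1, 4, 2, 5).reshape(N, self.c_out, 2 * H, 2 * W)
        if self.bias is not None:
            y += self.bias.value[None, :, None, None]
        self._x = x
        return np.ascontiguousarray(y)

    def backward(self, dy):
        x = self._x
        N, C, H, W = x.shape
        dyt = dy.reshape(N, self.c_out, H, 2, W, 2).transpose(0, 2, 4, 1, 3, 5)  # N,H,W,cout,2,2
        self.weight.grad += np.tensordot(x, dyt, axes=([0, 2, 3], [0, 1, 2]))
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        dx = np.tensordot(dyt, self.weight.value, axes=([3, 4, 5], [1, 2, 3]))  # N,H,W,cin
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))


class MaxPool2x2(Layer):
    def __init__(self):
        self._cache = None

    def forward(self, x, train=True):
        N, C, H, W = x.shape
        xf = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H // 2, W // 2, 4)
        idx = xf.argmax(axis=-1)
        y = np.take_along_axis(xf, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape)
        return np.ascontiguousarray(y)

    def backward(self, dy):
        idx, (N, C, H, W) = self._cache
        dxf = np.zeros((N, C, H // 2, W // 2, 4), dtype=DTYPE)
        np.put_along_axis(dxf, idx[..., None], dy[..., None], axis=-1)
        return np.ascontiguousarray(
            dxf.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H, W)
        )


class BatchNorm2d(Layer):
    """Batch normalisation over (N, H, W), running statistics for inference."""

    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train)
        return (self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]).astype(DTYPE)

    def backward(self, dy):
        xhat, inv, train = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None] * inv[None, :, None, None]
        if not train:
            return (dy * g).astype(DTYPE)
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        s1 = dy.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dy * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (g * (dy - s1 / m - xhat * s2 / m)).astype(DTYPE)


class InstanceNorm2d(Layer):
    """Per-sample, per-channel normalisation over (H, W) with affine scale."""

    def __init__(self, c, eps=1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.eps = eps
        self._cache = None

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def forward(self, x, train=True):
        mean = x.mean(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(x.var(axis=(2, 3), keepdims=True) + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv)
        return (self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]).astype(DTYPE)

    def backward(self, dy):
        xhat, inv = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None] * inv
        m = dy.shape[2] * dy.shape[3]
        s1 = dy.sum(axis=(2, 3), keepdims=True)
        s2 = (dy * xhat).sum(axis=(2, 3), keepdims=True)
        return (g * (dy - s1 / m - xhat * s2 / m)).astype(DTYPE)


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(DTYPE)

    def backward(self, dy):
        return np.where(self._mask, dy, 0).astype(DTYPE)


class LeakyReLU(Layer):
    def __init__(self, slope=0.2):
        self.slope = slope

    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x).astype(DTYPE)

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy).astype(DTYPE)


class GlobalAvgPool(Layer):
    """Average over all spatial positions; output (N, C)."""

    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        N, C, H, W = self._shape
        return np.broadcast_to(dy[:, :, None, None] / (H * W), self._shape).astype(DTYPE)


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for k, p in layer.params().items():
                out[f"{i}.{k}"] = p
        return out

    def buffers(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for k, b in layer.buffers().items():
                out[f"{i}.{k}"] = b
        return out

    def load_buffers(self, state):
        for i, layer in enumerate(self.layers):
            sub = {k.split(".", 1)[1]: v for k, v in state.items() if k.startswith(f"{i}.")}
            if sub:
                layer.load_buffers(sub)


class Adam:
    """Adam with per-parameter first/second moment accumulators."""

    def __init__(self, params: dict, lr=0.002, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.t = 0

    def zero_grad(self):
        for p in self.params.values():
            p.grad[...] = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        c1 = 1 - b1 ** self.t
        c2 = 1 - b2 ** self.t
        for k, p in self.params.items():
            self.m[k] += (1 - b1) * (p.grad - self.m[k])
            self.v[k] += (1 - b2) * (p.grad * p.grad - self.v[k])
            p.value -= self.lr * (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + self.eps)


def mse_loss(pred, target):
    """Mean squared error and its gradient with respect to ``pred``."""
    d = pred - target
    return float(np.mean(d * d)), (2.0 / d.size) * d


def l1_loss(pred, target):
    """Mean absolute error and its gradient with respect to ``pred``."""
    d = pred - target
    return float(np.mean(np.abs(d))), np.sign(d).astype(DTYPE) / d.size


def state_dict(module: Layer) -> dict:
    """Flat name -> array mapping of all parameters and buffers."""
    out = {f"p:{k}": p.value for k, p in module.params().items()}
    out.update({f"b:{k}": np.asarray(v) for k, v in module.buffers().items()})
    return out


def load_state_dict(module: Layer, state: dict) -> None:
    for k, p in module.params().items():
        p.value[...] = state[f"p:{k}"]
    module.load_buffers({k: state[f"b:{k}"] for k in module.buffers()})
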