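"""Minimal numpy neural-network layers for 3D grid classification.

A deliberately small, dependency-free stack: 3D convolutions computed by
slice-offset accumulation (equivalent to im2col but without the memory
blow-up), ReLU, average pooling, residual blocks, global average pooling,
dense layers, softmax cross-entropy and Adam.  Everything is float32 and
deterministic given a seeded generator and a fixed BLAS thread count.

Tensors are channels-last: ``(batch, D, H, W, C)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import VoxsiteError


class Layer:
    params: list    # list of [value, grad] pairs
    buffers: list   # non-trainable state (e.g. batch-norm running stats)

    def __init__(self):
        self.params = []
        self.buffers = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3D(Layer):
    """Same-padded 3D convolution with odd kernel size."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 zero_init: bool = False):
        super().__init__()
        if k % 2 != 1:
            raise VoxsiteError("kernel size must be odd")
        self.k, self.c_in, self.c_out = k, c_in, c_out
        fan_in = k ** 3 * c_in
        scale = 0.0 if zero_init else np.sqrt(2.0 / fan_in)
        self.W = (rng.normal(0.0, 1.0, size=(k ** 3, c_in, c_out)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [[self.W, self.dW], [self.b, self.db]]
        self._offsets = [(a, b, c) for a in range(k) for b in range(k) for c in range(k)]

    def forward(self, x, train=False):
        p = self.k // 2
        B, D, H, Wd, _ = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))
        self._xp = xp if train else None
        self._shape = x.shape
        out = np.broadcast_to(self.b, (B, D, H, Wd, self.c_out)).copy()
        for o, (a, b, c) in enumerate(self._offsets):
            out += xp[:, a:a + D, b:b + H, c:c + Wd, :] @ self.W[o]
        return out

    def backward(self, dout):
        B, D, H, Wd, _ = self._shape
        p = self.k // 2
        dxp = np.zeros_like(self._xp)
        self.db += dout.sum(axis=(0, 1, 2, 3))
        for o, (a, b, c) in enumerate(self._offsets):
            x_slice = self._xp[:, a:a + D, b:b + H, c:c + Wd, :]
            self.dW[o] += np.tensordot(x_slice, dout, axes=([0, 1, 2, 3], [0, 1, 2, 3]))
            dxp[:, a:a + D, b:b + H, c:c + Wd, :] += dout @ self.W[o].T
        self._xp = None
        if p == 0:
            return dxp
        return dxp[:, p:-p, p:-p, p:-p, :]


class BatchNorm(Layer):
    """Channel-wise batch normalization (statistics over batch + spatial axes).

    Training batches use their own statistics and update the running
    mean/variance; inference uses the running statistics, so single-grid
    prediction is well defined.
    """

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.params = [[self.gamma, self.dgamma], [self.beta, self.dbeta]]
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.buffers = [self.running_mean, self.running_var]
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train=False):
        axes = tuple(range(x.ndim - 1))
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean[...] = (self.momentum * self.running_mean
                                      + (1 - self.momentum) * mu)
            self.running_var[...] = (self.momentum * self.running_var
                                     + (1 - self.momentum) * var)
            invstd = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mu) * invstd
            self._cache = (xhat, invstd.astype(np.float32))
            return (self.gamma * xhat + self.beta).astype(np.float32)
        return (self.gamma * (x - self.running_mean)
                / np.sqrt(self.running_var + self.eps) + self.beta).astype(np.float32)

    def backward(self, dout):
        xhat, invstd = self._cache
        axes = tuple(range(dout.ndim - 1))
        n = dout.size // dout.shape[-1]
        self.dgamma += (dout * xhat).sum(axis=axes)
        self.dbeta += dout.sum(axis=axes)
        dxhat = dout * self.gamma
        dx = (invstd / n) * (n * dxhat - dxhat.sum(axis=axes, keepdims=True)
                             - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True))
        self._cache = None
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0 if train else None
        return np.maximum(x, 0.0)

    def backward(self, dout):
        return dout * self._mask


class AvgPool3D(Layer):
    """Non-overlapping pooling by an integer factor dividing the spatial edge."""

    def __init__(self, factor: int):
        super().__init__()
        self.f = factor

    def forward(self, x, train=False):
        B, D, H, W, C = x.shape
        f = self.f
        if D % f or H % f or W % f:
            raise VoxsiteError(f"pool factor {f} does not divide grid edge {D}")
        self._shape = x.shape
        return x.reshape(B, D // f, f, H // f, f, W // f, f, C).mean(axis=(2, 4, 6))

    def backward(self, dout):
        B, D, H, W, C = self._shape
        f = self.f
        d = dout / f ** 3
        d = d[:, :, None, :, None, :, None, :]
        return np.broadcast_to(
            d, (B, D // f, f, H // f, f, W // f, f, C)).reshape(self._shape)


class GlobalAvgPool(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(1, 2, 3))

    def backward(self, dout):
        B, D, H, W, C = self._shape
        return np.broadcast_to(dout[:, None, None, None, :] / (D * H * W), self._shape).copy()


class Dense(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        super().__init__()
        scale = 0.0 if zero_init else np.sqrt(2.0 / c_in)
        self.W = (rng.normal(0.0, 1.0, size=(c_in, c_out)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [[self.W, self.dW], [self.b, self.db]]

    def forward(self, x, train=False):
        self._x = x if train else None
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW += self._x.T @ dout
        self.db += dout.sum(axis=0)
        return dout @ self.W.T


class ResidualBlock(Layer):
    """conv-relu-conv plus identity (or 1x1-projected) skip, then relu."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv3D(c_in, c_out, k, rng)
        self.bn1 = BatchNorm(c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv3D(c_out, c_out, k, rng)
        self.bn2 = BatchNorm(c_out)
        self.proj = Conv3D(c_in, c_out, 1, rng) if c_in != c_out else None
        self.relu2 = ReLU()
        for lay in (self.conv1, self.bn1, self.conv2, self.bn2, self.proj):
            if lay is not None:
                self.params.extend(lay.params)
                self.buffers.extend(lay.buffers)

    def forward(self, x, train=False):
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        h = self.bn2.forward(self.conv2.forward(h, train), train)
        skip = x if self.proj is None else self.proj.forward(x, train)
        return self.relu2.forward(h + skip, train)

    def backward(self, dout):
        d = self.relu2.backward(dout)
        dskip = d if self.proj is None else self.proj.backward(d)
        dh = self.bn2.backward(d)
        dh = self.conv2.backward(dh)
        dh = self.conv1.backward(self.bn1.backward(self.relu1.backward(dh)))
        return dh + dskip


class BottleneckBlock(Layer):
    """1-3-1 bottleneck residual block (the ResNet-50 building block)."""

    def __init__(self, c_in: int, c_mid: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv3D(c_in, c_mid, 1, rng)
        self.bn1 = BatchNorm(c_mid)
        self.conv2 = Conv3D(c_mid, c_mid, 3, rng)
        self.bn2 = BatchNorm(c_mid)
        self.conv3 = Conv3D(c_mid, c_out, 1, rng)
        self.bn3 = BatchNorm(c_out)
        self.r1, self.r2, self.r3 = ReLU(), ReLU(), ReLU()
        self.proj = Conv3D(c_in, c_out, 1, rng) if c_in != c_out else None
        for lay in (self.conv1, self.bn1, self.conv2, self.bn2, self.conv3,
                    self.bn3, self.proj):
            if lay is not None:
                self.params.extend(lay.params)
                self.buffers.extend(lay.buffers)

    def forward(self, x, train=False):
        h = self.r1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        h = self.r2.forward(self.bn2.forward(self.conv2.forward(h, train), train), train)
        h = self.bn3.forward(self.conv3.forward(h, train), train)
        skip = x if self.proj is None else self.proj.forward(x, train)
        return self.r3.forward(h + skip, train)

    def backward(self, dout):
        d = self.r3.backward(dout)
        dskip = d if self.proj is None else self.proj.backward(d)
        dh = self.conv3.backward(self.bn3.backward(d))
        dh = self.conv2.backward(self.bn2.backward(self.r2.backward(dh)))
        dh = self.conv1.backward(self.bn1.backward(self.r1.backward(dh)))
        return dh + dskip


class WithGlobalSummary(Layer):
    """Run a body network and append the input's global channel means.

    The concatenated output [body(x), mean(x over space)] gives the head
    direct access to overall channel composition while the convolutional
    body contributes geometry-sensitive features.
    """

    def __init__(self, body: "Sequential"):
        super().__init__()
        self.body = body
        self.params = body.params
        self.buffers = body.buffers

    def forward(self, x, train=False):
        self._shape = x.shape
        h = self.body.forward(x, train)
        g = x.mean(axis=(1, 2, 3))
        self._split = h.shape[-1]
        return np.concatenate([h, g], axis=-1)

    def backward(self, dout):
        B, D, H, W, C = self._shape
        dx = self.body.backward(dout[:, :self._split])
        dg = dout[:, self._split:] / (D * H * W)
        return dx + np.broadcast_to(dg[:, None, None, None, :], self._shape)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers
        for lay in layers:
            self.params.extend(lay.params)
            self.buffers.extend(lay.buffers)

    def forward(self, x, train=False):
        for lay in self.layers:
            x = lay.forward(x, train)
        return x

    def backward(self, dout):
        for lay in reversed(self.layers):
            dout = lay.backward(dout)
        return dout


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, y: np.ndarray,
                       sample_weight: np.ndarray | None = None
                       ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits.astype(np.float64))
    n = len(y)
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float)
    loss = float(-(w * np.log(p[np.arange(n), y] + 1e-12)).sum() / w.sum())
    d = p.copy()
    d[np.arange(n), y] -= 1.0
    d *= (w / w.sum())[:, None]
    return loss, d.astype(np.float32)


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8,
                 clip_norm: float | None = 5.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.clip_norm = clip_norm
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g ** 2).sum()) for _, g in self.params))
            if total > self.clip_norm:
                scale = self.clip_norm / total
                for _, g in self.params:
                    g *= scale
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
            g[...] = 0.0
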