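"""Trainable layers with explicit forward/backward passes.

Tensors are ``(C, D, H, W)`` float32 (no batch axis: desk-scale training
feeds one crop at a time).  Each layer caches what its backward pass needs
and exposes ``params()`` as ``(name, value, grad)`` triples for the
optimizer.
"""

from __future__ import annotations

import numpy as np

from .ops import conv3d_same, conv3d_same_grad_input, conv3d_same_grad_weight


class Layer:
    def params(self):
        return []

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv3d(Layer):
    """Stride-1 'same' 3-D convolution with He-initialised weights."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator, bias: bool = True):
        fan_in = cin * k**3
        self.weight = (rng.standard_normal((cout, cin, k, k, k)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.bias = np.zeros(cout, dtype=np.float32) if bias else None
        self.k = k
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias) if bias else None

    def params(self):
        out = [("weight", self.weight, self.dweight)]
        if self.bias is not None:
            out.append(("bias", self.bias, self.dbias))
        return out

    def forward(self, x):
        self._x = x
        return conv3d_same(x, self.weight, self.bias)

    def backward(self, dy):
        self.dweight += conv3d_same_grad_weight(self._x, dy, self.k)
        if self.bias is not None:
            self.dbias += dy.sum(axis=(1, 2, 3))
        return conv3d_same_grad_input(dy, self.weight)


class GroupNorm(Layer):
    """Batch-independent normalisation over channel groups.

    Chosen over batch statistics so single-crop training is stable.
    """

    def __init__(self, channels: int, groups: int = 8, eps: float = 1e-5):
        self.groups = min(groups, channels)
        while channels % self.groups:
            self.groups -= 1
        self.eps = eps
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)

    def params(self):
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]

    def forward(self, x):
        c = x.shape[0]
        g = self.groups
        xg = x.reshape(g, c // g, *x.shape[1:])
        mu = xg.mean(axis=(1, 2, 3, 4), keepdims=True)
        var = xg.var(axis=(1, 2, 3, 4), keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = ((xg - mu) * self._inv).reshape(x.shape).astype(np.float32)
        return self.gamma[:, None, None, None] * self._xhat + self.beta[:, None, None, None]

    def backward(self, dy):
        c = dy.shape[0]
        g = self.groups
        self.dgamma += (dy * self._xhat).sum(axis=(1, 2, 3))
        self.dbeta += dy.sum(axis=(1, 2, 3))
        dxhat = (dy * self.gamma[:, None, None, None]).reshape(g, c // g, *dy.shape[1:])
        xhat = self._xhat.reshape(g, c // g, *dy.shape[1:])
        n = xhat[0].size
        mean_d = dxhat.mean(axis=(1, 2, 3, 4), keepdims=True)
        mean_dx = (dxhat * xhat).mean(axis=(1, 2, 3, 4), keepdims=True)
        dx = self._inv * (dxhat - mean_d - xhat * mean_dx)
        return dx.reshape(dy.shape).astype(np.float32)


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0).astype(np.float32)


class MaxPool3d(Layer):
    """2x2x2 max pooling; input spatial dims must be even."""

    def forward(self, x):
        c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"max-pool input must have even spatial dims, got {x.shape}")
        win = x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).transpose(0, 1, 3, 5, 2, 4, 6)
        flat = win.reshape(c, d // 2, h // 2, w // 2, 8)
        self._arg = flat.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(flat, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        c, d, h, w = self._shape
        flat = np.zeros((c, d // 2, h // 2, w // 2, 8), dtype=np.float32)
        np.put_along_axis(flat, self._arg[..., None], dy[..., None], axis=-1)
        win = flat.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2).transpose(0, 1, 4, 2, 5, 3, 6)
        return win.reshape(c, d, h, w)


class ConvTranspose3d(Layer):
    """2x upsampling transposed convolution (kernel 2, stride 2)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        fan_in = cin
        self.weight = (rng.standard_normal((cin, cout, 2, 2, 2)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.bias = np.zeros(cout, dtype=np.float32)
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)

    def params(self):
        return [("weight", self.weight, self.dweight), ("bias", self.bias, self.dbias)]

    def forward(self, x):
        self._x = x
        cin, d, h, w = x.shape
        cout = self.weight.shape[1]
        y = np.einsum("cdhw,coijk->odihjwk", x, self.weight, optimize=True)
        y = y.reshape(cout, 2 * d, 2 * h, 2 * w).astype(np.float32)
        return y + self.bias[:, None, None, None]

    def backward(self, dy):
        cin, d, h, w = self._x.shape
        cout = self.weight.shape[1]
        blocks = dy.reshape(cout, d, 2, h, 2, w, 2)
        self.dbias += dy.sum(axis=(1, 2, 3))
        self.dweight += np.einsum("cdhw,odihjwk->coijk", self._x, blocks, optimize=True)
        return np.einsum("odihjwk,coijk->cdhw", blocks, self.weight, optimize=True).astype(np.float32)


class ResidualBlock(Layer):
    """Full pre-activation residual block: (GN-ReLU-Conv) x2 + skip.

    A 1x1x1 projection carries the skip when the channel count changes.
    """

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        self.gn1 = GroupNorm(cin)
        self.relu1 = ReLU()
        self.conv1 = Conv3d(cin, cout, k, rng)
        self.gn2 = GroupNorm(cout)
        self.relu2 = ReLU()
        self.conv2 = Conv3d(cout, cout, k, rng)
        self.proj = Conv3d(cin, cout, 1, rng, bias=False) if cin != cout else None

    def sublayers(self):
        layers = [self.gn1, self.relu1, self.conv1, self.gn2, self.relu2, self.conv2]
        if self.proj is not None:
            layers.append(self.proj)
        return layers

    def params(self):
        out = []
        for i, l in enumerate(self.sublayers()):
            out.extend((f"{i}.{n}", v, g) for n, v, g in l.params())
        return out

    def forward(self, x):
        h = self.conv1.forward(self.relu1.forward(self.gn1.forward(x)))
        h = self.conv2.forward(self.relu2.forward(self.gn2.forward(h)))
        skip = x if self.proj is None else self.proj.forward(x)
        return h + skip

    def backward(self, dy):
        dskip = dy if self.proj is None else self.proj.backward(dy)
        dh = self.gn1.backward(self.relu1.backward(self.conv1.backward(
            self.gn2.backward(self.relu2.backward(self.conv2.backward(dy)))
        )))
        return dh + dskip
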