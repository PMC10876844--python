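"""Minimal numpy layers with explicit forward/backward passes.

The classifier at the core of the package is small (three residual blocks,
tens of channels, 32-96 voxels per side), so the layers are written directly
in numpy: depthwise (grouped, groups = channels) 3D convolution as a sum of
27 shifted slice products, pointwise (1x1x1) convolution as an einsum, a
shared-slope PReLU, and a dense head. Every layer caches what its backward
pass needs; gradients are verified against finite differences in the test
suite.

Array convention: activations are (B, C, D, H, W).
"""

from __future__ import annotations

from itertools import product

import numpy as np

__all__ = [
    "Param",
    "DepthwiseConv3d",
    "PointwiseConv3d",
    "PReLU",
    "Linear",
    "SeparableConv3d",
    "ResidualBlock",
    "Adam",
    "softmax",
    "cross_entropy",
]


class Param:
    """A trainable array with its gradient accumulator."""

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self):
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def n_params(self) -> int:
        return sum(p.value.size for p in self.params())


class DepthwiseConv3d(Layer):
    """Channel-wise KxKxK convolution (groups = channels), 'same' zero padding.

    With stride 2 on an even side D the output side is D/2.
    """

    def __init__(self, channels: int, kernel: int, stride: int, rng: np.random.Generator):
        if channels < 1 or kernel < 1 or kernel % 2 == 0:
            raise ValueError("channels >= 1 and odd kernel required")
        if stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        self.channels = channels
        self.kernel = kernel
        self.stride = stride
        fan_in = kernel**3
        bound = np.sqrt(2.0 / fan_in)
        self.weight = Param(rng.normal(0.0, bound, size=(channels, kernel, kernel, kernel)))
        self.bias = Param(np.zeros(channels))
        self._cache = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        K, s = self.kernel, self.stride
        p = K // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        out_sp = tuple((d + 2 * p - K) // s + 1 for d in x.shape[2:])
        out = np.zeros(x.shape[:2] + out_sp)
        w = self.weight.value
        for i, j, l in product(range(K), repeat=3):
            sl = xp[
                :,
                :,
                i : i + s * out_sp[0] : s,
                j : j + s * out_sp[1] : s,
                l : l + s * out_sp[2] : s,
            ]
            out += w[:, i, j, l][None, :, None, None, None] * sl
        out += self.bias.value[None, :, None, None, None]
        self._cache = (xp, x.shape, out_sp)
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xp, x_shape, out_sp = self._cache
        K, s = self.kernel, self.stride
        p = K // 2
        gxp = np.zeros_like(xp)
        w = self.weight.value
        for i, j, l in product(range(K), repeat=3):
            sl = (
                slice(None),
                slice(None),
                slice(i, i + s * out_sp[0], s),
                slice(j, j + s * out_sp[1], s),
                slice(l, l + s * out_sp[2], s),
            )
            self.weight.grad[:, i, j, l] += np.einsum("bcdhw,bcdhw->c", xp[sl], gout)
            gxp[sl] += w[:, i, j, l][None, :, None, None, None] * gout
        self.bias.grad += gout.sum(axis=(0, 2, 3, 4))
        if p == 0:
            return gxp
        return gxp[:, :, p:-p, p:-p, p:-p]


class PointwiseConv3d(Layer):
    """1x1x1 convolution mixing channels; optional spatial subsampling stride."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        rng: np.random.Generator,
        stride: int = 1,
        bias: bool = True,
    ):
        if in_channels < 1 or out_channels < 1:
            raise ValueError("channel counts must be positive")
        self.stride = stride
        bound = np.sqrt(2.0 / in_channels)
        self.weight = Param(rng.normal(0.0, bound, size=(out_channels, in_channels)))
        self.bias = Param(np.zeros(out_channels)) if bias else None
        self._cache = None

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray) -> np.ndarray:
        s = self.stride
        xs = x[:, :, ::s, ::s, ::s] if s > 1 else x
        out = np.einsum("bcdhw,oc->bodhw", xs, self.weight.value)
        if self.bias is not None:
            out += self.bias.value[None, :, None, None, None]
        self._cache = (xs, x.shape)
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xs, x_shape = self._cache
        s = self.stride
        self.weight.grad += np.einsum("bodhw,bcdhw->oc", gout, xs)
        if self.bias is not None:
            self.bias.grad += gout.sum(axis=(0, 2, 3, 4))
        gxs = np.einsum("bodhw,oc->bcdhw", gout, self.weight.value)
        if s == 1:
            return gxs
        gx = np.zeros(x_shape)
        gx[:, :, ::s, ::s, ::s] = gxs
        return gx


class PReLU(Layer):
    """Rectifier with one learnable negative-part slope (shared across channels)."""

    def __init__(self, init_slope: float = 0.25):
        self.slope = Param(np.array(init_slope))
        self._cache = None

    def params(self):
        return [self.slope]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x
        return np.where(x > 0, x, self.slope.value * x)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        x = self._cache
        neg = x <= 0
        self.slope.grad += np.sum(gout * x * neg)
        return np.where(neg, self.slope.value * gout, gout)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        bound = np.sqrt(1.0 / in_features)
        self.weight = Param(rng.normal(0.0, bound, size=(out_features, in_features)))
        self.bias = Param(np.zeros(out_features))
        self._cache = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, weight=None, bias=None) -> np.ndarray:
        """Affine map; ``weight``/``bias`` may override the stored parameters
        (used when the head is sampled stochastically)."""
        w = self.weight.value if weight is None else weight
        b = self.bias.value if bias is None else bias
        self._cache = (x, w)
        return x @ w.T + b

    def backward(self, gout: np.ndarray) -> np.ndarray:
        x, w = self._cache
        self.weight.grad += gout.T @ x
        self.bias.grad += gout.sum(axis=0)
        return gout @ w


class SeparableConv3d(Layer):
    """Depthwise KxKxK convolution followed by a pointwise channel mix.

    Weight parameters (excluding biases) number C*K^3 + C*O instead of the
    full convolution's C*O*K^3.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int,
        rng: np.random.Generator,
    ):
        self.depthwise = DepthwiseConv3d(in_channels, kernel, stride, rng)
        self.pointwise = PointwiseConv3d(in_channels, out_channels, rng)

    def params(self):
        return self.depthwise.params() + self.pointwise.params()

    def forward(self, x):
        return self.pointwise.forward(self.depthwise.forward(x))

    def backward(self, gout):
        return self.depthwise.backward(self.pointwise.backward(gout))


class ResidualBlock(Layer):
    """Two separable convolutions with PReLU, plus a shortcut.

    The first separable convolution carries the stride; when the stride or
    the channel count changes, the shortcut is a strided pointwise
    projection (no bias), otherwise the identity.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int,
        rng: np.random.Generator,
    ):
        self.sep1 = SeparableConv3d(in_channels, out_channels, kernel, stride, rng)
        self.act1 = PReLU()
        self.sep2 = SeparableConv3d(out_channels, out_channels, kernel, 1, rng)
        self.act2 = PReLU()
        if stride != 1 or in_channels != out_channels:
            self.proj = PointwiseConv3d(in_channels, out_channels, rng, stride=stride, bias=False)
        else:
            self.proj = None

    def params(self):
        ps = self.sep1.params() + [self.act1.slope] + self.sep2.params() + [self.act2.slope]
        if self.proj is not None:
            ps += self.proj.params()
        return ps

    def forward(self, x):
        main = self.act2.forward(self.sep2.forward(self.act1.forward(self.sep1.forward(x))))
        short = x if self.proj is None else self.proj.forward(x)
        return main + short

    def backward(self, gout):
        gshort = gout if self.proj is None else self.proj.backward(gout)
        gmain = self.sep1.backward(
            self.act1.backward(self.sep2.backward(self.act2.backward(gout)))
        )
        return gmain + gshort


class Adam:
    """Adam optimiser (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: list[Param], lr: float = 3e-4):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    probs = softmax(logits)
    n = len(labels)
    eps = 1e-12
    loss = -np.mean(np.log(probs[np.arange(n), labels] + eps))
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n
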