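"""Neural-network building blocks on top of :mod:`mitseg.autodiff`.

Layers follow the channels-last convention: images and feature maps are
(B, H, W, C) arrays, token sequences are (B, N, C).  Convolutions are
expressed as compositions of padding, strided slicing and matrix
multiplication, so every layer is differentiable through the autodiff tape
without any dedicated convolution kernels.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, matmul, pad2d

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "LayerNorm",
    "Conv2d",
    "DepthwiseConv2d",
    "Dropout",
    "Adam",
    "conv_output_size",
]


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with recursive parameter discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield key, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{key}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def train(self, mode: bool = True):
        self.training = mode
        for value in vars(self).values():
            if isinstance(value, Module):
                value.train(mode)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = sorted(set(own) - set(state))
        unexpected = sorted(set(state) - set(own))
        if missing or unexpected:
            raise KeyError(
                f"checkpoint mismatch: missing={missing}, unexpected={unexpected}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


def _trunc_normal(rng: np.random.Generator, shape, std: float = 0.02):
    # resample outside +-2 std (transformer-standard truncated init)
    x = rng.standard_normal(shape) * std
    return np.clip(x, -2 * std, 2 * std).astype(np.float32)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.in_dim, self.out_dim = in_dim, out_dim
        self.weight = Parameter(_trunc_normal(rng, (in_dim, out_dim)))
        self.bias = Parameter(np.zeros(out_dim, dtype=np.float32)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = matmul(x, self.weight)
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        self.eps = float(eps)
        self.weight = Parameter(np.ones(dim, dtype=np.float32))
        self.bias = Parameter(np.zeros(dim, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        from .autodiff import layer_norm
        return layer_norm(x, self.weight, self.bias, self.eps)


def conv_output_size(n: int, k: int, s: int, p: int) -> int:
    return (n + 2 * p - k) // s + 1


def _unfold(x: Tensor, k: int, s: int, p: int) -> Tensor:
    """im2col on a (B, H, W, C) tensor -> (B, Ho, Wo, k*k*C)."""
    B, H, W, C = x.shape
    Ho = conv_output_size(H, k, s, p)
    Wo = conv_output_size(W, k, s, p)
    if Ho < 1 or Wo < 1:
        raise ValueError("input too small for merge")
    if p > 0:
        x = pad2d(x, (p, p), (p, p))
    patches = []
    for dy in range(k):
        for dx in range(k):
            patches.append(x[:, dy:dy + s * Ho:s, dx:dx + s * Wo:s, :])
    return concat(patches, axis=3)


class Conv2d(Module):
    """2-D convolution, channels-last, stored as an unfolded weight matrix."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 padding: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.padding = kernel, stride, padding
        fan_in = kernel * kernel * in_ch
        std = float(np.sqrt(2.0 / fan_in))
        w = (rng.standard_normal((fan_in, out_ch)) * std).astype(np.float32)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        cols = _unfold(x, self.kernel, self.stride, self.padding)
        y = matmul(cols, self.weight)
        if self.bias is not None:
            y = y + self.bias
        return y


class DepthwiseConv2d(Module):
    """3x3 (or kxk) depthwise convolution, stride 1, 'same' padding."""

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        assert kernel % 2 == 1
        self.channels, self.kernel = channels, kernel
        fan_in = kernel * kernel
        std = float(np.sqrt(2.0 / fan_in))
        w = (rng.standard_normal((kernel * kernel, channels)) * std).astype(np.float32)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(channels, dtype=np.float32)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        k = self.kernel
        p = k // 2
        B, H, W, C = x.shape
        xp = pad2d(x, (p, p), (p, p))
        y = None
        for i in range(k):
            for j in range(k):
                term = xp[:, i:i + H, j:j + W, :] * self.weight[i * k + j]
                y = term if y is None else y + term
        if self.bias is not None:
            y = y + self.bias
        return y


class Dropout(Module):
    """Inverted dropout; identity in eval mode.  Seeded via the rng passed
    at construction so training runs are reproducible."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = float(rate)
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * Tensor(mask)


class Adam:
    """Adam optimizer (the configuration used for training the segmenter)."""

    def __init__(self, params, lr: float = 6e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = float(eps)
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
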