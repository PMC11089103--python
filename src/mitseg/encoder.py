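"""Hierarchical Mix-Transformer (MiT) encoder.

The encoder turns an H x W x 3 image into a four-level feature pyramid at
1/4, 1/8, 1/16 and 1/32 of the input resolution with channel widths
C1 < C2 < C3 < C4.  Each stage is: overlapped patch merging (a strided
convolution with kernel K >= stride S and padding P, followed by layer
normalization of the token embeddings), a stack of transformer blocks, and a
final layer norm.

The transformer block uses spatial-reduction attention (SRA): before the
key/value projections, the token grid is reshaped so that each R x R window
becomes one token of R*R*C features and linearly projected back to C (then
layer-normalized), shortening the K/V sequence by R**2 and cutting attention
cost from O(N^2) to O(N^2/R^2).  The feed-forward is a Mix-FFN — an MLP with
an embedded 3x3 depthwise convolution whose zero padding leaks enough
positional information that no explicit positional encoding is needed, so
the encoder accepts any admissible input size without interpolating a
learned embedding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, gelu, matmul, softmax
from .layers import (Conv2d, DepthwiseConv2d, Dropout, LayerNorm, Linear,
                     Module, conv_output_size)
from .model_config import ModelSpec

__all__ = [
    "FeatureMap", "FeaturePyramid", "MiTEncoder",
    "OverlapPatchEmbed", "EfficientSelfAttention", "MixFFN", "TransformerBlock",
    "encode", "overlapped_patch_merge",
]


@dataclass
class FeatureMap:
    """One pyramid level: (H_i, W_i, C_i) activations for a single image."""
    values: np.ndarray
    stage_index: int

    def __post_init__(self):
        if self.values.ndim != 3:
            raise ValueError("FeatureMap values must be (H, W, C)")
        if not 1 <= self.stage_index <= 4:
            raise ValueError("stage_index must be in 1..4")


@dataclass
class FeaturePyramid:
    """The four multi-scale encoder outputs F1..F4."""
    levels: list[FeatureMap]

    def __post_init__(self):
        if len(self.levels) != 4:
            raise ValueError("pyramid must have exactly 4 levels")
        shapes = [lv.values.shape for lv in self.levels]
        for (h1, w1, c1), (h2, w2, c2) in zip(shapes, shapes[1:]):
            if not (h2 < h1 and w2 < w1):
                raise ValueError("pyramid spatial sizes must strictly decrease")
            if not c2 > c1:
                raise ValueError("pyramid channel widths must strictly increase")

    @property
    def shapes(self):
        return [lv.values.shape for lv in self.levels]


class OverlapPatchEmbed(Module):
    """Overlapped patch merging: strided KxK convolution + token layer norm."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 padding: int, eps: float, rng: np.random.Generator):
        super().__init__()
        if kernel < stride:
            raise ValueError("kernel must be >= stride for overlapping patches")
        self.proj = Conv2d(in_ch, out_ch, kernel, stride, padding, rng)
        self.norm = LayerNorm(out_ch, eps)

    def __call__(self, x: Tensor) -> Tensor:
        return self.norm(self.proj(x))


class EfficientSelfAttention(Module):
    """Multi-head self-attention with spatial reduction of keys/values.

    Operates on a (B, H, W, C) grid.  With reduction ratio R > 1 the K/V
    sequence length is H*W/R**2; R must tile the grid exactly.
    """

    def __init__(self, dim: int, heads: int, sr_ratio: int, dropout: float,
                 eps: float, rng: np.random.Generator):
        super().__init__()
        if dim % heads != 0:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.dim, self.heads, self.sr_ratio = dim, heads, sr_ratio
        self.head_dim = dim // heads
        self.scale = 1.0 / float(np.sqrt(self.head_dim))
        self.q = Linear(dim, dim, rng)
        self.kv = Linear(dim, 2 * dim, rng)
        self.proj = Linear(dim, dim, rng)
        self.drop = Dropout(dropout, rng)
        if sr_ratio > 1:
            # Eq.-style reduction: reshape RxR windows to one R*R*C token,
            # project back to C (parameter-identical to a stride-R conv).
            self.sr = Linear(sr_ratio * sr_ratio * dim, dim, rng)
            self.sr_norm = LayerNorm(dim, eps)

    def _reduce(self, x: Tensor) -> Tensor:
        B, H, W, C = x.shape
        R = self.sr_ratio
        if H % R or W % R:
            raise ValueError(
                f"reduction ratio {R} does not tile a {H}x{W} token grid")
        x = x.reshape(B, H // R, R, W // R, R, C)
        x = x.transpose((0, 1, 3, 2, 4, 5)).reshape(B, (H // R) * (W // R), R * R * C)
        return self.sr_norm(self.sr(x))

    def __call__(self, x: Tensor) -> Tensor:
        B, H, W, C = x.shape
        N = H * W
        tokens = x.reshape(B, N, C)
        q = self.q(tokens)
        kv_in = self._reduce(x) if self.sr_ratio > 1 else tokens
        kv = self.kv(kv_in)
        M = kv.shape[1]
        h, d = self.heads, self.head_dim
        q = q.reshape(B, N, h, d).transpose((0, 2, 1, 3))
        k = kv[:, :, :C].reshape(B, M, h, d).transpose((0, 2, 3, 1))
        v = kv[:, :, C:].reshape(B, M, h, d).transpose((0, 2, 1, 3))
        attn = softmax(matmul(q, k) * self.scale, axis=-1)
        out = matmul(attn, v)  # (B, h, N, d)
        out = out.transpose((0, 2, 1, 3)).reshape(B, N, C)
        out = self.drop(self.proj(out))
        return out.reshape(B, H, W, C)


class MixFFN(Module):
    """MLP(GELU(DWConv3x3(MLP(x)))) with hidden width mlp_ratio * C."""

    def __init__(self, dim: int, mlp_ratio: int, dropout: float,
                 rng: np.random.Generator):
        super().__init__()
        hidden = dim * mlp_ratio
        self.fc1 = Linear(dim, hidden, rng)
        self.dwconv = DepthwiseConv2d(hidden, 3, rng)
        self.fc2 = Linear(hidden, dim, rng)
        self.drop = Dropout(dropout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        # x is (B, H, W, C); the depthwise conv needs the grid layout.
        y = self.fc1(x)
        y = self.dwconv(y)
        y = gelu(y)
        y = self.drop(y)
        y = self.fc2(y)
        return self.drop(y)


class TransformerBlock(Module):
    def __init__(self, dim: int, heads: int, sr_ratio: int, mlp_ratio: int,
                 dropout: float, eps: float, rng: np.random.Generator):
        super().__init__()
        self.norm1 = LayerNorm(dim, eps)
        self.attn = EfficientSelfAttention(dim, heads, sr_ratio, dropout, eps, rng)
        self.norm2 = LayerNorm(dim, eps)
        self.ffn = MixFFN(dim, mlp_ratio, dropout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        x = x + self.ffn(self.norm2(x))
        return x


class MiTEncoder(Module):
    """Four-stage hierarchical encoder defined by a :class:`ModelSpec`."""

    MIN_INPUT = 32

    def __init__(self, spec: ModelSpec, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.spec = spec
        self.stages = []
        in_ch = 3
        for i in range(4):
            embed = OverlapPatchEmbed(
                in_ch, spec.hidden_dims[i], spec.merge_kernels[i],
                spec.merge_strides[i], spec.merge_paddings[i],
                spec.layer_norm_eps, rng)
            blocks = [
                TransformerBlock(spec.hidden_dims[i], spec.attention_heads[i],
                                 spec.sr_ratios[i], spec.mlp_ratio,
                                 spec.dropout, spec.layer_norm_eps, rng)
                for _ in range(spec.depths[i])
            ]
            norm = LayerNorm(spec.hidden_dims[i], spec.layer_norm_eps)
            self.stages.append([embed, blocks, norm])
            in_ch = spec.hidden_dims[i]

    def named_parameters(self, prefix: str = ""):
        for i, (embed, blocks, norm) in enumerate(self.stages):
            yield from embed.named_parameters(f"{prefix}stage{i + 1}.embed.")
            for j, blk in enumerate(blocks):
                yield from blk.named_parameters(f"{prefix}stage{i + 1}.block{j}.")
            yield from norm.named_parameters(f"{prefix}stage{i + 1}.norm.")

    def train(self, mode: bool = True):
        self.training = mode
        for embed, blocks, norm in self.stages:
            embed.train(mode)
            for blk in blocks:
                blk.train(mode)
            norm.train(mode)
        return self

    def __call__(self, x: Tensor) -> list[Tensor]:
        B, H, W, C = x.shape
        if H < self.MIN_INPUT or W < self.MIN_INPUT:
            raise ValueError(
                f"input {H}x{W} smaller than minimum {self.MIN_INPUT}")
        features = []
        for embed, blocks, norm in self.stages:
            x = embed(x)
            for blk in blocks:
                x = blk(x)
            x = norm(x)
            features.append(x)
        return features


# -- functional surface -------------------------------------------------------

def overlapped_patch_merge(x: np.ndarray, kernel: int, stride: int,
                           padding: int, out_channels: int,
                           seed: int = 0) -> FeatureMap:
    """Apply one (randomly initialized) overlapped patch merge to an array.

    ``x`` is (H, W, C); output spatial size is floor((n + 2P - K)/S) + 1 per
    axis.  Mainly a geometry/contract surface; the trained pipeline uses
    :class:`MiTEncoder`.
    """
    x = np.asarray(x, dtype=np.float32)
    if x.ndim != 3 or x.size == 0:
        raise ValueError("input must be a non-empty (H, W, C) array")
    Ho = conv_output_size(x.shape[0], kernel, stride, padding)
    Wo = conv_output_size(x.shape[1], kernel, stride, padding)
    if Ho < 1 or Wo < 1:
        raise ValueError("input too small for merge")
    rng = np.random.default_rng(seed)
    layer = OverlapPatchEmbed(x.shape[2], out_channels, kernel, stride,
                              padding, 1e-6, rng)
    out = layer(Tensor(x[None])).data[0]
    return FeatureMap(values=out, stage_index=1)


def encode(image: np.ndarray, spec: ModelSpec,
           encoder: MiTEncoder | None = None, seed: int = 0) -> FeaturePyramid:
    """Run the encoder on one RGB image and return its feature pyramid.

    ``image`` is (H, W, 3), any numeric dtype (uint8 is scaled to [-1, 1]).
    If ``encoder`` is None a freshly initialized one is built from ``spec``
    with the given seed; passing a trained encoder reuses its weights.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("image must be (H, W, 3)")
    if img.dtype == np.uint8:
        img = img.astype(np.float32) / 127.5 - 1.0
    img = img.astype(np.float32)
    if encoder is None:
        encoder = MiTEncoder(spec, np.random.default_rng(seed))
    encoder.eval()
    feats = encoder(Tensor(img[None]))
    return FeaturePyramid(levels=[
        FeatureMap(values=f.data[0], stage_index=i + 1)
        for i, f in enumerate(feats)
    ])
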