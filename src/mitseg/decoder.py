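"""Lightweight all-MLP decoder fusing the feature pyramid into class logits.

Each pyramid level F_i is linearly mapped from C_i to a unified width C,
bilinearly upsampled to the stage-1 (H/4 x W/4) grid, concatenated (4C
channels), fused back to C by a linear layer, and projected to one logit per
class.  Upsampling uses half-pixel-centre bilinear interpolation
(align_corners disabled), expressed as multiplication with fixed
interpolation matrices so it is differentiable through the autodiff tape.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .autodiff import Tensor, concat, matmul
from .layers import Dropout, Linear, Module
from .model_config import ModelSpec

__all__ = ["SegformerHead", "decode", "upsample_logits", "interp_matrix"]


@lru_cache(maxsize=256)
def interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """1-D bilinear interpolation matrix (n_out x n_in), half-pixel centres."""
    M = np.zeros((n_out, n_in), dtype=np.float32)
    scale = n_in / n_out
    for i in range(n_out):
        s = (i + 0.5) * scale - 0.5
        s0 = int(np.floor(s))
        t = s - s0
        a = min(max(s0, 0), n_in - 1)
        b = min(max(s0 + 1, 0), n_in - 1)
        M[i, a] += 1.0 - t
        M[i, b] += t
    return M


def _resize_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Resize (B, H, W, C) to (B, out_h, out_w, C), differentiable."""
    B, H, W, C = x.shape
    if (H, W) == (out_h, out_w):
        return x
    Rh = Tensor(interp_matrix(out_h, H))
    Rw = Tensor(interp_matrix(out_w, W).T)
    # rows: (out_h, H) @ (B, H, W*C)
    y = matmul(Rh, x.reshape(B, H, W * C)).reshape(B, out_h, W, C)
    # cols: (B*out_h, W, C) -> per-channel matmul along W
    y = y.transpose((0, 1, 3, 2))            # (B, out_h, C, W)
    y = matmul(y, Rw)                         # (B, out_h, C, out_w)
    return y.transpose((0, 1, 3, 2))


class SegformerHead(Module):
    """All-MLP decoder head for a given :class:`ModelSpec`."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        C = spec.decoder_dim
        self.spec = spec
        self.linears = [Linear(ci, C, rng) for ci in spec.hidden_dims]
        self.fuse = Linear(4 * C, C, rng)
        self.drop = Dropout(spec.dropout, rng)
        self.classifier = Linear(C, spec.num_classes, rng)

    def __call__(self, features: list[Tensor]) -> Tensor:
        if len(features) != 4:
            raise ValueError("decoder expects a 4-level pyramid")
        B, H1, W1, _ = features[0].shape
        mapped = []
        for f, lin in zip(features, self.linears):
            g = lin(f)
            g = _resize_bilinear(g, H1, W1)
            mapped.append(g)
        fused = self.fuse(concat(mapped, axis=3))
        fused = self.drop(fused)
        return self.classifier(fused)


def decode(pyramid, decoder_dim: int = 256, num_classes: int = 12,
           head: SegformerHead | None = None, seed: int = 0) -> np.ndarray:
    """Fuse a :class:`~mitseg.encoder.FeaturePyramid` into an (H/4, W/4,
    num_classes) logit map.

    With ``head=None`` a freshly initialized head is used (geometry/contract
    surface); pass a trained head for real predictions.
    """
    levels = pyramid.levels
    dims = tuple(lv.values.shape[2] for lv in levels)
    if head is None:
        from .model_config import resolve_spec
        spec = resolve_spec("mit-b0")
        # build a minimal spec carrying the pyramid's channel widths
        from dataclasses import replace as _replace
        spec = _replace(spec, hidden_dims=dims, decoder_dim=decoder_dim,
                        num_classes=num_classes,
                        attention_heads=(1, 1, 1, 1))
        head = SegformerHead(spec, np.random.default_rng(seed))
    head.eval()
    feats = [Tensor(lv.values[None]) for lv in levels]
    return head(feats).data[0]


def upsample_logits(logits: np.ndarray, target_hw: tuple[int, int]) -> np.ndarray:
    """Bilinearly upsample an (h, w, K) logit map to ``target_hw``.

    Argmax of the result defines the predicted full-resolution mask.
    """
    logits = np.asarray(logits, dtype=np.float32)
    h, w, k = logits.shape
    H, W = target_hw
    if H < h or W < w:
        raise ValueError("target size must be at least the logit size")
    Rh = interp_matrix(H, h)
    Rw = interp_matrix(W, w)
    out = np.einsum("ij,jwk->iwk", Rh, logits)
    out = np.einsum("pw,hwk->hpk", Rw, out)
    return out
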