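"""End-to-end segmentation network: MiT encoder + all-MLP decoder head.

Checkpoints are stored as a flat ``key -> float32 array`` container
(NumPy ``.npz``).  Keys follow the module path, e.g.
``encoder.stage1.block0.attn.q.weight`` — externally trained Mix-Transformer
weights can be mapped in by renaming into this flat namespace.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .decoder import SegformerHead, upsample_logits
from .encoder import MiTEncoder
from .layers import Module
from .model_config import ModelSpec

__all__ = ["SegFormer", "save_checkpoint", "load_checkpoint"]


class SegFormer(Module):
    """Full segmenter producing an (H/4, W/4, num_classes) logit map."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.encoder = MiTEncoder(spec, rng)
        self.head = SegformerHead(spec, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.head(self.encoder(x))

    @staticmethod
    def normalize(images: np.ndarray) -> np.ndarray:
        """uint8 RGB (B, H, W, 3) -> float32 in [-1, 1]."""
        images = np.asarray(images)
        if images.dtype == np.uint8:
            images = images.astype(np.float32) / 127.5 - 1.0
        return images.astype(np.float32)

    def logits(self, images: np.ndarray) -> np.ndarray:
        """Inference logits at 1/4 resolution for a (B, H, W, 3) batch."""
        self.eval()
        return self(Tensor(self.normalize(images))).data

    def predict(self, image: np.ndarray, temperature: float = 1.0):
        """Full-resolution prediction for one (H, W, 3) image.

        Returns ``(mask, probs)``: the argmax label map and the (optionally
        temperature-scaled) softmax probabilities, both at H x W.
        """
        H, W = image.shape[:2]
        lg = self.logits(image[None])[0]
        full = upsample_logits(lg, (H, W)) / float(temperature)
        z = full - full.max(axis=-1, keepdims=True)
        e = np.exp(z)
        probs = e / e.sum(axis=-1, keepdims=True)
        return probs.argmax(axis=-1).astype(np.uint8), probs


def save_checkpoint(model: Module, path, spec: ModelSpec | None = None):
    """Write a flat key->array checkpoint (plus the spec as JSON metadata)."""
    path = Path(path)
    state = model.state_dict()
    if spec is None and hasattr(model, "spec"):
        spec = model.spec
    meta = {}
    if spec is not None:
        import json
        meta["__spec__"] = np.frombuffer(
            json.dumps(spec.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **state, **meta)


def load_checkpoint(path, seed: int = 0) -> SegFormer:
    """Rebuild a :class:`SegFormer` from a checkpoint written by
    :func:`save_checkpoint`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    with np.load(path) as zf:
        state = {k: zf[k] for k in zf.files if k != "__spec__"}
        if "__spec__" not in zf.files:
            raise KeyError("checkpoint lacks embedded model spec")
        import json
        spec = ModelSpec.from_dict(json.loads(bytes(zf["__spec__"]).decode()))
    model = SegFormer(spec, seed=seed)
    model.load_state_dict(state)
    return model
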