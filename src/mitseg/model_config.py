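"""Architectural specifications for the Mix-Transformer (MiT) encoder family.

A :class:`ModelSpec` bundles every hyperparameter needed to instantiate the
hierarchical encoder and its all-MLP decoder: per-stage block depths,
attention heads, channel widths C1..C4, per-dimension spatial-reduction
ratios R_i (the key/value sequence shrinks by R_i**2), and the overlapped
patch-merging geometry (kernel K, stride S, padding P per stage).

The registry holds the canonical MiT family: B0 is the lightest variant
(depths [2,2,2,2], widths [32,64,160,256]); B2/B3/B5 deepen stages 2-3 and
widen every stage ([64,128,320,512]).  ``count_parameters`` instantiates the
network and sums trainable scalars, so the registry geometry is directly
testable against published encoder sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = ["ModelSpec", "SpecValidationError", "resolve_spec", "count_parameters",
           "registry_names", "TINY_SPEC_OVERRIDES"]


class SpecValidationError(ValueError):
    """Raised when a model specification violates a structural invariant."""


@dataclass(frozen=True)
class ModelSpec:
    name: str
    depths: tuple[int, int, int, int]
    attention_heads: tuple[int, int, int, int]
    hidden_dims: tuple[int, int, int, int]
    sr_ratios: tuple[int, int, int, int] = (8, 4, 2, 1)
    merge_kernels: tuple[int, int, int, int] = (7, 3, 3, 3)
    merge_strides: tuple[int, int, int, int] = (4, 2, 2, 2)
    merge_paddings: tuple[int, int, int, int] = (3, 1, 1, 1)
    mlp_ratio: int = 4
    decoder_dim: int = 256
    num_classes: int = 12
    dropout: float = 0.1
    layer_norm_eps: float = 1e-6

    def __post_init__(self):
        for fname in ("depths", "attention_heads", "hidden_dims", "sr_ratios",
                      "merge_kernels", "merge_strides", "merge_paddings"):
            val = tuple(int(v) for v in getattr(self, fname))
            if len(val) != 4:
                raise SpecValidationError(f"{fname} must have 4 entries, got {val}")
            object.__setattr__(self, fname, val)
        self.validate()

    def validate(self):
        for fname in ("depths", "attention_heads", "hidden_dims", "sr_ratios"):
            if any(v < 1 for v in getattr(self, fname)):
                raise SpecValidationError(f"{fname} entries must be positive")
        for c, h in zip(self.hidden_dims, self.attention_heads):
            if c % h != 0:
                raise SpecValidationError(
                    f"hidden dim {c} not divisible by {h} attention heads "
                    f"(head dimension must be integral)")
        if not all(a < b for a, b in zip(self.hidden_dims, self.hidden_dims[1:])):
            raise SpecValidationError(
                f"hidden_dims must be strictly increasing, got {self.hidden_dims}")
        stride_prod = 1
        for s in self.merge_strides:
            stride_prod *= s
        if stride_prod != 32:
            raise SpecValidationError(
                f"product of merge strides must be 32 (final 1/32 resolution), "
                f"got {stride_prod}")
        if not all(a >= b for a, b in zip(self.sr_ratios, self.sr_ratios[1:])):
            raise SpecValidationError(
                f"sr_ratios must be non-increasing, got {self.sr_ratios}")
        for k, s in zip(self.merge_kernels, self.merge_strides):
            if k < s:
                raise SpecValidationError(
                    f"merge kernel {k} smaller than stride {s} (patches must overlap)")
        if self.mlp_ratio < 1:
            raise SpecValidationError("mlp_ratio must be a positive integer")
        if self.decoder_dim < 1 or self.num_classes < 1:
            raise SpecValidationError("decoder_dim and num_classes must be positive")
        if not 0.0 <= self.dropout <= 1.0:
            raise SpecValidationError("dropout must be in [0, 1]")
        if self.layer_norm_eps <= 0:
            raise SpecValidationError("layer_norm_eps must be positive")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(**d)

    def save(self, path):
        path = Path(path)
        d = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(d, sort_keys=False))
        else:
            path.write_text(json.dumps(d, indent=2))

    @classmethod
    def load(cls, path) -> "ModelSpec":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") \
            else json.loads(text)
        return cls.from_dict(d)


_REGISTRY: dict[str, dict] = {
    "mit-b0": dict(depths=(2, 2, 2, 2), hidden_dims=(32, 64, 160, 256)),
    "mit-b2": dict(depths=(3, 4, 6, 3), hidden_dims=(64, 128, 320, 512)),
    "mit-b3": dict(depths=(3, 4, 18, 3), hidden_dims=(64, 128, 320, 512)),
    "mit-b5": dict(depths=(3, 6, 40, 3), hidden_dims=(64, 128, 320, 512)),
}
_COMMON = dict(attention_heads=(1, 2, 5, 8))

# The learnability smoke configuration: a miniature B0 for CPU test runs.
TINY_SPEC_OVERRIDES = {"hidden_dims": (8, 16, 24, 32), "depths": (1, 1, 1, 1),
                       "attention_heads": (1, 2, 4, 8), "decoder_dim": 32}


def registry_names() -> list[str]:
    return sorted(_REGISTRY)


def resolve_spec(name: str, overrides: dict | None = None) -> ModelSpec:
    """Look up ``name`` in the registry and apply field overrides.

    Raises :class:`SpecValidationError` for unknown names, unknown override
    fields, or any violated structural invariant.
    """
    if name not in _REGISTRY:
        raise SpecValidationError(
            f"unknown model {name!r}; registered: {registry_names()}")
    fields = dict(name=name, **_COMMON, **_REGISTRY[name])
    overrides = dict(overrides or {})
    known = set(ModelSpec.__dataclass_fields__)
    unknown = set(overrides) - known
    if unknown:
        raise SpecValidationError(f"unknown spec fields in overrides: {sorted(unknown)}")
    fields.update(overrides)
    return ModelSpec(**fields)


def count_parameters(spec: ModelSpec, scope: str = "encoder") -> int:
    """Trainable-scalar count of the instantiated network for ``scope``.

    ``scope`` is one of ``encoder``, ``decoder``, ``full``.  The count is a
    property of the architecture alone (independent of input image size).
    """
    if scope not in ("encoder", "decoder", "full"):
        raise ValueError(f"scope must be encoder/decoder/full, got {scope!r}")
    from .encoder import MiTEncoder
    from .decoder import SegformerHead
    rng = np.random.default_rng(0)
    total = 0
    if scope in ("encoder", "full"):
        total += MiTEncoder(spec, rng).num_parameters()
    if scope in ("decoder", "full"):
        total += SegformerHead(spec, rng).num_parameters()
    return total
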