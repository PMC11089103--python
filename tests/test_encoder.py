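import numpy as np
import pytest

from mitseg.autodiff import Tensor, softmax
from mitseg.encoder import (EfficientSelfAttention, MixFFN, MiTEncoder,
                            encode, overlapped_patch_merge)
from mitseg.model_config import resolve_spec


def brute_force_attention(x, layer):
    """Direct evaluation of multi-head softmax attention from the layer's
    weights (independent of the layer's own forward path)."""
    B, H, W, C = x.shape
    N = H * W
    tok = x.reshape(B, N, C)
    q = tok @ layer.q.weight.data + layer.q.bias.data
    kv = tok @ layer.kv.weight.data + layer.kv.bias.data
    k, v = kv[..., :C], kv[..., C:]
    h, d = layer.heads, layer.head_dim
    out = np.zeros_like(q)
    for b in range(B):
        for j in range(h):
            qj = q[b, :, j * d:(j + 1) * d]
            kj = k[b, :, j * d:(j + 1) * d]
            vj = v[b, :, j * d:(j + 1) * d]
            s = qj @ kj.T / np.sqrt(d)
            s = np.exp(s - s.max(axis=1, keepdims=True))
            p = s / s.sum(axis=1, keepdims=True)
            out[b, :, j * d:(j + 1) * d] = p @ vj
    out = out @ layer.proj.weight.data + layer.proj.bias.data
    return out.reshape(B, H, W, C)


class TestOverlappedPatchMerge:
    def test_stage1_geometry_quarters_resolution(self):
        x = np.random.default_rng(0).random((512, 512, 3)).astype(np.float32)
        fm = overlapped_patch_merge(x, kernel=7, stride=4, padding=3,
                                    out_channels=32)
        assert fm.values.shape == (128, 128, 32)

    def test_unit_kernel_preserves_dims(self):
        x = np.random.default_rng(0).random((37, 23, 4)).astype(np.float32)
        fm = overlapped_patch_merge(x, kernel=1, stride=1, padding=0,
                                    out_channels=8)
        assert fm.values.shape == (37, 23, 8)

    def test_too_small_input_raises(self):
        x = np.zeros((6, 6, 3), dtype=np.float32)
        with pytest.raises(ValueError, match="too small"):
            overlapped_patch_merge(x, kernel=7, stride=4, padding=0,
                                   out_channels=8)


class TestEfficientSelfAttention:
    def test_r1_matches_brute_force_oracle(self, rng):
        layer = EfficientSelfAttention(dim=16, heads=2, sr_ratio=1,
                                       dropout=0.0, eps=1e-6,
                                       rng=np.random.default_rng(5))
        layer.eval()
        x = rng.standard_normal((2, 8, 8, 16)).astype(np.float32)
        got = layer(Tensor(x)).data
        want = brute_force_attention(x, layer)
        assert np.abs(got - want).max() < 1e-5

    def test_reduction_shortens_kv_sequence_by_r_squared(self):
        layer = EfficientSelfAttention(dim=8, heads=1, sr_ratio=8,
                                       dropout=0.0, eps=1e-6,
                                       rng=np.random.default_rng(0))
        x = Tensor(np.zeros((1, 128, 128, 8), dtype=np.float32))
        reduced = layer._reduce(x)
        assert reduced.shape == (1, 256, 8)   # 16384 / 8**2

    def test_single_token_output_is_projected_value(self):
        layer = EfficientSelfAttention(dim=4, heads=1, sr_ratio=1,
                                       dropout=0.0, eps=1e-6,
                                       rng=np.random.default_rng(2))
        layer.eval()
        x = np.random.default_rng(3).standard_normal((1, 1, 1, 4)).astype(np.float32)
        got = layer(Tensor(x)).data
        # softmax of a 1x1 score is 1, so output = proj(v(x))
        kv = x.reshape(1, 4) @ layer.kv.weight.data + layer.kv.bias.data
        v = kv[:, 4:]
        want = (v @ layer.proj.weight.data + layer.proj.bias.data).reshape(1, 1, 1, 4)
        assert np.allclose(got, want, atol=1e-6)

    def test_untiled_grid_rejected(self):
        layer = EfficientSelfAttention(dim=4, heads=1, sr_ratio=4,
                                       dropout=0.0, eps=1e-6,
                                       rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="does not tile"):
            layer(Tensor(np.zeros((1, 6, 6, 4), dtype=np.float32)))

    def test_attention_rows_are_distributions(self, rng):
        scores = Tensor(rng.standard_normal((3, 2, 10, 7)).astype(np.float32))
        p = softmax(scores, axis=-1).data
        assert np.abs(p.sum(axis=-1) - 1.0).max() < 1e-6
        assert (p >= 0).all()


class TestMixFFN:
    def test_zeroed_weights_give_identity_residual(self, rng):
        ffn = MixFFN(dim=8, mlp_ratio=4, dropout=0.0,
                     rng=np.random.default_rng(0))
        ffn.eval()
        for p in ffn.parameters():
            p.data[...] = 0.0
        x = rng.standard_normal((1, 4, 4, 8)).astype(np.float32)
        # block-level residual: x + ffn(x) with zero ffn weights
        out = (Tensor(x) + ffn(Tensor(x))).data
        assert np.array_equal(out, x)

    def test_hidden_width_is_ratio_times_dim(self):
        ffn = MixFFN(dim=32, mlp_ratio=4, dropout=0.0,
                     rng=np.random.default_rng(0))
        assert ffn.fc1.weight.data.shape == (32, 128)

    def test_output_shape_matches_input(self, rng):
        ffn = MixFFN(dim=64, mlp_ratio=4, dropout=0.0,
                     rng=np.random.default_rng(0))
        ffn.eval()
        x = rng.standard_normal((1, 16, 16, 64)).astype(np.float32)
        assert ffn(Tensor(x)).shape == (1, 16, 16, 64)


class TestEncode:
    def test_pyramid_shapes_64(self):
        spec = resolve_spec("mit-b0")
        img = (np.random.default_rng(0).random((64, 64, 3)) * 255).astype(np.uint8)
        pyr = encode(img, spec, seed=0)
        assert pyr.shapes == [(16, 16, 32), (8, 8, 64), (4, 4, 160), (2, 2, 256)]

    def test_encode_is_deterministic(self, tiny_spec):
        img = (np.random.default_rng(1).random((64, 64, 3)) * 255).astype(np.uint8)
        enc = MiTEncoder(tiny_spec, np.random.default_rng(0))
        a = encode(img, tiny_spec, encoder=enc)
        b = encode(img, tiny_spec, encoder=enc)
        for fa, fb in zip(a.levels, b.levels):
            assert np.array_equal(fa.values, fb.values)

    def test_rejects_tiny_images(self, tiny_spec):
        with pytest.raises(ValueError, match="smaller than minimum"):
            encode(np.zeros((16, 16, 3), dtype=np.uint8), tiny_spec)

    def test_no_positional_encoding_accepts_odd_sizes(self, tiny_spec):
        # any admissible size works without interpolating a learned embedding
        img = (np.random.default_rng(2).random((96, 64, 3)) * 255).astype(np.uint8)
        pyr = encode(img, tiny_spec, seed=0)
        assert pyr.shapes[0][:2] == (24, 16)
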