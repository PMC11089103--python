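"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The segmentation network in this package is small enough to train on a CPU,
so instead of depending on a deep-learning framework we record a tape of
array operations and differentiate it in reverse.  Only the primitives the
Mix-Transformer actually needs are provided: broadcasting arithmetic,
(batched) matrix multiplication, shape manipulation, padding/slicing,
concatenation, GELU, softmax, layer normalization, reductions, and a fused
softmax cross-entropy.

All tensors are float32.  Gradients are accumulated into ``Tensor.grad`` by
``Tensor.backward()``, which walks the graph in reverse topological order
iteratively (no recursion-depth limit on deep networks).
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = [
    "Tensor",
    "constant",
    "matmul",
    "concat",
    "gelu",
    "softmax",
    "layer_norm",
    "pad2d",
    "softmax_cross_entropy",
]

_DTYPE = np.float32
# sqrt(2/pi) and GELU tangent constants for the derivative of the erf form
_INV_SQRT2 = np.float32(1.0 / np.sqrt(2.0))
_INV_SQRT2PI = np.float32(1.0 / np.sqrt(2.0 * np.pi))


def _as_array(x) -> np.ndarray:
    a = np.asarray(x)
    if a.dtype != _DTYPE:
        a = a.astype(_DTYPE)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph construction -------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor.__new__(Tensor)
        out.data = data
        out.grad = None
        out.requires_grad = any(p.requires_grad for p in parents)
        out._parents = parents if out.requires_grad else ()
        out._backward = backward if out.requires_grad else None
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else constant(other)
        out_data = self.data + other.data

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else constant(other)
        return self + (-other)

    def __rsub__(self, other):
        return constant(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else constant(other)
        out_data = self.data * other.data

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * other ** -1.0
        return self * float(1.0 / other)

    def __pow__(self, p: float):
        p = float(p)
        out_data = self.data ** _DTYPE(p)

        def backward(g, a=self, p=p, y=out_data):
            if a.requires_grad:
                a._accumulate(g * _DTYPE(p) * a.data ** _DTYPE(p - 1.0))

        return Tensor._make(out_data, (self,), backward)

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        in_shape = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g, a=self, in_shape=in_shape):
            if a.requires_grad:
                a._accumulate(g.reshape(in_shape))

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, axes):
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
        out_data = np.ascontiguousarray(self.data.transpose(axes))

        def backward(g, a=self, inv=inv):
            if a.requires_grad:
                a._accumulate(g.transpose(inv))

        return Tensor._make(out_data, (self,), backward)

    def __getitem__(self, key):
        out_data = np.ascontiguousarray(self.data[key])

        def backward(g, a=self, key=key):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                full[key] = g  # basic slicing: disjoint target, no scatter-add
                a._accumulate(full)

        return Tensor._make(out_data, (self,), backward)

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims, dtype=_DTYPE)

        def backward(g, a=self, axis=axis, keepdims=keepdims):
            if not a.requires_grad:
                return
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.data.shape).astype(_DTYPE))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.data.shape).astype(_DTYPE))

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * float(1.0 / n)

    # -- autodiff driver ----------------------------------------------------
    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(_DTYPE, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=_DTYPE))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                if node is not self and not isinstance(node, _Leaf):
                    node.grad = None  # free intermediate grads eagerly


class _Leaf(Tensor):
    """Marker subclass for parameters/leaves whose grads must be kept."""
    __slots__ = ()


def constant(value) -> Tensor:
    return Tensor(value, requires_grad=False)


# -- functional primitives ---------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = np.matmul(a.data, b.data)

    def backward(g, a=a, b=b):
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accumulate(_unbroadcast(gb, b.data.shape))

    return Tensor._make(out_data, (a, b), backward)


def concat(tensors, axis: int) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g, tensors=tensors, axis=axis, offsets=offsets):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor._make(out_data, tuple(tensors), backward)


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-form) Gaussian error linear unit."""
    xd = x.data
    phi = 0.5 * (1.0 + erf(xd * _INV_SQRT2))
    out_data = (xd * phi).astype(_DTYPE)

    def backward(g, x=x, phi=phi, xd=xd):
        if x.requires_grad:
            pdf = _INV_SQRT2PI * np.exp(-0.5 * xd * xd)
            x._accumulate((g * (phi + xd * pdf)).astype(_DTYPE))

    return Tensor._make(out_data, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = (e / e.sum(axis=axis, keepdims=True)).astype(_DTYPE)

    def backward(g, x=x, y=y, axis=axis):
        if x.requires_grad:
            dot = (g * y).sum(axis=axis, keepdims=True)
            x._accumulate(y * (g - dot))

    return Tensor._make(y, (x,), backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-6) -> Tensor:
    """Layer normalization over the last axis."""
    xd = x.data
    mu = xd.mean(axis=-1, keepdims=True)
    xc = xd - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (xc * inv).astype(_DTYPE)
    out_data = xhat * gamma.data + beta.data

    def backward(g, x=x, gamma=gamma, beta=beta, xhat=xhat, inv=inv):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).reshape(-1, xhat.shape[-1]).sum(axis=0))
        if beta.requires_grad:
            beta._accumulate(g.reshape(-1, g.shape[-1]).sum(axis=0))
        if x.requires_grad:
            n = xhat.shape[-1]
            gx = g * gamma.data
            m1 = gx.mean(axis=-1, keepdims=True)
            m2 = (gx * xhat).mean(axis=-1, keepdims=True)
            x._accumulate(((gx - m1 - xhat * m2) * inv).astype(_DTYPE))

    return Tensor._make(out_data, (x, gamma, beta), backward)


def pad2d(x: Tensor, pad_h: tuple[int, int], pad_w: tuple[int, int],
          value: float = 0.0) -> Tensor:
    """Pad the H and W axes of a (B, H, W, C) tensor."""
    out_data = np.pad(
        x.data, ((0, 0), pad_h, pad_w, (0, 0)),
        mode="constant", constant_values=_DTYPE(value),
    )
    H, W = x.data.shape[1], x.data.shape[2]

    def backward(g, x=x, pad_h=pad_h, pad_w=pad_w, H=H, W=W):
        if x.requires_grad:
            x._accumulate(g[:, pad_h[0]:pad_h[0] + H, pad_w[0]:pad_w[0] + W, :])

    return Tensor._make(out_data, (x,), backward)


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray,
                          valid: np.ndarray | None = None) -> Tensor:
    """Mean cross-entropy of integer ``targets`` under row-wise softmax.

    ``logits``: (N, K); ``targets``: (N,) ints in [0, K); ``valid``: optional
    boolean (N,) — rows where it is False are excluded from the mean
    (used for padded pixels).
    """
    ld = logits.data
    n, k = ld.shape
    targets = np.asarray(targets).reshape(-1)
    if targets.shape[0] != n:
        raise ValueError("targets length does not match logits rows")
    if targets.min(initial=0) < 0 or targets.max(initial=0) >= k:
        raise ValueError(f"target class index outside [0, {k})")
    if valid is None:
        valid = np.ones(n, dtype=bool)
    else:
        valid = np.asarray(valid, dtype=bool).reshape(-1)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("no valid pixels to compute loss over")

    z = ld - ld.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    logp = z - np.log(e.sum(axis=1, keepdims=True))
    rows = np.arange(n)
    nll = -(logp[rows, targets] * valid).sum() / n_valid
    out_data = _DTYPE(nll)

    def backward(g, logits=logits, p=p, targets=targets, valid=valid,
                 n_valid=n_valid, rows=rows):
        if logits.requires_grad:
            grad = p.copy()
            grad[rows, targets] -= 1.0
            grad *= (valid / n_valid)[:, None]
            logits._accumulate((g * grad).astype(_DTYPE))

    return Tensor._make(np.asarray(out_data), (logits,), backward)
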