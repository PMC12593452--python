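"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module is the compute layer for the whole package: a tape-based
``Tensor`` with the operations needed by a small 3D encoder-decoder and a
structural-causal-model head (3D convolutions, transposed convolutions,
group normalization, PReLU, softmax, box filtering, separable linear
interpolation), plus layer modules, seeded initialisation and an AdamW
optimizer with polynomial learning-rate decay.

Conventions: volumetric activations are ``(N, C, X, Y, Z)`` float32 arrays;
gradients are accumulated by a topological backward sweep over the recorded
tape. Everything is deterministic given the seeds handed to the
initialisers.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import as_strided
from scipy import ndimage as ndi

__all__ = [
    "Tensor",
    "astensor",
    "concat",
    "matmul",
    "conv3d",
    "conv_transpose3d_2x",
    "box_filter3",
    "axis_interp",
    "interp_matrix",
    "softmax",
    "softplus",
    "prelu",
    "clip",
    "one_hot",
    "Module",
    "Conv3d",
    "ConvTranspose3d2x",
    "GroupNorm",
    "PReLU",
    "AdamW",
    "poly_lr",
]


# ---------------------------------------------------------------------------
# Tensor core
# ---------------------------------------------------------------------------

def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
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
    """Array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward: Callable | None = None):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float32)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # -- autodiff -----------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        if not self.requires_grad:
            raise ValueError("backward on a tensor that requires no grad")
        if grad is None:
            if self.data.size != 1:
                raise ValueError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)
        # iterative topological order over the tape
        topo: list[Tensor] = []
        seen: set[int] = set()
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    def zero_grad(self):
        self.grad = None

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = astensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))
        out._backward = bw if out.requires_grad else None
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = astensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bw if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __truediv__(self, other):
        other = astensor(other)
        return self * other.pow(-1.0)

    def __rtruediv__(self, other):
        return astensor(other) * self.pow(-1.0)

    def pow(self, p: float) -> "Tensor":
        out = Tensor(np.power(self.data, p), parents=(self,))

        def bw(g):
            self._accum(g * p * np.power(self.data, p - 1.0))
        out._backward = bw if out.requires_grad else None
        return out

    def __pow__(self, p: float):
        return self.pow(p)

    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), parents=(self,))

        def bw(g):
            self._accum(g * out.data)
        out._backward = bw if out.requires_grad else None
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), parents=(self,))

        def bw(g):
            self._accum(g / self.data)
        out._backward = bw if out.requires_grad else None
        return out

    def abs(self) -> "Tensor":
        out = Tensor(np.abs(self.data), parents=(self,))

        def bw(g):
            self._accum(g * np.sign(self.data))
        out._backward = bw if out.requires_grad else None
        return out

    def square(self) -> "Tensor":
        return self * self

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     parents=(self,))

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy()
                            if np.ndim(g) == self.data.ndim
                            else np.full_like(self.data, g))
                return
            gg = g
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                axes = tuple(a % self.data.ndim for a in axes)
                for a in sorted(axes):
                    gg = np.expand_dims(gg, a)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())
        out._backward = bw if out.requires_grad else None
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))

        def bw(g):
            self._accum(g.reshape(self.data.shape))
        out._backward = bw if out.requires_grad else None
        return out

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        axes = tuple(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))
        inv = tuple(np.argsort(axes))

        def bw(g):
            self._accum(g.transpose(inv))
        out._backward = bw if out.requires_grad else None
        return out

    def __getitem__(self, key) -> "Tensor":
        out = Tensor(self.data[key], parents=(self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accum(full)
        out._backward = bw if out.requires_grad else None
        return out


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])
    out._backward = bw if out.requires_grad else None
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product via ``np.matmul`` broadcasting rules."""
    a, b = astensor(a), astensor(b)
    out = Tensor(np.matmul(a.data, b.data), parents=(a, b))

    def bw(g):
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            a._accum(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            b._accum(_unbroadcast(gb, b.data.shape))
    out._backward = bw if out.requires_grad else None
    return out


# ---------------------------------------------------------------------------
# Nonlinearities
# ---------------------------------------------------------------------------

def softmax(x: Tensor, axis: int = 1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, parents=(x,))

    def bw(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accum(s * (g - dot))
    out._backward = bw if out.requires_grad else None
    return out


def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)
    out = Tensor(y, parents=(x,))

    def bw(g):
        x._accum(g * (1.0 - out.data ** 2))
    out._backward = bw if out.requires_grad else None
    return out


def softplus(x: Tensor) -> Tensor:
    d = x.data
    y = np.maximum(d, 0.0) + np.log1p(np.exp(-np.abs(d)))
    out = Tensor(y, parents=(x,))

    def bw(g):
        sig = 1.0 / (1.0 + np.exp(-d))
        x._accum(g * sig)
    out._backward = bw if out.requires_grad else None
    return out


def prelu(x: Tensor, alpha: Tensor) -> Tensor:
    """PReLU with (broadcastable) learnable negative slope."""
    pos = x.data > 0
    out = Tensor(np.where(pos, x.data, alpha.data * x.data),
                 parents=(x, alpha))

    def bw(g):
        if x.requires_grad:
            x._accum(np.where(pos, g, alpha.data * g))
        if alpha.requires_grad:
            ga = np.where(pos, 0.0, g * x.data)
            alpha._accum(_unbroadcast(ga, alpha.data.shape))
    out._backward = bw if out.requires_grad else None
    return out


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes only where not clipped."""
    out = Tensor(np.clip(x.data, lo, hi), parents=(x,))
    mask = (x.data > lo) & (x.data < hi)

    def bw(g):
        x._accum(g * mask)
    out._backward = bw if out.requires_grad else None
    return out


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """(N, X, Y, Z) int labels -> (N, C, X, Y, Z) float32 one-hot."""
    labels = np.asarray(labels)
    out = np.zeros((labels.shape[0], n_classes) + labels.shape[1:],
                   dtype=np.float32)
    n_idx = np.arange(labels.shape[0])[:, None, None, None]
    xi, yi, zi = np.meshgrid(*[np.arange(s) for s in labels.shape[1:]],
                             indexing="ij")
    out[n_idx, labels, xi[None], yi[None], zi[None]] = 1.0
    return out


# ---------------------------------------------------------------------------
# Volumetric primitives
# ---------------------------------------------------------------------------

def _tap_slices(k: int, stride: int, out_sp: tuple[int, int, int]):
    """Per-tap strided slices into the zero-padded input grid."""
    taps = []
    for a in range(k):
        for b in range(k):
            for c in range(k):
                sl = (slice(None), slice(None),
                      slice(a, a + stride * out_sp[0], stride),
                      slice(b, b + stride * out_sp[1], stride),
                      slice(c, c + stride * out_sp[2], stride))
                taps.append(((a, b, c), sl))
    return taps


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, pad: int | None = None) -> Tensor:
    """3D correlation; kernel ``w`` is (Cout, Cin, k, k, k).

    Implemented as a shift-and-accumulate over the k^3 kernel taps (one
    small GEMM per tap), which is cache-friendlier than im2col at these
    volume sizes. Odd k with 'same'-style default padding k//2.
    """
    k = w.data.shape[2]
    if pad is None:
        pad = k // 2
    n, ci = x.data.shape[:2]
    co = w.data.shape[0]
    in_sp = x.data.shape[2:]

    if k == 1 and stride == 1:
        y = np.matmul(w.data.reshape(co, ci), x.data.reshape(n, ci, -1))
        y = y.reshape((n, co) + in_sp)
        if b is not None:
            y = y + b.data.reshape(1, -1, 1, 1, 1)
        out = Tensor(y, parents=(x, w) if b is None else (x, w, b))

        def bw1(g):
            gl = g.reshape(n, co, -1)
            if w.requires_grad:
                xl = x.data.reshape(n, ci, -1)
                gw = np.matmul(gl, xl.transpose(0, 2, 1)).sum(axis=0)
                w._accum(gw.reshape(w.data.shape))
            if b is not None and b.requires_grad:
                b._accum(gl.sum(axis=(0, 2)))
            if x.requires_grad:
                gx = np.matmul(w.data.reshape(co, ci).T, gl)
                x._accum(gx.reshape(x.data.shape))
        out._backward = bw1 if out.requires_grad else None
        return out

    out_sp = tuple((s + 2 * pad - k) // stride + 1 for s in in_sp)
    taps = _tap_slices(k, stride, out_sp)
    xp = np.pad(x.data, ((0, 0), (0, 0)) + ((pad, pad),) * 3)
    nvox = int(np.prod(out_sp))
    y = np.zeros((n, co, nvox), dtype=x.data.dtype)
    for (a, bb_, c), sl in taps:
        sub = np.ascontiguousarray(xp[sl]).reshape(n, ci, nvox)
        y += np.matmul(w.data[:, :, a, bb_, c], sub)
    y = y.reshape((n, co) + out_sp)
    if b is not None:
        y = y + b.data.reshape(1, -1, 1, 1, 1)
    out = Tensor(y, parents=(x, w) if b is None else (x, w, b))

    def bw(g):
        gl = np.ascontiguousarray(g.reshape(n, co, nvox))
        if b is not None and b.requires_grad:
            b._accum(gl.sum(axis=(0, 2)))
        if w.requires_grad:
            gw = np.empty_like(w.data)
            glt = gl.transpose(0, 2, 1)  # n, L, co
            for (a, bb_, c), sl in taps:
                sub = np.ascontiguousarray(xp[sl]).reshape(n, ci, nvox)
                gw[:, :, a, bb_, c] = np.matmul(sub, glt).sum(axis=0).T
            w._accum(gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for (a, bb_, c), sl in taps:
                gsub = np.matmul(w.data[:, :, a, bb_, c].T, gl)
                gxp[sl] += gsub.reshape((n, ci) + out_sp)
            if pad:
                gxp = gxp[:, :, pad:-pad, pad:-pad, pad:-pad]
            x._accum(gxp)
    out._backward = bw if out.requires_grad else None
    return out


def conv_transpose3d_2x(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Transposed 3D conv with kernel 2, stride 2 (exact 2x upsampling).

    ``w`` is (Cin, Cout, 2, 2, 2); output spatial dims are doubled.
    """
    n, ci = x.data.shape[:2]
    sx, sy, sz = x.data.shape[2:]
    co = w.data.shape[1]
    t = np.tensordot(x.data, w.data, axes=([1], [0]))  # n,x,y,z,co,2,2,2
    t = t.transpose(0, 4, 1, 5, 2, 6, 3, 7)
    y = t.reshape(n, co, 2 * sx, 2 * sy, 2 * sz)
    if b is not None:
        y = y + b.data.reshape(1, -1, 1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(np.ascontiguousarray(y), parents=parents)

    def bw(g):
        gt = g.reshape(n, co, sx, 2, sy, 2, sz, 2)
        gt = gt.transpose(0, 2, 4, 6, 1, 3, 5, 7)  # n,x,y,z,co,2,2,2
        if x.requires_grad:
            gx = np.tensordot(gt, w.data, axes=([4, 5, 6, 7], [1, 2, 3, 4]))
            x._accum(np.ascontiguousarray(gx.transpose(0, 4, 1, 2, 3)))
        if w.requires_grad:
            gw = np.tensordot(x.data, gt, axes=([0, 2, 3, 4], [0, 1, 2, 3]))
            w._accum(gw)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3, 4)))
    out._backward = bw if out.requires_grad else None
    return out


def box_filter3(x: Tensor) -> Tensor:
    """3x3x3 mean filter with zero padding over the spatial axes.

    Self-adjoint (symmetric kernel, constant-mode padding), so the backward
    pass is the same filter applied to the gradient.
    """
    size = (1, 1, 3, 3, 3)
    y = ndi.uniform_filter(x.data, size=size, mode="constant")
    out = Tensor(y, parents=(x,))

    def bw(g):
        x._accum(ndi.uniform_filter(g, size=size, mode="constant"))
    out._backward = bw if out.requires_grad else None
    return out


def interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Linear-interpolation matrix mapping a length-``n_in`` axis to
    ``n_out`` samples (cell-centre aligned, edges clamped)."""
    m = np.zeros((n_out, n_in), dtype=np.float32)
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    scale = n_in / n_out
    for i in range(n_out):
        pos = (i + 0.5) * scale - 0.5
        pos = min(max(pos, 0.0), n_in - 1.0)
        lo = int(math.floor(pos))
        hi = min(lo + 1, n_in - 1)
        t = pos - lo
        m[i, lo] += 1.0 - t
        m[i, hi] += t
    return m


def axis_interp(x: Tensor, m: np.ndarray, axis: int) -> Tensor:
    """Apply interpolation matrix ``m`` (out, in) along ``axis``."""
    mt = np.asarray(m, dtype=np.float32)
    y = np.moveaxis(np.tensordot(mt, x.data, axes=([1], [axis])), 0, axis)
    out = Tensor(np.ascontiguousarray(y), parents=(x,))

    def bw(g):
        gx = np.moveaxis(np.tensordot(mt.T, g, axes=([1], [axis])), 0, axis)
        x._accum(np.ascontiguousarray(gx))
    out._backward = bw if out.requires_grad else None
    return out


def trilinear_resize(x: Tensor, out_shape: Sequence[int]) -> Tensor:
    """Resize the three trailing spatial axes of (N, C, X, Y, Z)."""
    y = x
    for i, n_out in enumerate(out_shape):
        axis = 2 + i
        if y.shape[axis] != n_out:
            y = axis_interp(y, interp_matrix(n_out, y.shape[axis]), axis)
    return y


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

class Module:
    """Tiny layer container with named-parameter traversal."""

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                out.append((key, val))
            elif isinstance(val, Module):
                out.extend(val.named_parameters(prefix=key + "."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(
                            prefix=f"{key}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append((f"{key}.{i}", item))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise ValueError(
                f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()


class Conv3d(Module):
    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k ** 3
        std = math.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0.0, std, (cout, cin, k, k, k)
                                        ).astype(np.float32),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)
        self.stride = stride
        self.k = k

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, stride=self.stride)


class ConvTranspose3d2x(Module):
    def __init__(self, cin: int, cout: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        std = math.sqrt(2.0 / (cin * 8))
        self.weight = Tensor(rng.normal(0.0, std, (cin, cout, 2, 2, 2)
                                        ).astype(np.float32),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose3d_2x(x, self.weight, self.bias)


class GroupNorm(Module):
    def __init__(self, n_channels: int, n_groups: int, eps: float = 1e-5):
        if n_channels % n_groups:
            raise ValueError(
                f"channels ({n_channels}) not divisible by groups ({n_groups})")
        self.gamma = Tensor(np.ones((1, n_channels, 1, 1, 1), dtype=np.float32),
                            requires_grad=True)
        self.beta = Tensor(np.zeros((1, n_channels, 1, 1, 1), dtype=np.float32),
                           requires_grad=True)
        self.n_groups = n_groups
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        n, c = x.shape[:2]
        sp = x.shape[2:]
        g = self.n_groups
        xg = x.reshape(n, g, -1)
        mu = xg.mean(axis=2, keepdims=True)
        xc = xg - mu
        var = xc.square().mean(axis=2, keepdims=True)
        y = xc * (var + self.eps).pow(-0.5)
        y = y.reshape((n, c) + sp)
        return y * self.gamma + self.beta


class PReLU(Module):
    def __init__(self, n_channels: int, init: float = 0.25):
        self.alpha = Tensor(np.full((1, n_channels, 1, 1, 1), init,
                                    dtype=np.float32),
                            requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return prelu(x, self.alpha)


# ---------------------------------------------------------------------------
# Optimisation
# ---------------------------------------------------------------------------

class AdamW(Module):
    """Decoupled-weight-decay Adam over a parameter list."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-5):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


def poly_lr(base_lr: float, step: int, total_steps: int,
            power: float = 0.9) -> float:
    """Polynomial decay schedule, the usual segmentation default."""
    frac = min(step, total_steps) / max(total_steps, 1)
    return base_lr * (1.0 - frac) ** power
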