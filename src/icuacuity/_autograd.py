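"""Compact reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations the acuity sequence model needs: broadcast
arithmetic, matmul, pointwise nonlinearities, reductions, slicing, embedding
lookup, 1-D convolutions, gather along the sequence axis, and a diagonal
linear recurrence (the selective-scan primitive) with a chunked, vectorized
forward and an adjoint reverse scan.

Gradients are accumulated by topological traversal of the tape; every
backward rule is covered by finite-difference checks in the test suite.
"""

from __future__ import annotations

import ctypes
import sys

import numpy as np
from scipy.special import expit as _expit

__all__ = ["Tensor", "diag_scan", "diag_scan_sequential"]


def _tune_allocator() -> None:
    """Keep large numpy temporaries on the reusable heap.

    Autodiff over big batches allocates and frees many multi-megabyte
    arrays per step. By default glibc serves those via mmap and returns
    them to the kernel on free, so every training step re-faults the same
    pages; disabling mmap-backed allocations and heap trimming lets the
    allocator recycle the pages instead. Best effort: silently skipped on
    non-glibc platforms.
    """
    if not sys.platform.startswith("linux"):
        return
    try:
        libc = ctypes.CDLL("libc.so.6")
        libc.mallopt(-4, 0)  # M_MMAP_MAX: no mmap-backed malloc
        libc.mallopt(-1, ctypes.c_int(2**30))  # M_TRIM_THRESHOLD: keep heap
    except OSError:  # pragma: no cover
        pass


_tune_allocator()


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _make(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            # copy: the incoming array may be aliased by another node's grad
            self.grad = np.array(grad, dtype=np.float64)
        else:
            self.grad += grad

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return Tensor._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(-g)

        return Tensor._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data**2), b.shape))

        return Tensor._make(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * exponent * a.data ** (exponent - 1))

        return Tensor._make(a.data**exponent, (a,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accumulate(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accumulate(_unbroadcast(gb, b.shape))

        return Tensor._make(np.matmul(a.data, b.data), (a, b), backward)

    # ------------------------------------------------------------- pointwise
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * out_data)

        return Tensor._make(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(g / a.data)

        return Tensor._make(np.log(a.data), (a,), backward)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (a,), backward)

    def sigmoid(self):
        a = self
        out_data = _expit(a.data)

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (a,), backward)

    def softplus(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * _expit(a.data))

        return Tensor._make(np.logaddexp(0.0, a.data), (a,), backward)

    def silu(self):
        return self * self.sigmoid()

    def clip_max(self, bound: float):
        """Elementwise minimum with a constant (subgradient 0 where clipped)."""
        a = self
        clipped = a.data > bound

        def backward(g):
            if a.requires_grad:
                a._accumulate(np.where(clipped, 0.0, g))

        return Tensor._make(np.where(clipped, bound, a.data), (a,), backward)

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.shape).copy())

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---------------------------------------------------------------- shapes
    def reshape(self, *shape):
        a = self
        old = a.shape

        def backward(g):
            if a.requires_grad:
                a._accumulate(g.reshape(old))

        return Tensor._make(a.data.reshape(*shape), (a,), backward)

    def swapaxes(self, ax1: int, ax2: int):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(np.swapaxes(g, ax1, ax2))

        return Tensor._make(np.swapaxes(a.data, ax1, ax2), (a,), backward)

    def __getitem__(self, idx):
        a = self

        def backward(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accumulate(full)

        return Tensor._make(a.data[idx], (a,), backward)


# --------------------------------------------------------------- custom ops
def embedding(weight: Tensor, indices: np.ndarray) -> Tensor:
    """Row lookup ``weight[indices]`` with scatter-add backward."""
    idx = np.asarray(indices)

    def backward(g):
        if weight.requires_grad:
            full = np.zeros_like(weight.data)
            np.add.at(full, idx, g)
            weight._accumulate(full)

    return Tensor._make(weight.data[idx], (weight,), backward)


def conv1d_same(x: Tensor, weight: Tensor, bias: Tensor, causal: bool = False) -> Tensor:
    """1-D convolution with length-preserving padding.

    ``x`` is (N, L, Cin), ``weight`` is (K, Cin, Cout), ``bias`` is (Cout,).
    With ``causal=True`` all padding is on the left, so output position t
    depends only on inputs at positions <= t.
    """
    K = weight.shape[0]
    L = x.shape[1]
    pad_l = K - 1 if causal else (K - 1) // 2
    pad_r = K - 1 - pad_l
    xp = np.pad(x.data, ((0, 0), (pad_l, pad_r), (0, 0)))
    y = np.zeros(x.shape[:2] + (weight.shape[2],))
    for k in range(K):
        y += np.matmul(xp[:, k : k + L], weight.data[k])
    y += bias.data

    def backward(g):
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 1)))
        if weight.requires_grad:
            gw = np.empty_like(weight.data)
            for k in range(K):
                gw[k] = np.tensordot(xp[:, k : k + L], g, axes=([0, 1], [0, 1]))
            weight._accumulate(gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for k in range(K):
                gxp[:, k : k + L] += np.matmul(g, weight.data[k].T)
            x._accumulate(gxp[:, pad_l : pad_l + L])

    return Tensor._make(y, (x, weight, bias), backward)


def causal_depthwise_conv(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Per-channel causal 1-D convolution.

    ``x`` is (N, L, C), ``weight`` is (K, C), ``bias`` is (C,); output at
    position t only sees positions <= t (left padding K-1).
    """
    K = weight.shape[0]
    L = x.shape[1]
    xp = np.pad(x.data, ((0, 0), (K - 1, 0), (0, 0)))
    y = np.zeros_like(x.data)
    for k in range(K):
        y += xp[:, k : k + L] * weight.data[k]
    y += bias.data

    def backward(g):
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 1)))
        if weight.requires_grad:
            gw = np.empty_like(weight.data)
            for k in range(K):
                gw[k] = (xp[:, k : k + L] * g).sum(axis=(0, 1))
            weight._accumulate(gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for k in range(K):
                gxp[:, k : k + L] += g * weight.data[k]
            x._accumulate(gxp[:, K - 1 :])

    return Tensor._make(y, (x, weight, bias), backward)


def take_along_seq(x: Tensor, indices: np.ndarray) -> Tensor:
    """Gather positions along the sequence axis: (N, L, D) x (N, k) -> (N, k, D)."""
    N, _, D = x.shape
    idx = np.broadcast_to(indices[:, :, None], indices.shape + (D,))

    def backward(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            np.add.at(
                full,
                (np.arange(N)[:, None, None], idx, np.arange(D)[None, None, :]),
                g,
            )
            x._accumulate(full)

    return Tensor._make(np.take_along_axis(x.data, idx, axis=1), (x,), backward)


# ------------------------------------------------------------ diagonal scan
def _chunked_scan(a: np.ndarray, u: np.ndarray, chunk: int = 8) -> np.ndarray:
    """h_t = a_t * h_{t-1} + u_t along axis 1 (h_{-1} = 0), vectorized.

    Within each chunk, h_t = P_t * (carry + sum_{j<=t} u_j / P_j) with
    P_t the running product of a. Chunking bounds the dynamic range of P,
    keeping the division stable; carries propagate sequentially.
    Precondition: every a_t > 0 (the product trick divides by P).
    """
    L = a.shape[1]
    h = np.empty_like(u)
    carry = np.zeros(a.shape[:1] + a.shape[2:])
    for s in range(0, L, chunk):
        e = min(s + chunk, L)
        P = np.cumprod(a[:, s:e], axis=1)
        safe_P = np.maximum(P, 1e-300)
        G = np.cumsum(u[:, s:e] / safe_P, axis=1)
        h[:, s:e] = P * (carry[:, None] + G)
        carry = h[:, e - 1]
    return h


def diag_scan_sequential(a: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Reference sequential implementation of the diagonal recurrence."""
    h = np.empty_like(u)
    carry = np.zeros(a.shape[:1] + a.shape[2:])
    for t in range(a.shape[1]):
        carry = a[:, t] * carry + u[:, t]
        h[:, t] = carry
    return h


def diag_scan(a: Tensor, u: Tensor, chunk: int = 8) -> Tensor:
    """Differentiable diagonal linear recurrence h_t = a_t h_{t-1} + u_t.

    The adjoint is itself a diagonal recurrence run backward in time:
    lam_t = g_t + a_{t+1} lam_{t+1}, with da_t = lam_t * h_{t-1} and
    du_t = lam_t.
    """
    h_data = _chunked_scan(a.data, u.data, chunk=chunk)

    def backward(g):
        # the reversed coefficient sequence starts with a placeholder; it
        # multiplies the zero initial carry, but must be nonzero because
        # the chunked scan divides by running products
        ar = np.empty_like(a.data)
        ar[:, 0] = 1.0
        ar[:, 1:] = a.data[:, :0:-1]
        lam = _chunked_scan(ar, np.ascontiguousarray(g[:, ::-1]), chunk=chunk)[:, ::-1]
        if u.requires_grad:
            u._accumulate(lam.copy())
        if a.requires_grad:
            h_prev = np.zeros_like(h_data)
            h_prev[:, 1:] = h_data[:, :-1]
            a._accumulate(lam * h_prev)

    return Tensor._make(h_data, (a, u), backward)
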