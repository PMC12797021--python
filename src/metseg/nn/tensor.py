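"""A compact reverse-mode automatic-differentiation core on NumPy arrays.

This is the numerical substrate for the segmentation networks in this
package: a define-by-run computation graph over float32 arrays with exactly
the operators the architecture needs (broadcast arithmetic, batched matmul,
softmax, normalization, gathers backed by sparse matrices, and the 3D
convolution family implemented as kernel-offset loops over BLAS calls).
It favors clarity and predictable performance on a single CPU.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Tensor",
    "no_grad",
    "cat",
    "layer_norm_affine",
    "instance_norm_affine",
    "nbr_scores",
    "nbr_output",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "_grad_shared")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple["Tensor", ...] = ()
        self._grad_shared = False

    # -------------------------------------------------------------- plumbing
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        # First contribution is stored by reference (flagged shared, since the
        # producing op may alias it elsewhere, e.g. a view or the child's own
        # grad); a second contribution allocates a fresh sum, after which
        # accumulation is in place. Stored-shared arrays are never mutated.
        if self.grad is None:
            if g.dtype != np.float32:
                g = g.astype(np.float32)
            self.grad = g
            self._grad_shared = True
        elif self._grad_shared:
            self.grad = self.grad + g
            self._grad_shared = False
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _make(data, parents: Iterable["Tensor"], backward) -> "Tensor":
        parents = tuple(p for p in parents if isinstance(p, Tensor))
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        if not isinstance(other, Tensor):
            data = self.data + np.float32(other) if np.isscalar(other) else self.data + other

            def back_s(g, a=self):
                if a.requires_grad:
                    a._accumulate(_unbroadcast(g, a.data.shape))

            return Tensor._make(data, (self,), back_s)
        data = self.data + other.data

        def back(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))

        return Tensor._make(data, (self, other), back)

    __radd__ = __add__

    def __neg__(self):
        def back(g, a=self):
            if a.requires_grad:
                a._accumulate(-g)

        return Tensor._make(-self.data, (self,), back)

    def __sub__(self, other):
        return self + (-other if isinstance(other, Tensor) else -np.asarray(other))

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        if not isinstance(other, Tensor):
            c = np.asarray(other, dtype=np.float32)

            def back_s(g, a=self, c=c):
                if a.requires_grad:
                    a._accumulate(_unbroadcast(g * c, a.data.shape))

            return Tensor._make(self.data * c, (self,), back_s)
        data = self.data * other.data

        def back(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(data, (self, other), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise NotImplementedError("divide by a Tensor via reciprocal if needed")
        return self * (1.0 / np.asarray(other, dtype=np.float32))

    def __matmul__(self, other):
        assert isinstance(other, Tensor)
        data = np.matmul(self.data, other.data)

        def back(g, a=self, b=other):
            if a.requires_grad:
                ga = np.matmul(g, b.data.swapaxes(-1, -2))
                a._accumulate(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.matmul(a.data.swapaxes(-1, -2), g)
                b._accumulate(_unbroadcast(gb, b.data.shape))

        return Tensor._make(data, (self, other), back)

    def pow(self, k: float):
        data = self.data**k

        def back(g, a=self, k=k):
            if a.requires_grad:
                a._accumulate(g * k * a.data ** (k - 1))

        return Tensor._make(data, (self,), back)

    # ------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src = self.data.shape

        def back(g, a=self, src=src):
            if a.requires_grad:
                a._accumulate(g.reshape(src))

        return Tensor._make(self.data.reshape(shape), (self,), back)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def back(g, a=self, inv=inv):
            if a.requires_grad:
                a._accumulate(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), back)

    def __getitem__(self, idx):
        data = self.data[idx]
        src_shape = self.data.shape

        def back(g, a=self, idx=idx, src_shape=src_shape):
            if a.requires_grad:
                full = np.zeros(src_shape, dtype=np.float32)
                full[idx] = g  # basic (slice) indexing only: no duplicates
                a._accumulate(full)

        return Tensor._make(data, (self,), back)

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims=False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def back(g, a=self, axis=axis, keepdims=keepdims):
            if not a.requires_grad:
                return
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.data.shape).astype(np.float32))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.data.shape).astype(np.float32))

        return Tensor._make(data, (self,), back)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ----------------------------------------------------------- activations
    def relu(self):
        out = np.maximum(self.data, 0.0)

        def back(g, a=self, out=out):
            if a.requires_grad:
                a._accumulate(np.where(out > 0, g, np.float32(0.0)))

        return Tensor._make(out, (self,), back)

    def gelu(self):
        # tanh approximation of GELU
        x = self.data
        c = np.float32(np.sqrt(2.0 / np.pi))
        inner = c * (x + 0.044715 * x**3)
        t = np.tanh(inner)
        out = 0.5 * x * (1.0 + t)

        def back(g, a=self, x=x, c=c, t=t):
            if a.requires_grad:
                d_inner = c * (1.0 + 3 * 0.044715 * x**2)
                dt = (1.0 - t**2) * d_inner
                a._accumulate(g * (0.5 * (1.0 + t) + 0.5 * x * dt))

        return Tensor._make(out, (self,), back)

    def softmax(self, axis=-1):
        x = self.data
        m = x.max(axis=axis, keepdims=True)
        e = np.exp(x - m)
        y = e / e.sum(axis=axis, keepdims=True)

        def back(g, a=self, y=y, axis=axis):
            if a.requires_grad:
                gy = g * y
                a._accumulate(gy - y * gy.sum(axis=axis, keepdims=True))

        return Tensor._make(y, (self,), back)

    def normalize(self, axes, eps: float = 1e-5):
        """(x - mean) / sqrt(var + eps) over ``axes`` (fused norm core)."""
        if isinstance(axes, int):
            axes = (axes,)
        axes = tuple(axes)
        x = self.data
        mu = x.mean(axis=axes, keepdims=True)
        xc = x - mu
        var = (xc**2).mean(axis=axes, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        y = xc * inv
        n = np.prod([x.shape[a] for a in axes])

        def back(g, a=self, y=y, inv=inv, axes=axes, n=n):
            if a.requires_grad:
                gm = g.mean(axis=axes, keepdims=True)
                gym = (g * y).mean(axis=axes, keepdims=True)
                a._accumulate(inv * (g - gm - y * gym))

        return Tensor._make(y, (self,), back)

    # --------------------------------------------------------------- gathers
    def gather_rows(self, gmat: sp.csr_matrix):
        """Gather/duplicate rows of a 2D tensor with a sparse selection matrix.

        ``gmat`` is (R, T) with one unit entry per row; forward is
        ``gmat @ x`` and backward is the transposed scatter-add.
        """
        data = gmat @ self.data

        def back(g, a=self, gmat=gmat):
            if a.requires_grad:
                a._accumulate(np.asarray(gmat.T @ g, dtype=np.float32))

        return Tensor._make(data, (self,), back)

    def take_rows(self, idx: np.ndarray):
        """Row gather of a small 2D table with bincount scatter backward."""
        idx = np.asarray(idx)
        data = self.data[idx]
        rows, cols = self.data.shape

        def back(g, a=self, idx=idx, rows=rows, cols=cols):
            if a.requires_grad:
                out = np.empty((rows, cols), dtype=np.float32)
                flat = idx.ravel()
                gf = g.reshape(-1, cols)
                for c in range(cols):
                    out[:, c] = np.bincount(flat, weights=gf[:, c], minlength=rows)
                a._accumulate(out)

        return Tensor._make(data, (self,), back)

    # ---------------------------------------------------------- convolutions
    def conv3d(self, w: "Tensor", b: "Tensor | None" = None, stride: int = 1, padding: int = 0):
        """3D convolution; self is (Ci, D, H, W), ``w`` is (Co, Ci, k, k, k)."""
        x = self.data
        k = w.data.shape[2]
        s, p = stride, padding
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p))) if p else x
        dims_in = xp.shape[1:]
        dims_out = tuple((d - k) // s + 1 for d in dims_in)
        co = w.data.shape[0]
        out = np.zeros((co,) + dims_out, dtype=np.float32)
        for dz in range(k):
            for dy in range(k):
                for dx in range(k):
                    sl = (
                        slice(None),
                        slice(dz, dz + s * dims_out[0], s),
                        slice(dy, dy + s * dims_out[1], s),
                        slice(dx, dx + s * dims_out[2], s),
                    )
                    out += np.tensordot(w.data[:, :, dz, dy, dx], xp[sl], axes=([1], [0]))
        if b is not None:
            out += b.data[:, None, None, None]

        def back(g, a=self, w=w, b=b, xp=xp, k=k, s=s, p=p, dims_out=dims_out):
            need_x = a.requires_grad
            gxp = np.zeros_like(xp) if need_x else None
            gw = np.zeros_like(w.data) if w.requires_grad else None
            for dz in range(k):
                for dy in range(k):
                    for dx in range(k):
                        sl = (
                            slice(None),
                            slice(dz, dz + s * dims_out[0], s),
                            slice(dy, dy + s * dims_out[1], s),
                            slice(dx, dx + s * dims_out[2], s),
                        )
                        if gw is not None:
                            gw[:, :, dz, dy, dx] = np.tensordot(
                                g, xp[sl], axes=([1, 2, 3], [1, 2, 3])
                            )
                        if need_x:
                            gxp[sl] += np.tensordot(
                                w.data[:, :, dz, dy, dx], g, axes=([0], [0])
                            )
            if gw is not None:
                w._accumulate(gw)
            if b is not None and b.requires_grad:
                b._accumulate(g.sum(axis=(1, 2, 3)))
            if need_x:
                if p:
                    gxp = gxp[:, p:-p, p:-p, p:-p]
                a._accumulate(gxp)

        parents = (self, w) if b is None else (self, w, b)
        return Tensor._make(out, parents, back)

    def depthwise_conv3d(self, w: "Tensor", b: "Tensor | None" = None, padding: int = 1):
        """Depthwise 3D convolution; self is (C, D, H, W), ``w`` is (C, k, k, k)."""
        x = self.data
        k = w.data.shape[1]
        p = padding
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p))) if p else x
        dims_out = tuple(d - k + 1 for d in xp.shape[1:])
        out = np.zeros((x.shape[0],) + dims_out, dtype=np.float32)
        for dz in range(k):
            for dy in range(k):
                for dx in range(k):
                    sl = (
                        slice(None),
                        slice(dz, dz + dims_out[0]),
                        slice(dy, dy + dims_out[1]),
                        slice(dx, dx + dims_out[2]),
                    )
                    out += w.data[:, dz, dy, dx][:, None, None, None] * xp[sl]
        if b is not None:
            out += b.data[:, None, None, None]

        def back(g, a=self, w=w, b=b, xp=xp, k=k, p=p, dims_out=dims_out):
            need_x = a.requires_grad
            gxp = np.zeros_like(xp) if need_x else None
            gw = np.zeros_like(w.data) if w.requires_grad else None
            for dz in range(k):
                for dy in range(k):
                    for dx in range(k):
                        sl = (
                            slice(None),
                            slice(dz, dz + dims_out[0]),
                            slice(dy, dy + dims_out[1]),
                            slice(dx, dx + dims_out[2]),
                        )
                        if gw is not None:
                            gw[:, dz, dy, dx] = (g * xp[sl]).sum(axis=(1, 2, 3))
                        if need_x:
                            gxp[sl] += w.data[:, dz, dy, dx][:, None, None, None] * g
            if gw is not None:
                w._accumulate(gw)
            if b is not None and b.requires_grad:
                b._accumulate(g.sum(axis=(1, 2, 3)))
            if need_x:
                if p:
                    gxp = gxp[:, p:-p, p:-p, p:-p]
                a._accumulate(gxp)

        parents = (self, w) if b is None else (self, w, b)
        return Tensor._make(out, parents, back)

    def conv_transpose3d_s2(self, w: "Tensor", b: "Tensor | None" = None):
        """Transposed conv, kernel 2 stride 2 (non-overlapping upsampling).

        self is (Ci, D, H, W); ``w`` is (Ci, Co, 2, 2, 2); output is
        (Co, 2D, 2H, 2W).
        """
        x = self.data
        ci, D, H, W = x.shape
        co = w.data.shape[1]
        out = np.empty((co, 2 * D, 2 * H, 2 * W), dtype=np.float32)
        for az in range(2):
            for ay in range(2):
                for ax in range(2):
                    out[:, az::2, ay::2, ax::2] = np.tensordot(
                        w.data[:, :, az, ay, ax], x, axes=([0], [0])
                    )
        if b is not None:
            out += b.data[:, None, None, None]

        def back(g, a=self, w=w, b=b, x=x):
            gx = np.zeros_like(x) if a.requires_grad else None
            gw = np.zeros_like(w.data) if w.requires_grad else None
            for az in range(2):
                for ay in range(2):
                    for ax in range(2):
                        gs = g[:, az::2, ay::2, ax::2]
                        if gx is not None:
                            gx += np.tensordot(w.data[:, :, az, ay, ax], gs, axes=([1], [0]))
                        if gw is not None:
                            gw[:, :, az, ay, ax] = np.tensordot(
                                x, gs, axes=([1, 2, 3], [1, 2, 3])
                            )
            if gx is not None:
                a._accumulate(gx)
            if gw is not None:
                w._accumulate(gw)
            if b is not None and b.requires_grad:
                b._accumulate(g.sum(axis=(1, 2, 3)))

        parents = (self, w) if b is None else (self, w, b)
        return Tensor._make(out, parents, back)


def cat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back(g, tensors=tuple(tensors), axis=axis, offsets=offsets):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(data, tensors, back)


# --------------------------------------------------------------------------
# fused ops backed by compiled kernels (see _kernels.py)

from . import _kernels as _K  # noqa: E402


def _c32(x: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(x, dtype=np.float32)


def layer_norm_affine(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """y = normalize(x over last axis) * gamma + beta, fused."""
    shape = x.data.shape
    C = shape[-1]
    x2 = _c32(x.data.reshape(-1, C))
    out = np.empty_like(x2)
    xhat = np.empty_like(x2)
    inv = np.empty(x2.shape[0], dtype=np.float32)
    _K.row_norm_forward(x2, gamma.data, beta.data, np.float32(eps), out, xhat, inv)

    def back(g, x=x, gamma=gamma, beta=beta, xhat=xhat, inv=inv, shape=shape, C=C):
        g2 = _c32(g.reshape(-1, C))
        gx = np.empty_like(g2)
        ggamma = np.zeros(C, dtype=np.float32)
        gbeta = np.zeros(C, dtype=np.float32)
        _K.row_norm_backward(g2, xhat, inv, gamma.data, gx, ggamma, gbeta)
        if x.requires_grad:
            x._accumulate(gx.reshape(shape))
        if gamma.requires_grad:
            gamma._accumulate(ggamma)
        if beta.requires_grad:
            beta._accumulate(gbeta)

    return Tensor._make(out.reshape(shape), (x, gamma, beta), back)


def instance_norm_affine(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-channel normalisation of a (C, ...) map over its spatial axes, fused."""
    shape = x.data.shape
    C = shape[0]
    x2 = _c32(x.data.reshape(C, -1))
    out = np.empty_like(x2)
    xhat = np.empty_like(x2)
    inv = np.empty(C, dtype=np.float32)
    _K.chan_norm_forward(x2, gamma.data.reshape(-1), beta.data.reshape(-1), np.float32(eps), out, xhat, inv)

    def back(g, x=x, gamma=gamma, beta=beta, xhat=xhat, inv=inv, shape=shape, C=C):
        g2 = _c32(g.reshape(C, -1))
        gx = np.empty_like(g2)
        ggamma = np.zeros(C, dtype=np.float32)
        gbeta = np.zeros(C, dtype=np.float32)
        _K.chan_norm_backward(g2, xhat, inv, gamma.data.reshape(-1), gx, ggamma, gbeta)
        if x.requires_grad:
            x._accumulate(gx.reshape(shape))
        if gamma.requires_grad:
            gamma._accumulate(ggamma.reshape(gamma.data.shape))
        if beta.requires_grad:
            beta._accumulate(gbeta.reshape(beta.data.shape))

    return Tensor._make(out.reshape(shape), (x, gamma, beta), back)


def gelu_fused(x: Tensor) -> Tensor:
    xd = _c32(x.data)
    out = np.empty_like(xd)
    t = np.empty_like(xd)
    _K.gelu_forward(xd, out, t)

    def back(g, x=x, xd=xd, t=t):
        if x.requires_grad:
            gx = np.empty_like(xd)
            _K.gelu_backward(_c32(g), xd, t, gx)
            x._accumulate(gx)

    return Tensor._make(out, (x,), back)


def depthwise3_fused(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Depthwise 3x3x3 convolution with padding 1 (compiled path)."""
    xp = np.pad(_c32(x.data), ((0, 0), (1, 1), (1, 1), (1, 1)))
    out = np.empty_like(x.data)
    _K.dw3_forward(xp, w.data, b.data, out)

    def back(g, x=x, w=w, b=b, xp=xp):
        g = _c32(g)
        gxp = np.zeros_like(xp)
        gw = np.zeros_like(w.data)
        gb = np.zeros_like(b.data)
        _K.dw3_backward(g, xp, w.data, gxp, gw, gb)
        if x.requires_grad:
            x._accumulate(gxp[:, 1:-1, 1:-1, 1:-1])
        if w.requires_grad:
            w._accumulate(gw)
        if b.requires_grad:
            b._accumulate(gb)

    return Tensor._make(out, (x, w, b), back)


def nbr_scores(q: Tensor, kn: Tensor) -> Tensor:
    """Per-neighbor dot products: q (T,H,d) x kn (T,n,H,d) -> (T,n,H)."""
    qd, knd = _c32(q.data), _c32(kn.data)
    T_, n, H, d = knd.shape
    out = np.empty((T_, n, H), dtype=np.float32)
    _K.nbr_scores_forward(qd, knd, out)

    def back(g, q=q, kn=kn, qd=qd, knd=knd):
        g = _c32(g)
        gq = np.zeros_like(qd)
        gkn = np.empty_like(knd)
        _K.nbr_scores_backward(g, qd, knd, gq, gkn)
        if q.requires_grad:
            q._accumulate(gq)
        if kn.requires_grad:
            kn._accumulate(gkn)

    return Tensor._make(out, (q, kn), back)


def nbr_output(attn: Tensor, vn: Tensor) -> Tensor:
    """Attention-weighted neighbor sum: attn (T,n,H) x vn (T,n,H,d) -> (T,H,d)."""
    ad, vd = _c32(attn.data), _c32(vn.data)
    T_, n, H, d = vd.shape
    out = np.empty((T_, H, d), dtype=np.float32)
    _K.nbr_output_forward(ad, vd, out)

    def back(g, attn=attn, vn=vn, ad=ad, vd=vd):
        g = _c32(g)
        gattn = np.empty_like(ad)
        gvn = np.empty_like(vd)
        _K.nbr_output_backward(g, ad, vd, gattn, gvn)
        if attn.requires_grad:
            attn._accumulate(gattn)
        if vn.requires_grad:
            vn._accumulate(gvn)

    return Tensor._make(out, (attn, vn), back)
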