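"""Numba JIT kernels for the hot inner loops of the autodiff core.

These fuse multi-pass NumPy expressions (depthwise convolution, norm +
affine, GELU, neighborhood score/output contractions) into single-pass
compiled loops. Shapes and semantics mirror the NumPy fallbacks in
``tensor.py``; everything is float32 and single-threaded.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_OPTS = dict(cache=True, fastmath=True)


# ------------------------------------------------------------- depthwise conv


@njit(**_OPTS)
def dw3_forward(xp, w, b, out):
    C, D, H, W = out.shape
    for c in range(C):
        for z in range(D):
            for y in range(H):
                for x in range(W):
                    acc = b[c]
                    for dz in range(3):
                        for dy in range(3):
                            for dx in range(3):
                                acc += w[c, dz, dy, dx] * xp[c, z + dz, y + dy, x + dx]
                    out[c, z, y, x] = acc


@njit(**_OPTS)
def dw3_backward(g, xp, w, gxp, gw, gb):
    C, D, H, W = g.shape
    for c in range(C):
        for z in range(D):
            for y in range(H):
                for x in range(W):
                    gv = g[c, z, y, x]
                    gb[c] += gv
                    for dz in range(3):
                        for dy in range(3):
                            for dx in range(3):
                                gw[c, dz, dy, dx] += gv * xp[c, z + dz, y + dy, x + dx]
                                gxp[c, z + dz, y + dy, x + dx] += gv * w[c, dz, dy, dx]


# ------------------------------------------------------- fused norm + affine
# layernorm operates on rows (N, C) reducing over C; instancenorm callers
# reshape (C, spatial) and swap the roles via row_norm on the first axis.


@njit(**_OPTS)
def row_norm_forward(x, gamma, beta, eps, out, xhat, inv):
    N, C = x.shape
    for i in range(N):
        mu = np.float32(0.0)
        for j in range(C):
            mu += x[i, j]
        mu /= C
        var = np.float32(0.0)
        for j in range(C):
            d = x[i, j] - mu
            var += d * d
        var /= C
        s = np.float32(1.0) / np.sqrt(var + eps)
        inv[i] = s
        for j in range(C):
            h = (x[i, j] - mu) * s
            xhat[i, j] = h
            out[i, j] = h * gamma[j] + beta[j]


@njit(**_OPTS)
def row_norm_backward(g, xhat, inv, gamma, gx, ggamma, gbeta):
    N, C = g.shape
    for i in range(N):
        s1 = np.float32(0.0)
        s2 = np.float32(0.0)
        for j in range(C):
            gg = g[i, j] * gamma[j]
            s1 += gg
            s2 += gg * xhat[i, j]
            ggamma[j] += g[i, j] * xhat[i, j]
            gbeta[j] += g[i, j]
        s1 /= C
        s2 /= C
        for j in range(C):
            gx[i, j] = inv[i] * (g[i, j] * gamma[j] - s1 - xhat[i, j] * s2)


@njit(**_OPTS)
def chan_norm_forward(x, gamma, beta, eps, out, xhat, inv):
    # x: (C, N); normalise each row (channel) over N, affine per channel
    C, N = x.shape
    for c in range(C):
        mu = np.float32(0.0)
        for j in range(N):
            mu += x[c, j]
        mu /= N
        var = np.float32(0.0)
        for j in range(N):
            d = x[c, j] - mu
            var += d * d
        var /= N
        s = np.float32(1.0) / np.sqrt(var + eps)
        inv[c] = s
        for j in range(N):
            h = (x[c, j] - mu) * s
            xhat[c, j] = h
            out[c, j] = h * gamma[c] + beta[c]


@njit(**_OPTS)
def chan_norm_backward(g, xhat, inv, gamma, gx, ggamma, gbeta):
    C, N = g.shape
    for c in range(C):
        s1 = np.float32(0.0)
        s2 = np.float32(0.0)
        for j in range(N):
            s1 += g[c, j]
            s2 += g[c, j] * xhat[c, j]
            ggamma[c] += g[c, j] * xhat[c, j]
            gbeta[c] += g[c, j]
        gs1 = gamma[c] * s1 / N
        gs2 = gamma[c] * s2 / N
        for j in range(N):
            gx[c, j] = inv[c] * (g[c, j] * gamma[c] - gs1 - xhat[c, j] * gs2)


# --------------------------------------------------------------------- GELU


@njit(**_OPTS)
def gelu_forward(x, out, t):
    c = np.float32(0.7978845608028654)  # sqrt(2/pi)
    a = np.float32(0.044715)
    for i in range(x.size):
        v = x.flat[i]
        tt = np.tanh(c * (v + a * v * v * v))
        t.flat[i] = tt
        out.flat[i] = np.float32(0.5) * v * (np.float32(1.0) + tt)


@njit(**_OPTS)
def gelu_backward(g, x, t, gx):
    c = np.float32(0.7978845608028654)
    a = np.float32(0.044715)
    for i in range(x.size):
        v = x.flat[i]
        tt = t.flat[i]
        dt = (np.float32(1.0) - tt * tt) * c * (np.float32(1.0) + np.float32(3.0) * a * v * v)
        gx.flat[i] = g.flat[i] * (np.float32(0.5) * (np.float32(1.0) + tt) + np.float32(0.5) * v * dt)


# ----------------------------------------------- neighborhood contractions


@njit(**_OPTS)
def nbr_scores_forward(q, kn, out):
    # q: (T, H, d); kn: (T, n, H, d); out: (T, n, H)
    T, n, H, d = kn.shape
    for t in range(T):
        for m in range(n):
            for h in range(H):
                acc = np.float32(0.0)
                for j in range(d):
                    acc += q[t, h, j] * kn[t, m, h, j]
                out[t, m, h] = acc


@njit(**_OPTS)
def nbr_scores_backward(g, q, kn, gq, gkn):
    T, n, H, d = kn.shape
    for t in range(T):
        for m in range(n):
            for h in range(H):
                gv = g[t, m, h]
                for j in range(d):
                    gq[t, h, j] += gv * kn[t, m, h, j]
                    gkn[t, m, h, j] = gv * q[t, h, j]


@njit(**_OPTS)
def nbr_output_forward(attn, vn, out):
    # attn: (T, n, H); vn: (T, n, H, d); out: (T, H, d)
    T, n, H, d = vn.shape
    for t in range(T):
        for h in range(H):
            for j in range(d):
                acc = np.float32(0.0)
                for m in range(n):
                    acc += attn[t, m, h] * vn[t, m, h, j]
                out[t, h, j] = acc


@njit(**_OPTS)
def nbr_output_backward(g, attn, vn, gattn, gvn):
    T, n, H, d = vn.shape
    for t in range(T):
        for m in range(n):
            for h in range(H):
                acc = np.float32(0.0)
                for j in range(d):
                    acc += g[t, h, j] * vn[t, m, h, j]
                    gvn[t, m, h, j] = attn[t, m, h] * g[t, h, j]
                gattn[t, m, h] = acc
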