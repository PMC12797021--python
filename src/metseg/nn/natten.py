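"""3D neighborhood self-attention with learnable relative position bias.

Each token on an H x W x D token grid attends to the n = M^3 tokens of a
sliding M x M x M window centred on it; near the grid border the window is
shifted (clamped) minimally to stay in-grid, so every token has exactly n
neighbors. Per head, the attention score of token (i,j,k) against neighbor t
is the scaled dot product of the central query with the neighbor key plus a
learnable bias indexed by their 3D offset; the softmax-weighted sum of
neighbor value vectors is the attention output. Heads are concatenated and
output-projected. Because the neighborhood is defined by relative offsets,
the operator is translationally equivariant away from the borders.

``brute_force_oracle`` recomputes the same quantity token-by-token with
explicit Python loops and is used only for testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.sparse as sp

from . import tensor as T
from .layers import Linear, Module
from .tensor import Tensor

__all__ = [
    "AttentionConfig",
    "NeighborhoodMap",
    "build_neighborhood",
    "NeighborhoodAttention3D",
    "neighborhood_attention",
    "brute_force_oracle",
]


@dataclass(frozen=True)
class AttentionConfig:
    """Shape hyperparameters of one attention operator.

    ``embed_dim`` must divide evenly into ``heads`` heads; ``neighborhood``
    (M) is odd. The per-head dimension d = embed_dim / heads is the scale in
    the softmax (scores divided by sqrt(d)).
    """

    embed_dim: int
    heads: int
    neighborhood: int = 7

    def __post_init__(self) -> None:
        if self.embed_dim % self.heads:
            raise ValueError("embed_dim must be divisible by heads")
        if self.neighborhood % 2 == 0 or self.neighborhood < 1:
            raise ValueError("neighborhood size M must be odd and positive")

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.heads


@dataclass(frozen=True)
class NeighborhoodMap:
    """Precomputed neighbor indices for one (grid, window) combination.

    ``indices[t]`` lists, in raster order of the window offsets, the flat
    token indices of the n neighbors of token t; ``offset_ids[t]`` gives the
    corresponding rows of the (2M-1)^3 relative-position bias table.
    """

    grid: tuple[int, int, int]
    window: tuple[int, int, int]
    M: int  # configured window size indexing the bias table
    indices: np.ndarray  # (T, n) int32
    offset_ids: np.ndarray  # (T, n) int32

    @property
    def n_neighbors(self) -> int:
        return int(np.prod(self.window))

    @property
    def gather_matrix(self) -> sp.csr_matrix:
        g = getattr(self, "_gmat", None)
        if g is None:
            T_tokens = int(np.prod(self.grid))
            flat = self.indices.ravel()
            g = sp.csr_matrix(
                (
                    np.ones(flat.size, dtype=np.float32),
                    (np.arange(flat.size), flat),
                ),
                shape=(flat.size, T_tokens),
            )
            object.__setattr__(self, "_gmat", g)
        return g


def _axis_windows(n: int, m: int) -> np.ndarray:
    """Window start index per position on one axis (clamped to stay in-grid)."""
    centers = np.arange(n)
    return np.clip(centers - (m - 1) // 2, 0, n - m)


@lru_cache(maxsize=64)
def build_neighborhood(grid: tuple[int, int, int], M) -> NeighborhoodMap:
    """Neighbor map for a token grid and window size.

    ``M`` may be an int (cubic window) or a per-axis tuple; every grid axis
    must be at least as large as the window on that axis.
    """
    grid = tuple(int(g) for g in grid)
    window = (M, M, M) if isinstance(M, int) else tuple(int(m) for m in M)
    if any(g < m for g, m in zip(grid, window)):
        raise ValueError(f"grid {grid} smaller than window {window} on some axis")
    m_cfg = max(window)

    starts = [_axis_windows(grid[a], window[a]) for a in range(3)]
    offs = [np.arange(window[a]) for a in range(3)]
    # per-axis neighbor coordinates: (n_axis, m_axis)
    coords = [starts[a][:, None] + offs[a][None, :] for a in range(3)]

    gi, gj, gk = np.meshgrid(np.arange(grid[0]), np.arange(grid[1]), np.arange(grid[2]), indexing="ij")
    ci = coords[0][gi.ravel()]  # (T, m0)
    cj = coords[1][gj.ravel()]
    ck = coords[2][gk.ravel()]
    # raster order over (di, dj, dk)
    ii = ci[:, :, None, None]
    jj = cj[:, None, :, None]
    kk = ck[:, None, None, :]
    flat = (ii * grid[1] + jj) * grid[2] + kk  # (T, m0, m1, m2)
    Ttok = flat.shape[0]
    indices = flat.reshape(Ttok, -1).astype(np.int32)

    di = ii - gi.ravel()[:, None, None, None]
    dj = jj - gj.ravel()[:, None, None, None]
    dk = kk - gk.ravel()[:, None, None, None]
    span = 2 * m_cfg - 1
    oid = ((di + m_cfg - 1) * span + (dj + m_cfg - 1)) * span + (dk + m_cfg - 1)
    offset_ids = oid.reshape(Ttok, -1).astype(np.int32)
    return NeighborhoodMap(grid, window, m_cfg, indices, offset_ids)


class NeighborhoodAttention3D(Module):
    """Multi-head neighborhood attention over flattened (T, C) token features."""

    def __init__(self, cfg: AttentionConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.qkv = Linear(cfg.embed_dim, 3 * cfg.embed_dim, rng)
        self.proj = Linear(cfg.embed_dim, cfg.embed_dim, rng)
        span = 2 * cfg.neighborhood - 1
        self.bias = Tensor(np.zeros((span**3, cfg.heads), dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor, nbmap: NeighborhoodMap) -> Tensor:
        cfg = self.cfg
        Ttok = x.shape[0]
        n = nbmap.n_neighbors
        H, d = cfg.heads, cfg.head_dim

        qkv = self.qkv(x)  # (T, 3C)
        q = qkv[:, : cfg.embed_dim]
        k = qkv[:, cfg.embed_dim : 2 * cfg.embed_dim]
        v = qkv[:, 2 * cfg.embed_dim :]

        q = q.reshape(Ttok, H, d)
        kn = k.gather_rows(nbmap.gather_matrix).reshape(Ttok, n, H, d)
        vn = v.gather_rows(nbmap.gather_matrix).reshape(Ttok, n, H, d)

        scores = T.nbr_scores(q, kn)  # (T, n, H)
        bias = self.bias.take_rows(nbmap.offset_ids.ravel()).reshape(Ttok, n, H)
        # the whole score matrix (dot products + bias) is scaled by 1/sqrt(d)
        attn = ((scores + bias) * (1.0 / float(np.sqrt(d)))).softmax(axis=1)
        out = T.nbr_output(attn, vn)  # (T, H, d)
        return self.proj(out.reshape(Ttok, cfg.embed_dim))


def _weights_of(module: NeighborhoodAttention3D) -> dict[str, np.ndarray]:
    return {
        "w_qkv": module.qkv.w.data,
        "b_qkv": module.qkv.b.data,
        "w_proj": module.proj.w.data,
        "b_proj": module.proj.b.data,
        "bias": module.bias.data,
    }


def _module_from_weights(cfg: AttentionConfig, weights: dict) -> NeighborhoodAttention3D:
    mod = NeighborhoodAttention3D(cfg, np.random.default_rng(0))
    mod.qkv.w.data = np.asarray(weights["w_qkv"], dtype=np.float32)
    mod.qkv.b.data = np.asarray(weights["b_qkv"], dtype=np.float32)
    mod.proj.w.data = np.asarray(weights["w_proj"], dtype=np.float32)
    mod.proj.b.data = np.asarray(weights["b_proj"], dtype=np.float32)
    mod.bias.data = np.asarray(weights["bias"], dtype=np.float32)
    return mod


def random_weights(cfg: AttentionConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Random attention weights in the functional-API format."""
    C = cfg.embed_dim
    span = 2 * cfg.neighborhood - 1
    return {
        "w_qkv": rng.standard_normal((C, 3 * C)).astype(np.float32) * 0.2,
        "b_qkv": rng.standard_normal(3 * C).astype(np.float32) * 0.05,
        "w_proj": rng.standard_normal((C, C)).astype(np.float32) * 0.2,
        "b_proj": rng.standard_normal(C).astype(np.float32) * 0.05,
        "bias": rng.standard_normal((span**3, cfg.heads)).astype(np.float32) * 0.1,
    }


def neighborhood_attention(
    x: np.ndarray, cfg: AttentionConfig, weights: dict, window=None
) -> np.ndarray:
    """Functional neighborhood attention on a (D, H, W, C) feature grid."""
    grid = x.shape[:3]
    win = cfg.neighborhood if window is None else window
    nbmap = build_neighborhood(tuple(grid), win)
    mod = _module_from_weights(cfg, weights)
    with T.no_grad():
        out = mod(Tensor(x.reshape(-1, cfg.embed_dim)), nbmap)
    return out.data.reshape(x.shape)


def brute_force_oracle(x: np.ndarray, cfg: AttentionConfig, weights: dict) -> np.ndarray:
    """Explicit-loop reference for neighborhood attention (small grids only).

    Recomputes, token by token and head by head: the clamped window, the
    per-neighbor dot-product scores with relative-position bias, the scaled
    softmax, and the weighted sum of neighbor values, then concatenates heads
    and applies the output projection.
    """
    grid = x.shape[:3]
    if np.prod(grid) > 8**3:
        raise ValueError("oracle is for small grids only")
    C = cfg.embed_dim
    H, d = cfg.heads, cfg.head_dim
    M = cfg.neighborhood
    win = tuple(min(M, g) for g in grid)
    span = 2 * M - 1

    xf = x.reshape(-1, C).astype(np.float64)
    qkv = xf @ weights["w_qkv"].astype(np.float64) + weights["b_qkv"].astype(np.float64)
    q_all, k_all, v_all = qkv[:, :C], qkv[:, C : 2 * C], qkv[:, 2 * C :]
    bias = weights["bias"].astype(np.float64)

    def flat(i, j, k):
        return (i * grid[1] + j) * grid[2] + k

    out = np.zeros_like(xf)
    for i in range(grid[0]):
        for j in range(grid[1]):
            for k in range(grid[2]):
                s0 = min(max(i - (win[0] - 1) // 2, 0), grid[0] - win[0])
                s1 = min(max(j - (win[1] - 1) // 2, 0), grid[1] - win[1])
                s2 = min(max(k - (win[2] - 1) // 2, 0), grid[2] - win[2])
                nbrs = [
                    (a, b, c)
                    for a in range(s0, s0 + win[0])
                    for b in range(s1, s1 + win[1])
                    for c in range(s2, s2 + win[2])
                ]
                t0 = flat(i, j, k)
                for h in range(H):
                    sl = slice(h * d, (h + 1) * d)
                    qh = q_all[t0, sl]
                    scores = np.empty(len(nbrs))
                    for idx, (a, b, c) in enumerate(nbrs):
                        kh = k_all[flat(a, b, c), sl]
                        oid = (
                            ((a - i) + M - 1) * span + ((b - j) + M - 1)
                        ) * span + ((c - k) + M - 1)
                        scores[idx] = qh @ kh + bias[oid, h]
                    scores = scores / np.sqrt(d)
                    e = np.exp(scores - scores.max())
                    wts = e / e.sum()
                    acc = np.zeros(d)
                    for idx, (a, b, c) in enumerate(nbrs):
                        acc += wts[idx] * v_all[flat(a, b, c), sl]
                    out[t0, sl] = acc
    out = out @ weights["w_proj"].astype(np.float64) + weights["b_proj"].astype(np.float64)
    return out.reshape(x.shape).astype(np.float32)
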