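"""U-shaped encoder/decoder segmentation network with 3D neighborhood attention.

The encoder embeds non-overlapping 2x2x2 patches of the S-channel input into
an E-dimensional token space and runs four stages of pre-norm transformer
blocks (neighborhood attention + MLP), each followed by a stride-2 3x3x3
convolutional downsampler that halves every grid axis (ceiling division on
odd axes) and doubles the embedding. The decoder mirrors the hierarchy:
depthwise-convolution residual blocks on each encoder output, kernel-2
stride-2 deconvolution upsampling, concatenation with the earlier-stage skip
(including a full-resolution convolutional projection of the raw input), and
a softmax segmentation head producing per-voxel class probabilities.

Two instances make up the cascade: a locator (2 input channels: T1c, FLAIR)
over the whole volume, and a segmenter (3 channels: T1c, FLAIR, and the
locator's probability map) over lesion-centred crops.

When a deep stage's token grid is smaller than the configured neighborhood M
on an axis, the window shrinks to the grid size on that axis (attention
becomes global there), which keeps small desk-scale inputs legal.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import tensor as T
from .layers import (
    AdamW,
    Conv3d,
    ConvTranspose3d,
    DepthwiseConv3d,
    InstanceNorm3d,
    LayerNorm,
    Linear,
    Mlp,
    Module,
)
from .natten import AttentionConfig, NeighborhoodAttention3D, build_neighborhood
from .tensor import Tensor, cat

__all__ = ["NetworkConfig", "TransformerBlock", "MetsNet"]

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    ``in_channels`` is 2 for the locator and 3 for the segmenter. The token
    embedding starts at ``embed_dim`` (default 72) and doubles at each of the
    four downsamplers; heads are set per stage as (stage dim / head_dim) with
    head_dim fixed (default 24) so the softmax scale is constant across
    stages. ``depths`` are the transformer-block counts of the four stages.
    """

    in_channels: int = 2
    patch: tuple[int, int, int] = (2, 2, 2)
    embed_dim: int = 72
    depths: tuple[int, int, int, int] = (2, 2, 2, 2)
    neighborhood: int = 7
    n_classes: int = 2
    head_dim: int = 24
    mlp_ratio: int = 4

    def __post_init__(self) -> None:
        if self.embed_dim % self.head_dim:
            raise ValueError("embed_dim must be divisible by head_dim")
        if self.neighborhood % 2 == 0:
            raise ValueError("neighborhood M must be odd")
        if len(self.depths) != 4:
            raise ValueError("exactly four encoder stages are expected")

    def stage_dim(self, t: int) -> int:
        return self.embed_dim * (2 ** max(t, 0))

    def stage_heads(self, t: int) -> int:
        return self.stage_dim(t) // self.head_dim


class TransformerBlock(Module):
    """Pre-norm block: x + Attn(LN(x)), then x + MLP(LN(x))."""

    def __init__(self, dim: int, heads: int, M: int, rng: np.random.Generator, mlp_ratio: int = 4):
        self.norm1 = LayerNorm(dim)
        self.attn = NeighborhoodAttention3D(AttentionConfig(dim, heads, M), rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(dim, rng, ratio=mlp_ratio)

    def __call__(self, x: Tensor, nbmap) -> Tensor:
        x = x + self.attn(self.norm1(x), nbmap)
        return x + self.mlp(self.norm2(x))


class ResBlock(Module):
    """Depthwise 3x3x3 + pointwise projection with residual shortcut."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.dw = DepthwiseConv3d(c_in, 3, rng, padding=1)
        self.norm = InstanceNorm3d(c_in)
        self.pw = Conv3d(c_in, c_out, 1, rng)
        self.shortcut = Conv3d(c_in, c_out, 1, rng) if c_in != c_out else None

    def __call__(self, x: Tensor) -> Tensor:
        y = self.pw(self.norm(self.dw(x)).relu())
        s = x if self.shortcut is None else self.shortcut(x)
        return (y + s).relu()


def _tokens_to_map(x: Tensor, grid) -> Tensor:
    return x.reshape(*grid, x.shape[-1]).transpose(3, 0, 1, 2)


def _map_to_tokens(x: Tensor) -> Tensor:
    c = x.shape[0]
    return x.transpose(1, 2, 3, 0).reshape(-1, c)


class MetsNet(Module):
    """The segmentation network (used for both the locator and the segmenter)."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        E = cfg.embed_dim
        # t = -1 skip: full-resolution projection of the raw input
        self.input_proj = Conv3d(cfg.in_channels, E, 3, rng, padding=1)
        self.patch_embed_conv = Conv3d(cfg.in_channels, E, 2, rng, stride=2)
        self.embed_norm = LayerNorm(E)

        self.stages = []
        self.downsamplers = []
        for t in range(4):
            dim = cfg.stage_dim(t)
            blocks = [
                TransformerBlock(dim, cfg.stage_heads(t), cfg.neighborhood, rng, cfg.mlp_ratio)
                for _ in range(cfg.depths[t])
            ]
            self.stages.append(blocks)
            self.downsamplers.append(Conv3d(dim, dim * 2, 3, rng, stride=2, padding=1))

        # decoder: one residual block per skip level, deconv between levels
        self.skip_blocks = [ResBlock(cfg.stage_dim(t), cfg.stage_dim(t), rng) for t in range(5)]
        self.ups = [ConvTranspose3d(cfg.stage_dim(t), cfg.stage_dim(t - 1), rng) for t in range(4, 0, -1)]
        self.fuse_blocks = [
            ResBlock(2 * cfg.stage_dim(t), cfg.stage_dim(t), rng) for t in range(3, -1, -1)
        ]
        self.up_full = ConvTranspose3d(E, E, rng)
        self.input_block = ResBlock(E, E, rng)
        self.fuse_full = ResBlock(2 * E, E, rng)
        self.head = Conv3d(E, cfg.n_classes, 1, rng)

    # ------------------------------------------------------------- encoder
    def patch_embed(self, x: Tensor) -> tuple[Tensor, tuple[int, int, int]]:
        """Embed 2x2x2 patches; returns tokens (T, E) and the token grid."""
        spatial = x.shape[1:]
        if any(s % 2 for s in spatial):
            raise ValueError(f"input axes must be divisible by 2, got {spatial}")
        fmap = self.patch_embed_conv(x)
        grid = fmap.shape[1:]
        return self.embed_norm(_map_to_tokens(fmap)), grid

    def _stage_window(self, grid) -> tuple[int, int, int]:
        M = self.cfg.neighborhood
        return tuple(min(M, g) for g in grid)

    def encoder_forward(self, tokens: Tensor, grid) -> list[tuple[Tensor, tuple]]:
        """Run the four stages; returns feature maps for t = 0..4 as (map, grid)."""
        outputs = []
        x, g = tokens, tuple(grid)
        for t in range(4):
            nbmap = build_neighborhood(g, self._stage_window(g))
            for block in self.stages[t]:
                x = block(x, nbmap)
            fmap = _tokens_to_map(x, g)
            outputs.append((fmap, g))
            down = self.downsamplers[t](fmap)
            g = down.shape[1:]
            x = _map_to_tokens(down)
        outputs.append((_tokens_to_map(x, g), g))
        return outputs

    # ------------------------------------------------------------- decoder
    def decoder_forward(self, enc: list[tuple[Tensor, tuple]], input_skip: Tensor) -> Tensor:
        x = self.skip_blocks[4](enc[4][0])
        for i, t in enumerate(range(3, -1, -1)):
            x = self.ups[i](x)
            skip, g = enc[t]
            x = x[:, : g[0], : g[1], : g[2]]  # crop ceil-division overshoot
            skip = self.skip_blocks[t](skip)
            x = self.fuse_blocks[i](cat([x, skip], axis=0))
        x = self.up_full(x)
        s = self.input_block(input_skip)
        x = x[:, : s.shape[1], : s.shape[2], : s.shape[3]]
        x = self.fuse_full(cat([x, s], axis=0))
        logits = self.head(x)
        # softmax over the class axis, voxelwise
        c = logits.shape[0]
        probs = _map_to_tokens(logits).softmax(axis=-1)
        return probs.reshape(*logits.shape[1:], c).transpose(3, 0, 1, 2)

    def __call__(self, x) -> Tensor:
        """Forward pass: (S, D, H, W) array or Tensor -> (n_classes, D, H, W) probs."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.shape[0] != self.cfg.in_channels:
            raise ValueError(f"expected {self.cfg.in_channels} channels, got {x.shape[0]}")
        tokens, grid = self.patch_embed(x)
        enc = self.encoder_forward(tokens, grid)
        return self.decoder_forward(enc, self.input_proj(x))

    def predict_prob(self, channels: np.ndarray) -> np.ndarray:
        """Inference: tumor-class probability map, same spatial shape as input."""
        with T.no_grad():
            probs = self(np.asarray(channels, dtype=np.float32))
        return probs.data[1]

    # ---------------------------------------------------------- checkpoints
    def save(self, path) -> None:
        path = Path(path)
        cfg = asdict(self.cfg)
        np.savez(
            path,
            __config__=np.frombuffer(json.dumps({"version": CHECKPOINT_VERSION, "cfg": cfg}).encode(), dtype=np.uint8),
            **self.state_dict(),
        )

    @classmethod
    def load(cls, path, seed: int = 0) -> "MetsNet":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__config__"]).decode())
            if meta.get("version") != CHECKPOINT_VERSION:
                raise ValueError(f"unsupported checkpoint version: {meta.get('version')}")
            cfg_d = meta["cfg"]
            cfg_d["patch"] = tuple(cfg_d["patch"])
            cfg_d["depths"] = tuple(cfg_d["depths"])
            cfg = NetworkConfig(**cfg_d)
            net = cls(cfg, seed=seed)
            net.load_state_dict({k: z[k] for k in z.files if k != "__config__"})
        return net
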