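"""Neural-network building blocks: modules, initialisation, optimizer."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, depthwise3_fused, gelu_fused, instance_norm_affine, layer_norm_affine

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "InstanceNorm3d",
    "Conv3d",
    "DepthwiseConv3d",
    "ConvTranspose3d",
    "Mlp",
    "AdamW",
]


class Module:
    """Base class: recursive parameter discovery and state (de)serialisation."""

    def parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}

        def visit(prefix: str, val) -> None:
            if isinstance(val, Tensor):
                if val.requires_grad:
                    out[prefix] = val
            elif isinstance(val, Module):
                for sub, p in val.parameters().items():
                    out[f"{prefix}.{sub}"] = p
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    visit(f"{prefix}.{i}", item)

        for name, val in vars(self).items():
            visit(name, val)
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def num_params(self) -> int:
        return sum(p.data.size for p in self.parameters().values())

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.grad = None


def _trunc_normal(rng: np.random.Generator, shape, std=0.02) -> np.ndarray:
    x = rng.standard_normal(shape) * std
    return np.clip(x, -2 * std, 2 * std).astype(np.float32)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        self.w = Tensor(_trunc_normal(rng, (d_in, d_out)), requires_grad=True)
        self.b = Tensor(np.zeros(d_out, dtype=np.float32), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.w
        return y + self.b if self.b is not None else y


class LayerNorm(Module):
    """Normalisation over the last (channel) axis with learnable affine."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=np.float32), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm_affine(x, self.gamma, self.beta, eps=self.eps)


class InstanceNorm3d(Module):
    """Per-channel normalisation over the spatial axes of a (C, D, H, W) map."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones((channels, 1, 1, 1), dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros((channels, 1, 1, 1), dtype=np.float32), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return instance_norm_affine(x, self.gamma, self.beta, eps=self.eps)


class Conv3d(Module):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int = 0,
    ):
        fan_in = c_in * kernel**3
        std = float(np.sqrt(2.0 / fan_in))
        self.w = Tensor(
            (rng.standard_normal((c_out, c_in, kernel, kernel, kernel)) * std).astype(np.float32),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv3d(self.w, self.b, stride=self.stride, padding=self.padding)


class DepthwiseConv3d(Module):
    def __init__(self, channels: int, kernel: int, rng: np.random.Generator, padding: int = 1):
        std = float(np.sqrt(2.0 / kernel**3))
        self.w = Tensor(
            (rng.standard_normal((channels, kernel, kernel, kernel)) * std).astype(np.float32),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        if self.w.data.shape[1] == 3 and self.padding == 1:
            return depthwise3_fused(x, self.w, self.b)
        return x.depthwise_conv3d(self.w, self.b, padding=self.padding)


class ConvTranspose3d(Module):
    """Kernel-2 stride-2 deconvolution (exact 2x upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        std = float(np.sqrt(2.0 / c_in))
        self.w = Tensor(
            (rng.standard_normal((c_in, c_out, 2, 2, 2)) * std).astype(np.float32),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv_transpose3d_s2(self.w, self.b)


class Mlp(Module):
    def __init__(self, dim: int, rng: np.random.Generator, ratio: int = 4):
        self.fc1 = Linear(dim, dim * ratio, rng)
        self.fc2 = Linear(dim * ratio, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(gelu_fused(self.fc1(x)))


class AdamW:
    """AdamW with decoupled weight decay.

    ``beta2`` (the second-moment coefficient) defaults to 0.99, matching the
    training recipe's momentum parameter; ``beta1`` keeps its conventional
    value. Parameters without gradients in a step are skipped.
    """

    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.99,
        eps: float = 1e-8,
        weight_decay: float = 1e-5,
    ):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / bc1
            v_hat = self.v[k] / bc2
            p.data -= self.lr * (m_hat / (np.sqrt(v_hat) + self.eps) + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
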