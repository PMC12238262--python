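"""Neural-network building blocks on top of the autograd core.

Initialization is fully deterministic: every module draws its parameters
from the `numpy.random.Generator` handed to its constructor, so two models
built from generators with the same seed are bit-identical.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concatenate, conv1d, conv_transpose1d

__all__ = [
    "Module", "Linear", "Conv1d", "ConvTranspose1d", "LayerNorm",
    "MultiheadSelfAttention", "TransformerBlock",
]


class Module:
    """Minimal parameter container with recursive parameter discovery."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {str(i): p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state dict does not match model parameters")
        for i, p in enumerate(params):
            arr = np.asarray(state[str(i)], dtype=np.float64)
            if arr.shape != p.shape:
                raise ValueError(f"parameter {i} shape mismatch")
            p.data[...] = arr

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _collect(value):
    if isinstance(value, Tensor) and value.requires_grad:
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int, fan_out: int) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator):
        self.weight = _glorot(rng, (in_features, out_features),
                              in_features, out_features)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, *, stride: int = 1,
                 padding: int = 0, dilation: int = 1):
        fan_in = in_channels * kernel_size
        self.weight = _glorot(rng, (out_channels, in_channels, kernel_size),
                              fan_in, out_channels * kernel_size)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)
        self.stride, self.padding, self.dilation = stride, padding, dilation

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, dilation=self.dilation)


class ConvTranspose1d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, *, stride: int = 1,
                 padding: int = 0, output_padding: int = 0):
        fan_in = in_channels * kernel_size
        self.weight = _glorot(rng, (in_channels, out_channels, kernel_size),
                              fan_in, out_channels * kernel_size)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)
        self.stride, self.padding = stride, padding
        self.output_padding = output_padding

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose1d(x, self.weight, self.bias, stride=self.stride,
                                padding=self.padding,
                                output_padding=self.output_padding)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered ** 2).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps).sqrt() * self.gamma + self.beta


class MultiheadSelfAttention(Module):
    """Bidirectional (unmasked) scaled dot-product self-attention."""

    def __init__(self, embed_dim: int, n_heads: int, rng: np.random.Generator):
        if embed_dim % n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.head_dim = embed_dim // n_heads
        self.qkv = Linear(embed_dim, 3 * embed_dim, rng)
        self.out = Linear(embed_dim, embed_dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        B, N, E = x.shape
        H, D = self.n_heads, self.head_dim
        qkv = self.qkv(x)                              # (B, N, 3E)
        qkv = qkv.reshape(B, N, 3, H, D).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]               # (B, H, N, D)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(D))
        attn = scores.softmax(axis=-1)
        ctx = attn @ v                                  # (B, H, N, D)
        ctx = ctx.transpose(0, 2, 1, 3).reshape(B, N, E)
        return self.out(ctx)


class TransformerBlock(Module):
    """Pre-norm transformer block: attention and a GELU MLP, both residual."""

    def __init__(self, embed_dim: int, n_heads: int, rng: np.random.Generator,
                 mlp_ratio: int = 2):
        self.norm1 = LayerNorm(embed_dim)
        self.attn = MultiheadSelfAttention(embed_dim, n_heads, rng)
        self.norm2 = LayerNorm(embed_dim)
        self.fc1 = Linear(embed_dim, mlp_ratio * embed_dim, rng)
        self.fc2 = Linear(mlp_ratio * embed_dim, embed_dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.fc2(self.fc1(self.norm2(x)).gelu())
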