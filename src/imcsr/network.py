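"""Residual channel-attention separation network.

The model maps a superimposed grayscale SR image (or a triple of
consecutive frames in temporal-continuity mode) to one output channel
per structure class.  Layout:

    stem conv-GELU
      -> n_groups residual groups, each of n_blocks residual
         channel-attention blocks plus a group-level additive skip
      -> conv-GELU (feature reorganization)
      -> conv + sigmoid (per-class output)

Each residual channel-attention block is conv-GELU, conv-GELU, channel
attention (global average pool -> bottleneck -> sigmoid gates), plus an
additive skip from the block input.  There is no long skip across
groups and no upsampling head: input and output share the same spatial
resolution, so all convolutions are same-padded.

Everything runs on the package's own numpy autodiff engine; weights are
He-initialized from an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterator

import numpy as np

from .autograd import Tensor, conv2d, gelu, sigmoid

__all__ = [
    "ModelConfig",
    "SeparationModel",
    "build_model",
    "forward",
    "channel_attention",
    "count_parameters",
    "Conv2d",
    "ChannelAttention",
    "RCAB",
    "ResidualGroup",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``in_channels`` is 1 for static separation and 3 in
    temporal-continuity mode; ``out_channels`` is the number of
    structure classes C (1 for a single-structure model).
    """

    n_groups: int = 5
    n_blocks: int = 10
    n_features: int = 64
    reduction: int = 16
    in_channels: int = 1
    out_channels: int = 3
    kernel: int = 3

    def __post_init__(self):
        for name in ("n_groups", "n_blocks", "n_features", "reduction",
                     "in_channels", "out_channels", "kernel"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise ValueError(f"ModelConfig.{name} must be a positive integer, got {v!r}")
        if self.kernel % 2 == 0:
            raise ValueError("kernel size must be odd (same-padding contract)")

    @property
    def bottleneck(self) -> int:
        return max(1, self.n_features // self.reduction)


class Module:
    """Tiny layer base: parameter discovery by attribute walk."""

    def parameters(self) -> Iterator[Tensor]:
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                yield v
            elif isinstance(v, Module):
                yield from v.parameters()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.parameters()


def _he_conv(rng: np.random.Generator, c_out: int, c_in: int, k: int) -> Tensor:
    std = np.sqrt(2.0 / (c_in * k * k))
    return Tensor(rng.normal(0.0, std, size=(c_out, c_in, k, k)).astype(np.float32),
                  requires_grad=True)


class Conv2d(Module):
    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int, k: int):
        self.weight = _he_conv(rng, c_out, c_in, k)
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)


class ConvGELU(Module):
    """One 3x3 (configurable) convolution followed by GELU."""

    def __init__(self, rng, c_in: int, c_out: int, k: int):
        self.conv = Conv2d(rng, c_in, c_out, k)

    def __call__(self, x: Tensor) -> Tensor:
        return gelu(self.conv(x))


class ChannelAttention(Module):
    """Squeeze-and-excitation gating over feature channels.

    Global spatial average per channel, a GELU bottleneck of width
    ``max(1, F // reduction)``, expansion back to F, sigmoid; each input
    channel is multiplied by its scalar gate in (0, 1).
    """

    def __init__(self, rng, n_features: int, reduction: int):
        fb = max(1, n_features // reduction)
        std1 = np.sqrt(2.0 / n_features)
        std2 = np.sqrt(2.0 / fb)
        self.w_squeeze = Tensor(
            rng.normal(0.0, std1, size=(n_features, fb)).astype(np.float32), requires_grad=True
        )
        self.b_squeeze = Tensor(np.zeros(fb, dtype=np.float32), requires_grad=True)
        self.w_expand = Tensor(
            rng.normal(0.0, std2, size=(fb, n_features)).astype(np.float32), requires_grad=True
        )
        self.b_expand = Tensor(np.zeros(n_features, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        n, f = x.shape[0], x.shape[1]
        pooled = x.mean(axis=(2, 3))                        # (N, F)
        hidden = gelu(pooled @ self.w_squeeze + self.b_squeeze)
        gates = sigmoid(hidden @ self.w_expand + self.b_expand)  # (N, F)
        return x * gates.reshape(n, f, 1, 1)


def channel_attention(features, attention: ChannelAttention) -> Tensor:
    """Apply a channel-attention module to a (N, F, H, W) or (F, H, W) stack."""
    x = features if isinstance(features, Tensor) else Tensor(features)
    squeeze = x.ndim == 3
    if squeeze:
        x = x.reshape(1, *x.shape)
    out = attention(x)
    return out.reshape(*out.shape[1:]) if squeeze else out


class RCAB(Module):
    """Residual channel-attention block: conv-GELU x2 + attention + skip."""

    def __init__(self, rng, n_features: int, reduction: int, k: int):
        self.body1 = ConvGELU(rng, n_features, n_features, k)
        self.body2 = ConvGELU(rng, n_features, n_features, k)
        self.attention = ChannelAttention(rng, n_features, reduction)

    def __call__(self, x: Tensor) -> Tensor:
        return x + self.attention(self.body2(self.body1(x)))


class ResidualGroup(Module):
    """A stack of RCABs with an additive skip from group input to output."""

    def __init__(self, rng, n_blocks: int, n_features: int, reduction: int, k: int):
        self.blocks = [RCAB(rng, n_features, reduction, k) for _ in range(n_blocks)]

    def __call__(self, x: Tensor) -> Tensor:
        y = x
        for block in self.blocks:
            y = block(y)
        return x + y


class SeparationModel(Module):
    """The full separation network (see module docstring for the layout)."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        k = config.kernel
        self.stem = ConvGELU(rng, config.in_channels, config.n_features, k)
        self.groups = [
            ResidualGroup(rng, config.n_blocks, config.n_features, config.reduction, k)
            for _ in range(config.n_groups)
        ]
        self.tail = ConvGELU(rng, config.n_features, config.n_features, k)
        self.out_conv = Conv2d(rng, config.n_features, config.out_channels, k)

    def __call__(self, x: Tensor | np.ndarray) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
        squeeze = x.ndim == 3
        if squeeze:
            x = x.reshape(1, *x.shape)
        if x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"model expects {self.config.in_channels} input channel(s), got "
                f"{x.shape[1]} — check static vs temporal-continuity packing"
            )
        if min(x.shape[2], x.shape[3]) < self.config.kernel:
            raise ValueError("input spatial dimensions must be >= kernel size")
        y = self.stem(x)
        for group in self.groups:
            y = group(y)
        y = sigmoid(self.out_conv(self.tail(y)))
        return y.reshape(*y.shape[1:]) if squeeze else y

    # -- persistence -------------------------------------------------

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = list(self.parameters())
        if len(params) != len(arrays):
            raise ValueError("checkpoint parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("checkpoint parameter shape mismatch")
            p.data = a.astype(p.data.dtype, copy=True)

    def save(self, path) -> None:
        """Save weights (.npz) with the config serialized alongside."""
        arrays = {f"p{i}": a for i, a in enumerate(self.state_arrays())}
        np.savez(path, **arrays)
        cfg_path = str(path)
        cfg_path = cfg_path[: -len(".npz")] if cfg_path.endswith(".npz") else cfg_path
        with open(cfg_path + ".config.txt", "w") as fh:
            for key, value in asdict(self.config).items():
                fh.write(f"{key}: {value}\n")

    @classmethod
    def load(cls, path) -> "SeparationModel":
        cfg_path = str(path)
        cfg_path = cfg_path[: -len(".npz")] if cfg_path.endswith(".npz") else cfg_path
        fields: dict[str, int] = {}
        with open(cfg_path + ".config.txt") as fh:
            for line in fh:
                key, _, value = line.partition(":")
                fields[key.strip()] = int(value)
        model = cls(ModelConfig(**fields), seed=0)
        with np.load(path) as data:
            model.load_state_arrays([data[f"p{i}"] for i in range(len(data.files))])
        return model


def build_model(config: ModelConfig, seed: int = 0) -> SeparationModel:
    """Construct a seeded separation model (identical weights for equal seeds)."""
    return SeparationModel(config, seed=seed)


def forward(model: SeparationModel, x) -> np.ndarray:
    """Run the network on a (C_in, H, W) stack, returning a (C_out, H, W) array."""
    return model(np.asarray(x, dtype=np.float32)).data


def count_parameters(model: SeparationModel) -> int:
    return sum(p.data.size for p in model.parameters())
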