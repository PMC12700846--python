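"""Module system: parameter containers and common layers."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import tensor as T
from .tensor import Parameter

__all__ = [
    "Module",
    "ModuleList",
    "Sequential",
    "Conv2d",
    "DepthwiseConv2d",
    "Linear",
    "ChannelScale",
    "ChannelConv1d",
    "ReLU",
    "GELU",
]


def kaiming_uniform(rng: np.random.Generator, shape, fan_in: int, dtype=np.float32) -> np.ndarray:
    bound = np.sqrt(6.0 / max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Module:
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        # attributes starting with "_" are not registered (plain references)
        for name, value in vars(self).items():
            if name.startswith("_"):
                continue
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def num_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)}, unexpected={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name])
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.astype(p.data.dtype, copy=True)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class ModuleList(Module):
    def __init__(self, modules=()):
        for i, m in enumerate(modules):
            setattr(self, f"m{i}", m)
        self._n = len(tuple(modules)) if not isinstance(modules, (list, tuple)) else len(modules)

    def __len__(self):
        return self._n

    def __iter__(self):
        return (getattr(self, f"m{i}") for i in range(self._n))

    def __getitem__(self, i: int):
        return getattr(self, f"m{i % self._n if i < 0 else i}")

    def named_parameters(self, prefix: str = ""):
        for i in range(self._n):
            yield from getattr(self, f"m{i}").named_parameters(f"{prefix}{i}.")


class Sequential(Module):
    def __init__(self, *modules):
        self.layers = ModuleList(list(modules))

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class ReLU(Module):
    def forward(self, x):
        return T.relu(x)


class GELU(Module):
    def forward(self, x):
        return T.gelu(x)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, dilation: int = 1,
                 bias: bool = True, dtype=np.float32):
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(kaiming_uniform(rng, (out_ch, in_ch, kernel, kernel), fan_in, dtype))
        self.bias = Parameter(np.zeros(out_ch, dtype=dtype)) if bias else None
        self.stride, self.padding, self.dilation = stride, padding, dilation

    def forward(self, x):
        return T.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, dilation=self.dilation)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel: int, rng: np.random.Generator,
                 padding: int = 0, dilation: int = 1, bias: bool = True, dtype=np.float32):
        self.weight = Parameter(kaiming_uniform(rng, (channels, kernel, kernel), kernel * kernel, dtype))
        self.bias = Parameter(np.zeros(channels, dtype=dtype)) if bias else None
        self.padding, self.dilation = padding, dilation

    def forward(self, x):
        return T.depthwise_conv2d(x, self.weight, self.bias,
                                  padding=self.padding, dilation=self.dilation)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True, dtype=np.float32):
        self.weight = Parameter(kaiming_uniform(rng, (in_features, out_features), in_features, dtype))
        self.bias = Parameter(np.zeros(out_features, dtype=dtype)) if bias else None

    def forward(self, x):
        out = T.matmul(x, self.weight)
        if self.bias is not None:
            out = out + self.bias
        return out


class ChannelScale(Module):
    """1x1 depth-wise projection: per-channel scale and bias along axis 1.

    Works on any (B, C, ...) layout; this is the depth-wise counterpart of a
    dense projection, used for token Q/K/V projections and cheap upsample heads.
    """

    def __init__(self, channels: int, rng: np.random.Generator | None = None,
                 init: str = "random", dtype=np.float32):
        if init == "identity" or rng is None:
            w = np.ones(channels, dtype=dtype)
        else:
            w = (1.0 + 0.1 * rng.standard_normal(channels)).astype(dtype)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(channels, dtype=dtype))

    def forward(self, x):
        shape = (1, x.shape[1]) + (1,) * (x.ndim - 2)
        return x * self.weight.reshape(shape) + self.bias.reshape(shape)


class ChannelConv1d(Module):
    """ECA-style 1D convolution along the channel axis with circular padding.

    A single shared kernel of odd size ``k`` slides over the channel vector of
    each sample; input/output shape (B, C).
    """

    def __init__(self, k: int, rng: np.random.Generator, dtype=np.float32):
        if k % 2 == 0 or k < 1:
            raise ValueError(f"channel kernel must be odd and positive, got {k}")
        self.k = k
        self.weight = Parameter(kaiming_uniform(rng, (k,), k, dtype))
        self.bias = Parameter(np.zeros(1, dtype=dtype))

    def forward(self, x):
        c = x.shape[-1]
        pad = self.k // 2
        xp = T.pad_circular_1d(x, pad, axis=-1)
        out = None
        for j in range(self.k):
            idx = (slice(None),) * (x.ndim - 1) + (slice(j, j + c),)
            term = xp[idx] * self.weight[j:j + 1]
            out = term if out is None else out + term
        return out + self.bias
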