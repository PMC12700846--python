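"""U-Net backbone, attention-bridge attachment and parameter accounting."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields, replace

import numpy as np

from . import nn
from .attention import GLCSABlock, GLCSAConfig
from .errors import ConfigError, SchemaError
from .nn import Tensor

__all__ = [
    "NetworkSpec",
    "UNet",
    "build_unet",
    "attach_glcsa",
    "count_parameters",
    "param_overhead",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class NetworkSpec:
    """Backbone description: ``stages`` encoder levels (incl. bottleneck),
    channel width doubling from ``base_channels``."""

    stages: int = 5
    base_channels: int = 64
    in_channels: int = 1
    out_classes: int = 3
    placement: str = "none"  # none | bridge | per_skip

    def validate(self) -> "NetworkSpec":
        if self.stages < 2:
            raise ConfigError("need at least one encoder stage plus a bottleneck")
        if self.base_channels < 1 or self.in_channels < 1 or self.out_classes < 2:
            raise ConfigError("invalid channel/class configuration")
        if self.placement not in {"none", "bridge", "per_skip"}:
            raise ConfigError(f"unknown placement {self.placement!r}")
        return self

    @property
    def channels(self) -> list[int]:
        return [self.base_channels * 2**i for i in range(self.stages)]

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise SchemaError(f"unknown network config keys: {sorted(unknown)}")
        return cls(**d).validate()


class _DoubleConv(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, rng, dtype=np.float32):
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, rng, padding=1, dtype=dtype)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, rng, padding=1, dtype=dtype)

    def forward(self, x):
        return nn.relu(self.conv2(nn.relu(self.conv1(x))))


class _UpBlock(nn.Module):
    """Bilinear upsample + channel-halving conv, then double conv on the
    concatenation with the skip feature."""

    def __init__(self, in_ch: int, out_ch: int, rng, dtype=np.float32):
        self.up = nn.Conv2d(in_ch, out_ch, 3, rng, padding=1, dtype=dtype)
        self.conv = _DoubleConv(2 * out_ch, out_ch, rng, dtype=dtype)

    def forward(self, x, skip):
        x = nn.bilinear_resize(x, (skip.shape[2], skip.shape[3]))
        x = nn.relu(self.up(x))
        return self.conv(nn.concatenate([skip, x], axis=1))


class UNet(nn.Module):
    """Vanilla encoder-decoder with skip connections and a 3-class head.

    An optional attention bridge transforms the list of skip features before
    decoding; any callable mapping ``list[Tensor] -> list[Tensor]`` with
    matching shapes can be hooked in via :meth:`set_skip_transform`, which is
    how GLCSA (and, in principle, other backbones' skip providers) attach.
    """

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator, dtype=np.float32):
        spec.validate()
        self.spec = spec
        chans = spec.channels
        self.encoders = nn.ModuleList([
            _DoubleConv(spec.in_channels if i == 0 else chans[i - 1], chans[i], rng, dtype)
            for i in range(spec.stages)])
        self.decoders = nn.ModuleList([
            _UpBlock(chans[i + 1], chans[i], rng, dtype)
            for i in reversed(range(spec.stages - 1))])
        self.head = nn.Conv2d(chans[0], spec.out_classes, 1, rng, dtype=dtype)
        self.glcsa: nn.Module | None = None
        self.glcsa_cfg: GLCSAConfig | None = None
        self._skip_transform = None

    # -- hook interface --------------------------------------------------
    def set_skip_transform(self, transform) -> None:
        self._skip_transform = transform

    def encode(self, x: Tensor):
        skips = []
        for i, enc in enumerate(self.encoders):
            x = enc(x)
            if i < self.spec.stages - 1:
                skips.append(x)
                x = nn.max_pool2d(x, 2)
        return x, skips

    def decode(self, x: Tensor, skips: list[Tensor]) -> Tensor:
        for dec, skip in zip(self.decoders, reversed(skips)):
            x = dec(x, skip)
        return self.head(x)

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        down = 2 ** (self.spec.stages - 1)
        if h % down or w % down:
            raise ConfigError(f"extent {(h, w)} not divisible by 2^{self.spec.stages - 1}")
        bottom, skips = self.encode(x)
        if self._skip_transform is not None:
            new_skips = self._skip_transform(skips)
            for a, b in zip(new_skips, skips):
                if a.shape != b.shape:
                    raise ConfigError("skip transform changed feature shapes")
            skips = new_skips
        return self.decode(bottom, skips)


def build_unet(spec: NetworkSpec, rng: np.random.Generator | int = 0,
               dtype=np.float32) -> UNet:
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    return UNet(replace(spec), rng, dtype=dtype)  # copy: attach mutates placement


def attach_glcsa(net: UNet, cfg: GLCSAConfig, placement: str = "bridge",
                 rng: np.random.Generator | int = 0) -> UNet:
    """Route the first n skip features through GLCSA; output shapes unchanged."""
    if placement not in {"bridge", "per_skip"}:
        raise ConfigError(f"placement must be 'bridge' or 'per_skip', got {placement!r}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    skip_channels = net.spec.channels[:-1]
    if placement == "bridge":
        block = GLCSABlock(skip_channels, cfg, rng)
        net.glcsa = block
        net.set_skip_transform(block)
    else:  # one single-stage block per skip connection
        blocks = nn.ModuleList([GLCSABlock([c], cfg, rng) for c in skip_channels])
        net.glcsa = blocks

        def transform(skips, _blocks=blocks):
            return [b([s])[0] for b, s in zip(_blocks, skips)]

        net.set_skip_transform(transform)
    net.glcsa_cfg = cfg
    net.spec.placement = placement
    return net


def count_parameters(net: nn.Module) -> int:
    return net.num_parameters()


def param_overhead(base: nn.Module | int, augmented: nn.Module | int) -> float:
    """Percent increase in trainable parameters: 100*(P1-P0)/P0."""
    p0 = base if isinstance(base, (int, np.integer)) else count_parameters(base)
    p1 = augmented if isinstance(augmented, (int, np.integer)) else count_parameters(augmented)
    if p0 <= 0:
        raise ValueError("baseline has no parameters")
    return 100.0 * (p1 - p0) / p0


# -- checkpointing -------------------------------------------------------------


def save_checkpoint(net: UNet, path) -> None:
    meta = {
        "spec": asdict(net.spec),
        "glcsa": asdict(net.glcsa_cfg) if net.glcsa_cfg is not None else None,
    }
    state = {f"param/{k}": v for k, v in net.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path, rng: np.random.Generator | int = 0) -> UNet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
    spec = NetworkSpec(**meta["spec"])
    placement = spec.placement
    spec.placement = "none"
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    net = build_unet(spec, rng)
    if meta["glcsa"] is not None:
        attach_glcsa(net, GLCSAConfig(**meta["glcsa"]), placement, rng)
    net.load_state_dict(state)
    return net
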