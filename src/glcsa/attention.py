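"""Global-local channel/spatial attention (GLCSA) block and its submodules.

The block sits between a U-Net encoder and decoder.  Skip features from the
first ``n`` stages are embedded into a shared token space, refined by four
attention maps — global channel (``Ygc``), global spatial (``Ygs``), local
channel (``Ylc``) and local spatial (``Yls``) — with a slice-interaction step
that attends across the batch axis (repurposed as pseudo-depth), and finally
fused with the untouched tokens through a learned convex combination before
being upsampled back to each stage's resolution.

Shapes follow the ``(b, c, h, w)`` convention where ``b`` is the slice count
of one subject volume (pseudo-depth).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from . import nn
from .errors import ConfigError
from .nn import Tensor

__all__ = [
    "GLCSAConfig",
    "scaled_dot_attention",
    "multi_head_attention",
    "MultiscaleEmbedding",
    "GlobalChannelAttention",
    "GlobalSpatialAttention",
    "LocalChannelAttention",
    "LocalSpatialAttention",
    "SliceInteraction",
    "FusionWeights",
    "combine_glca",
    "combine_glsa",
    "fuse_maps",
    "GLCSABlock",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_CHOICES = {
    "embedding_mode": {"patch", "global"},
    "fusion_mode": {"weighted_avg"},
    "attention_order": {"glca_first", "glsa_first"},
    "module_fusion": {"sequential", "sum", "parallel"},
    "local_mode": {"la1", "la2"},
    "lca_window": {"global", "grid"},
}


@dataclass
class GLCSAConfig:
    """Every architectural knob of the attention block.

    Defaults follow the best-performing configuration: patch size 8,
    1 channel-attention head, 4 spatial-attention heads, sequential module
    fusion with the channel path first, and slice interaction enabled.
    """

    ps: int = 8
    glca_heads: int = 1
    glsa_heads: int = 4
    lca_kernel: int = 3
    embedding_mode: str = "patch"
    fusion_mode: str = "weighted_avg"
    attention_order: str = "glca_first"
    module_fusion: str = "sequential"
    sim_enabled: bool = True
    local_mode: str = "la1"
    enable_glca: bool = True
    enable_glsa: bool = True
    lsa_residual: bool = False
    lca_window: str = "global"
    lsa_reduction: int = 4

    def validate(self) -> "GLCSAConfig":
        if self.ps < 1 or (self.ps & (self.ps - 1)) != 0:
            raise ConfigError(f"patch size must be a positive power of two, got {self.ps}")
        if self.lca_kernel % 2 == 0 or self.lca_kernel < 1:
            raise ConfigError(f"lca_kernel must be odd, got {self.lca_kernel}")
        if self.glca_heads < 1 or self.glsa_heads < 1:
            raise ConfigError("head counts must be >= 1")
        if self.lsa_reduction < 1:
            raise ConfigError("lsa_reduction must be >= 1")
        for name, allowed in _CHOICES.items():
            value = getattr(self, name)
            if value not in allowed:
                raise ConfigError(f"{name} must be one of {sorted(allowed)}, got {value!r}")
        return self

    @classmethod
    def from_dict(cls, d: dict) -> "GLCSAConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            from .errors import SchemaError

            raise SchemaError(f"unknown glcsa config keys: {sorted(unknown)}")
        return cls(**d).validate()


# ---------------------------------------------------------------------------
# attention primitives
# ---------------------------------------------------------------------------


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor, scale: float):
    """Scaled dot-product attention.

    ``q`` (..., Lq, D), ``k`` (..., Lk, D), ``v`` (..., Lk, Dv); returns
    ``(output, weights)`` with row-stochastic ``weights`` of shape
    (..., Lq, Lk).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if q.shape[-1] != k.shape[-1] or k.shape[-2] != v.shape[-2]:
        raise ValueError(
            f"non-conformable attention shapes q={q.shape} k={k.shape} v={v.shape}")
    logits = nn.matmul(q, k.swapaxes(-1, -2)) * float(scale)
    weights = nn.softmax(logits, axis=-1)
    return nn.matmul(weights, v), weights


def _split_heads(x: Tensor, heads: int) -> Tensor:
    """(..., L, D) -> (..., H, L, D/H)."""
    *lead, length, dim = x.shape
    if dim % heads:
        raise ConfigError(f"head count {heads} does not divide dimension {dim}")
    x = x.reshape(*lead, length, heads, dim // heads)
    nd = x.ndim
    return x.swapaxes(nd - 3, nd - 2)


def _merge_heads(x: Tensor) -> Tensor:
    """(..., H, L, Dh) -> (..., L, H*Dh)."""
    nd = x.ndim
    x = x.swapaxes(nd - 3, nd - 2)
    *lead, length, heads, dh = x.shape
    return x.reshape(*lead, length, heads * dh)


def multi_head_attention(q: Tensor, k: Tensor, v: Tensor, heads: int,
                         scale: float | None = None):
    """Multi-head scaled dot-product attention over the last two axes.

    Channels are split into ``heads`` groups, attended independently and
    re-concatenated.  Returns ``(output, weights)`` with per-head weights of
    shape (..., H, Lq, Lk).
    """
    qh, kh, vh = (_split_heads(t, heads) for t in (q, k, v))
    if scale is None:
        scale = 1.0 / np.sqrt(qh.shape[-1])
    out, w = scaled_dot_attention(qh, kh, vh, scale)
    return _merge_heads(out), w


# ---------------------------------------------------------------------------
# multiscale token embedding
# ---------------------------------------------------------------------------


class MultiscaleEmbedding(nn.Module):
    """Pool each encoder stage into a shared token grid and project depth-wise.

    Stage ``i`` (1-based) of spatial extent (H/2^(i-1), W/2^(i-1)) is pooled
    with kernel = stride = Ps/2^(i-1) (patch mode) or resized to the common
    token grid by bilinear interpolation (global mode), flattened to
    (b, C_i, P) and passed through a 1x1 depth-wise projection.
    """

    def __init__(self, channels: list[int], cfg: GLCSAConfig,
                 rng: np.random.Generator, dtype=np.float32):
        self.cfg = cfg
        self.channels = list(channels)
        self.projs = nn.ModuleList([nn.ChannelScale(c, rng, dtype=dtype) for c in channels])

    def forward(self, feats: list[Tensor]):
        cfg = self.cfg
        n = len(self.channels)
        if len(feats) != n:
            raise ConfigError(f"expected {n} stages, got {len(feats)}")
        h0, w0 = feats[0].shape[2], feats[0].shape[3]
        if h0 % cfg.ps or w0 % cfg.ps:
            raise ConfigError(f"stage-1 extent {(h0, w0)} not divisible by patch size {cfg.ps}")
        hp, wp = h0 // cfg.ps, w0 // cfg.ps
        tokens = []
        for i, (f, proj) in enumerate(zip(feats, self.projs)):
            b, c, h, w = f.shape
            if c != self.channels[i]:
                raise ConfigError(f"stage {i + 1} has {c} channels, expected {self.channels[i]}")
            if cfg.embedding_mode == "patch":
                if cfg.ps % (2**i):
                    raise ConfigError(
                        f"per-stage patch size Ps/2^{i} is not an integer for Ps={cfg.ps}")
                p_si = cfg.ps // (2**i)
                if h % p_si or w % p_si:
                    raise ConfigError(f"stage {i + 1} extent {(h, w)} not divisible by {p_si}")
                pooled = nn.avg_pool2d(f, p_si)
                if pooled.shape[2:] != (hp, wp):
                    raise ConfigError(
                        f"stage {i + 1} token grid {pooled.shape[2:]} != shared grid {(hp, wp)}")
            else:  # global: resize whole map onto the token grid
                pooled = nn.bilinear_resize(f, (hp, wp))
            tokens.append(proj(pooled.reshape(b, c, hp * wp)))
        return tokens, (hp, wp)


# ---------------------------------------------------------------------------
# global attention
# ---------------------------------------------------------------------------


class GlobalChannelAttention(nn.Module):
    """Channel-by-channel similarity attention over multiscale tokens.

    Keys/values come from the channel-wise concatenation of all stages'
    layer-normalized tokens; each stage queries with its own tokens.  All
    projections are 1x1 depth-wise.  ``Ygc`` rows are softmax-normalized over
    the concatenated channel axis and scaled by 1/sqrt(C_c).
    """

    def __init__(self, channels: list[int], heads: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.channels = list(channels)
        self.heads = heads
        self.c_cat = sum(channels)
        self.q_projs = nn.ModuleList([nn.ChannelScale(c, rng, dtype=dtype) for c in channels])
        self.k_proj = nn.ChannelScale(self.c_cat, rng, dtype=dtype)
        self.v_proj = nn.ChannelScale(self.c_cat, rng, dtype=dtype)
        self.out_projs = nn.ModuleList([nn.ChannelScale(c, rng, dtype=dtype) for c in channels])

    def forward(self, tokens: list[Tensor], values: list[Tensor] | None = None):
        if len(tokens) != len(self.channels):
            raise ConfigError("token stage count mismatch")
        p = tokens[0].shape[-1]
        for t in tokens:
            if t.shape[-1] != p:
                raise ValueError("tokens must share the same token count P")
        if p % self.heads:
            raise ConfigError(f"glca_heads={self.heads} does not divide token count {p}")
        normed = [nn.layer_norm(t, axis=-1) for t in tokens]
        t_c = nn.concatenate(normed, axis=1)  # (b, C_c, P)
        k = self.k_proj(t_c)
        v_src = nn.concatenate(values, axis=1) if values is not None else t_c
        v = self.v_proj(v_src)
        scale = 1.0 / np.sqrt(self.c_cat)
        ygc_list, out_list = [], []
        kh = _split_heads(k, self.heads)  # (b, H, C_c, P/H)
        vh = _split_heads(v, self.heads)
        for t, qp, op, c in zip(normed, self.q_projs, self.out_projs, self.channels):
            qh = _split_heads(qp(t), self.heads)  # (b, H, C_i, P/H)
            out_h, w = scaled_dot_attention(qh, kh, vh, scale)  # w: (b, H, C_i, C_c)
            out = op(_merge_heads(out_h))
            ygc = w.mean(axis=1)  # average heads -> (b, C_i, C_c), rows still sum to 1
            ygc_list.append(ygc)
            out_list.append(out)
        return ygc_list, out_list


class GlobalSpatialAttention(nn.Module):
    """Token-position similarity attention shared across stages.

    Queries and keys are the channel-wise concatenation of all normalized
    tokens (multi-head over channels, d_k = C_c / H_c); each stage's tokens
    act as values.  ``Ygs`` is row-stochastic of shape (b, H, P, P).
    """

    def __init__(self, channels: list[int], heads: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.channels = list(channels)
        self.heads = heads
        self.c_cat = sum(channels)
        if self.c_cat % heads:
            raise ConfigError(f"glsa_heads={heads} does not divide C_c={self.c_cat}")
        for c in channels:
            if c % heads:
                raise ConfigError(f"glsa_heads={heads} does not divide stage channels {c}")
        self.q_proj = nn.ChannelScale(self.c_cat, rng, dtype=dtype)
        self.k_proj = nn.ChannelScale(self.c_cat, rng, dtype=dtype)
        self.v_projs = nn.ModuleList([nn.ChannelScale(c, rng, dtype=dtype) for c in channels])
        self.out_projs = nn.ModuleList([nn.ChannelScale(c, rng, dtype=dtype) for c in channels])

    def forward(self, tokens: list[Tensor], values: list[Tensor] | None = None):
        if len(tokens) != len(self.channels):
            raise ConfigError("token stage count mismatch")
        normed = [nn.layer_norm(t, axis=-1) for t in tokens]
        t_c = nn.concatenate(normed, axis=1)  # (b, C_c, P)
        d_k = self.c_cat // self.heads
        # split channels into heads: (b, C_c, P) -> (b, H, d_k, P)
        q = _split_channel_heads(self.q_proj(t_c), self.heads)
        k = _split_channel_heads(self.k_proj(t_c), self.heads)
        logits = nn.matmul(q.swapaxes(-1, -2), k) * float(1.0 / np.sqrt(d_k))  # (b,H,P,P)
        ygs = nn.softmax(logits, axis=-1)
        src = values if values is not None else normed
        out_list = []
        for v_src, vp, op in zip(src, self.v_projs, self.out_projs):
            v = _split_channel_heads(vp(v_src), self.heads)  # (b, H, C_i/H, P)
            out_h = nn.matmul(v, ygs.swapaxes(-1, -2))  # position p <- sum_q Ygs[p,q] v[:,q]
            out_list.append(op(_merge_channel_heads(out_h)))
        return ygs, out_list


def _split_channel_heads(x: Tensor, heads: int) -> Tensor:
    """(b, C, P) -> (b, H, C/H, P)."""
    b, c, p = x.shape
    if c % heads:
        raise ConfigError(f"head count {heads} does not divide channels {c}")
    return x.reshape(b, heads, c // heads, p)


def _merge_channel_heads(x: Tensor) -> Tensor:
    b, h, ch, p = x.shape
    return x.reshape(b, h * ch, p)


# ---------------------------------------------------------------------------
# local attention
# ---------------------------------------------------------------------------


class LocalChannelAttention(nn.Module):
    """ECA-style channel gating: pool -> 1D channel conv -> sigmoid -> gate.

    Default window is the whole map (``Ylc`` shape (b, c, 1, 1)); optional
    ``grid`` window pools over a Ps x Ps grid of windows and gates each window
    with its own channel weights.
    """

    def __init__(self, k: int, rng: np.random.Generator,
                 window: str = "global", grid: int = 8, dtype=np.float32):
        if k % 2 == 0:
            raise ConfigError(f"LCA kernel must be odd, got {k}")
        self.conv = nn.ChannelConv1d(k, rng, dtype=dtype)
        self.window = window
        self.grid = grid

    def forward(self, f: Tensor):
        b, c, h, w = f.shape
        if self.window == "global":
            gap = f.mean(axis=(2, 3))  # (b, c)
            ylc = nn.sigmoid(self.conv(gap)).reshape(b, c, 1, 1)
            return ylc, f * ylc + f
        # grid of local windows
        gh = min(self.grid, h)
        gw = min(self.grid, w)
        if h % gh or w % gw:
            raise ConfigError(f"extent {(h, w)} not divisible into a {gh}x{gw} window grid")
        pooled = nn.avg_pool2d(f, h // gh) if h // gh == w // gw else None
        if pooled is None:
            raise ConfigError("grid windows must be square")
        z = pooled.transpose(0, 2, 3, 1)  # (b, gh, gw, c)
        ylc_grid = nn.sigmoid(self.conv(z)).transpose(0, 3, 1, 2)  # (b, c, gh, gw)
        rh, rw = h // gh, w // gw
        up = ylc_grid.reshape(b, c, gh, 1, gw, 1)
        ones = Tensor(np.ones((1, 1, 1, rh, 1, rw), dtype=f.dtype))
        ylc_full = (up * ones).reshape(b, c, h, w)
        return ylc_grid, f * ylc_full + f


class LocalSpatialAttention(nn.Module):
    """Inception-style dilated-convolution spatial gating.

    1x1 channel reduction, three depth-wise dilated branches (3x3/d1, 5x5/d2,
    7x7/d3, 'same' padding), concatenation to 4c' channels and a final 1x1
    reduction to a single sigmoid-bounded map ``Yls`` of shape (b, 1, h, w).
    ``F_s_l = F * Yls`` (no residual unless ``residual=True``).
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 reduction: int = 4, residual: bool = False, dtype=np.float32):
        c_red = max(channels // reduction, 1)
        self.reduce = nn.Conv2d(channels, c_red, 1, rng, dtype=dtype)
        self.branch1 = nn.DepthwiseConv2d(c_red, 3, rng, padding=1, dilation=1, dtype=dtype)
        self.branch2 = nn.DepthwiseConv2d(c_red, 5, rng, padding=4, dilation=2, dtype=dtype)
        self.branch3 = nn.DepthwiseConv2d(c_red, 7, rng, padding=9, dilation=3, dtype=dtype)
        self.out = nn.Conv2d(4 * c_red, 1, 1, rng, dtype=dtype)
        self.residual = residual

    def forward(self, f: Tensor):
        r = self.reduce(f)
        cat = nn.concatenate([r, self.branch1(r), self.branch2(r), self.branch3(r)], axis=1)
        yls = nn.sigmoid(self.out(cat))  # (b, 1, h, w)
        fsl = f * yls
        if self.residual:
            fsl = fsl + f
        return yls, fsl


class SliceInteraction(nn.Module):
    """Cross-slice attention along the batch (pseudo-depth) axis.

    The input (b, c, h, w) is reshaped so each spatial position carries a
    length-``b`` sequence of per-slice channel vectors; linear Q/K/V
    projections and multi-head dot-product attention mix information across
    slices.  No positional encoding, hence permutation equivariance along b.
    In ``la2`` mode every slice is treated as its own pseudo-depth-1 stack,
    degenerating to the value projection.
    """

    def __init__(self, channels: int, heads: int, rng: np.random.Generator,
                 la2: bool = False, dtype=np.float32):
        if channels % heads:
            raise ConfigError(f"SIM heads {heads} do not divide channels {channels}")
        self.heads = heads
        self.la2 = la2
        self.q = nn.Linear(channels, channels, rng, dtype=dtype)
        self.k = nn.Linear(channels, channels, rng, dtype=dtype)
        self.v = nn.Linear(channels, channels, rng, dtype=dtype)

    def forward(self, f: Tensor) -> Tensor:
        shape = f.shape
        b, c = shape[0], shape[1]
        x = f.reshape(b, c, -1).transpose(2, 0, 1)  # (n, b, c)
        if self.la2 or b == 1:
            out = self.v(x)  # singleton attention reduces to the value path
        else:
            out, _ = multi_head_attention(self.q(x), self.k(x), self.v(x), self.heads)
        return out.transpose(1, 2, 0).reshape(shape)


# ---------------------------------------------------------------------------
# combination and fusion
# ---------------------------------------------------------------------------


def combine_glca(f_c_l: Tensor, ygc: Tensor, context: Tensor | None = None) -> Tensor:
    """``Fl = Ygc (x) context + F_c_l`` — channel mixing plus residual.

    ``ygc`` is (b, c_out, c_in); ``context`` defaults to ``f_c_l`` (then the
    map must be square).  ``Ygc = 0`` returns ``f_c_l`` unchanged.
    """
    if context is None:
        context = f_c_l
    b, co, ci = ygc.shape
    if context.shape[1] != ci or f_c_l.shape[1] != co:
        raise ValueError(
            f"combine_glca shape mismatch: ygc {ygc.shape}, F_c_l {f_c_l.shape}, "
            f"context {context.shape}")
    spatial = f_c_l.shape[2:]
    mixed = nn.matmul(ygc, context.reshape(b, ci, -1)).reshape((b, co) + spatial)
    return mixed + f_c_l


def combine_glsa(f_s_l: Tensor, ygs: Tensor) -> Tensor:
    """``Fg = Ygs (x) F_s_l + F_s_l`` — spatial mixing plus residual.

    ``ygs`` is (b, p, p) or per-head (b, H, p, p) with channels split across
    heads; ``p`` must equal the flattened spatial extent of ``f_s_l``.
    """
    shape = f_s_l.shape
    b, c = shape[0], shape[1]
    p = int(np.prod(shape[2:])) if len(shape) > 2 else shape[2]
    flat = f_s_l.reshape(b, c, p)
    if ygs.ndim == 3:
        if ygs.shape != (b, p, p):
            raise ValueError(f"combine_glsa shape mismatch: ygs {ygs.shape}, p={p}")
        mixed = nn.matmul(flat, ygs.swapaxes(-1, -2))
    elif ygs.ndim == 4:
        heads = ygs.shape[1]
        if ygs.shape != (b, heads, p, p):
            raise ValueError(f"combine_glsa shape mismatch: ygs {ygs.shape}, p={p}")
        vh = _split_channel_heads(flat, heads)
        mixed = _merge_channel_heads(nn.matmul(vh, ygs.swapaxes(-1, -2)))
    else:
        raise ValueError("ygs must be 3- or 4-dimensional")
    return (mixed + flat).reshape(shape)


class FusionWeights(nn.Module):
    """Three raw parameters softmax-normalized onto the probability simplex."""

    def __init__(self, n: int = 3, dtype=np.float32):
        self.raw = nn.Parameter(np.zeros(n, dtype=dtype))

    @property
    def normalized(self) -> np.ndarray:
        e = np.exp(self.raw.data - self.raw.data.max())
        return e / e.sum()

    def forward(self) -> Tensor:
        return nn.softmax(self.raw, axis=-1)


def fuse_maps(fl: Tensor, fg: Tensor, f: Tensor, w: FusionWeights | Tensor) -> Tensor:
    """Convex combination ``Fgl = wlo*Fl + wgo*Fg + wt*F``."""
    if fl.shape != fg.shape or fl.shape != f.shape:
        raise ValueError(f"fuse_maps shape mismatch: {fl.shape}, {fg.shape}, {f.shape}")
    weights = w() if isinstance(w, FusionWeights) else w
    return fl * weights[0:1] + fg * weights[1:2] + f * weights[2:3]


# ---------------------------------------------------------------------------
# assembled block
# ---------------------------------------------------------------------------


class GLCSABlock(nn.Module):
    """The full encoder-decoder bridge.

    forward: embedding -> (GLCA / GLSA paths in the configured order and
    module fusion, slice interaction inside both paths) -> weighted fusion ->
    LN -> GeLU -> per-stage upsampling back to (C_i, H/2^(i-1), W/2^(i-1)).
    Output shapes always equal the input skip-feature shapes.
    """

    def __init__(self, channels: list[int], cfg: GLCSAConfig,
                 rng: np.random.Generator, dtype=np.float32):
        cfg.validate()
        self.cfg = cfg
        self.channels = list(channels)
        self.dtype = dtype
        self.embed = MultiscaleEmbedding(channels, cfg, rng, dtype=dtype)
        if cfg.enable_glca:
            self.gca = GlobalChannelAttention(channels, cfg.glca_heads, rng, dtype=dtype)
            self.lca = LocalChannelAttention(cfg.lca_kernel, rng, window=cfg.lca_window,
                                             grid=cfg.ps, dtype=dtype)
        if cfg.enable_glsa:
            self.gsa = GlobalSpatialAttention(channels, cfg.glsa_heads, rng, dtype=dtype)
            self.lsas = nn.ModuleList([
                LocalSpatialAttention(c, rng, reduction=cfg.lsa_reduction,
                                      residual=cfg.lsa_residual, dtype=dtype)
                for c in channels])
        if cfg.sim_enabled:
            # one SIM per stage, shared by the GLCA and GLSA paths to keep the
            # parameter overhead near the ~1% regime
            self.sims = nn.ModuleList([
                SliceInteraction(c, _sim_heads(c, cfg.glsa_heads), rng,
                                 la2=(cfg.local_mode == "la2"), dtype=dtype)
                for c in channels])
        self.fusion = FusionWeights(dtype=dtype)
        self.up_projs = nn.ModuleList([nn.ChannelScale(c, rng, dtype=dtype) for c in channels])
        self.last_maps: dict = {}

    # -- paths ---------------------------------------------------------------
    def _glca_path(self, maps: list[Tensor], grid) -> list[Tensor]:
        cfg = self.cfg
        b = maps[0].shape[0]
        tokens = [m.reshape(b, m.shape[1], -1) for m in maps]
        lca_out = [self.lca(m) for m in maps]
        self.last_maps["ylc"] = [y for y, _ in lca_out]
        fcl_maps = [f for _, f in lca_out]
        fcl_tokens = [f.reshape(b, f.shape[1], -1) for f in fcl_maps]
        ygc_list, mixed = self.gca(tokens, values=fcl_tokens)
        self.last_maps["ygc"] = ygc_list
        out = []
        for i, (fcl, mix) in enumerate(zip(fcl_maps, mixed)):
            fl = mix.reshape(fcl.shape) + fcl
            if cfg.sim_enabled:
                fl = fl + self.sims[i](fl)
            out.append(fl)
        return out

    def _glsa_path(self, maps: list[Tensor], grid) -> list[Tensor]:
        cfg = self.cfg
        b = maps[0].shape[0]
        tokens = [m.reshape(b, m.shape[1], -1) for m in maps]
        lsa_out = [lsa(m) for lsa, m in zip(self.lsas, maps)]
        self.last_maps["yls"] = [y for y, _ in lsa_out]
        fsl_maps = [f for _, f in lsa_out]
        fsl_tokens = [f.reshape(b, f.shape[1], -1) for f in fsl_maps]
        ygs, mixed = self.gsa(tokens, values=fsl_tokens)
        self.last_maps["ygs"] = ygs
        out = []
        for i, (fsl, mix) in enumerate(zip(fsl_maps, mixed)):
            fg = mix.reshape(fsl.shape) + fsl
            if cfg.sim_enabled:
                fg = fg + self.sims[i](fg)
            out.append(fg)
        return out

    # -- forward -------------------------------------------------------------
    def forward(self, feats: list[Tensor]) -> list[Tensor]:
        cfg = self.cfg
        self._check_stages(feats)
        tokens, grid = self.embed(feats)
        hp, wp = grid
        b = tokens[0].shape[0]
        maps0 = [t.reshape(b, t.shape[1], hp, wp) for t in tokens]

        paths = {"glca": (cfg.enable_glca, self._glca_path),
                 "glsa": (cfg.enable_glsa, self._glsa_path)}
        first = "glca" if cfg.attention_order == "glca_first" else "glsa"
        second = "glsa" if first == "glca" else "glca"

        if cfg.module_fusion == "sequential":
            en1, fn1 = paths[first]
            out1 = fn1(maps0, grid) if en1 else maps0
            en2, fn2 = paths[second]
            out2 = fn2(out1, grid) if en2 else out1
            results = {first: out1, second: out2}
        else:  # sum / parallel: both paths read the original tokens
            results = {}
            for name, (enabled, fn) in paths.items():
                results[name] = fn(maps0, grid) if enabled else maps0
            if cfg.module_fusion == "sum":
                summed = [a + g for a, g in zip(results["glca"], results["glsa"])]
                results = {"glca": summed, "glsa": summed}
        fl_list, fg_list = results["glca"], results["glsa"]

        outputs = []
        for fl, fg, f0, feat, proj in zip(fl_list, fg_list, maps0, feats, self.up_projs):
            fused = fuse_maps(fl, fg, f0, self.fusion)
            tok = nn.gelu(nn.layer_norm(fused.reshape(b, fused.shape[1], -1), axis=-1))
            tok = tok.reshape(fused.shape)
            up = nn.bilinear_resize(tok, (feat.shape[2], feat.shape[3]))
            outputs.append(proj(up))
        return outputs

    def _check_stages(self, feats: list[Tensor]) -> None:
        if len(feats) != len(self.channels):
            raise ConfigError(f"expected {len(self.channels)} stages, got {len(feats)}")
        h0, w0 = feats[0].shape[2], feats[0].shape[3]
        for i, f in enumerate(feats):
            expect = (f.shape[0], self.channels[i], h0 // 2**i, w0 // 2**i)
            if tuple(f.shape) != expect:
                raise ConfigError(f"stage {i + 1} shape {tuple(f.shape)} != expected {expect}")


def _sim_heads(channels: int, preferred: int) -> int:
    h = min(preferred, channels)
    while channels % h:
        h -= 1
    return max(h, 1)
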