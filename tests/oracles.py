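"""Naive, loop-based reference implementations used as independent oracles.

Everything here is deliberately written with explicit Python loops over
NumPy scalars/rows so it shares no code path with the vectorized package
implementations it is checked against.
"""

from __future__ import annotations

import numpy as np


def softmax_rows(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    for idx in np.ndindex(x.shape[:-1]):
        row = x[idx]
        e = np.exp(row - row.max())
        out[idx] = e / e.sum()
    return out


def naive_attention(q, k, v, scale):
    """Triple-loop scaled dot-product attention for 2D q/k/v."""
    lq, d = q.shape
    lk, dv = k.shape[0], v.shape[1]
    logits = np.zeros((lq, lk))
    for i in range(lq):
        for j in range(lk):
            s = 0.0
            for t in range(d):
                s += q[i, t] * k[j, t]
            logits[i, j] = s * scale
    weights = softmax_rows(logits)
    out = np.zeros((lq, dv))
    for i in range(lq):
        for j in range(lk):
            for t in range(dv):
                out[i, t] += weights[i, j] * v[j, t]
    return out, weights


def naive_multihead(q, k, v, heads, scale=None):
    """Per-head loop around :func:`naive_attention`; splits the last axis."""
    lq, d = q.shape
    dh = d // heads
    dv = v.shape[1] // heads
    outs, ws = [], []
    for h in range(heads):
        qh = q[:, h * dh:(h + 1) * dh]
        kh = k[:, h * dh:(h + 1) * dh]
        vh = v[:, h * dv:(h + 1) * dv]
        o, w = naive_attention(qh, kh, vh, scale if scale is not None else 1.0 / np.sqrt(dh))
        outs.append(o)
        ws.append(w)
    return np.concatenate(outs, axis=1), np.stack(ws)


def layer_norm_rows(x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    for idx in np.ndindex(x.shape[:-1]):
        row = x[idx]
        mu = row.mean()
        var = ((row - mu) ** 2).mean()
        out[idx] = (row - mu) / np.sqrt(var + eps)
    return out


def _chan_proj(x, weight, bias):
    """Per-channel scale+bias along axis 1 of (b, c, ...)."""
    out = np.empty_like(x)
    for c in range(x.shape[1]):
        out[:, c] = x[:, c] * weight[c] + bias[c]
    return out


def naive_gca(module, tokens):
    """Loop re-implementation of GlobalChannelAttention.forward (values=tokens)."""
    normed = [layer_norm_rows(t) for t in tokens]
    t_c = np.concatenate(normed, axis=1)
    k = _chan_proj(t_c, module.k_proj.weight.data, module.k_proj.bias.data)
    v = _chan_proj(t_c, module.v_proj.weight.data, module.v_proj.bias.data)
    scale = 1.0 / np.sqrt(module.c_cat)
    heads = module.heads
    ygc_list, out_list = [], []
    for t, qp, op in zip(normed, module.q_projs, module.out_projs):
        q = _chan_proj(t, qp.weight.data, qp.bias.data)
        b = q.shape[0]
        outs = np.zeros((b, q.shape[1], q.shape[2]))
        ygcs = np.zeros((b, heads, q.shape[1], v.shape[1]))
        ph = q.shape[2] // heads
        for bi in range(b):
            for h in range(heads):
                sl = slice(h * ph, (h + 1) * ph)
                o, w = naive_attention(q[bi][:, sl], k[bi][:, sl], v[bi][:, sl], scale)
                outs[bi][:, sl] = o
                ygcs[bi, h] = w
        out_list.append(_chan_proj(outs, op.weight.data, op.bias.data))
        ygc_list.append(ygcs.mean(axis=1))
    return ygc_list, out_list


def naive_gsa(module, tokens):
    """Loop re-implementation of GlobalSpatialAttention.forward (values=normed)."""
    normed = [layer_norm_rows(t) for t in tokens]
    t_c = np.concatenate(normed, axis=1)
    q = _chan_proj(t_c, module.q_proj.weight.data, module.q_proj.bias.data)
    k = _chan_proj(t_c, module.k_proj.weight.data, module.k_proj.bias.data)
    heads = module.heads
    d_k = module.c_cat // heads
    b, cc, p = q.shape
    ygs = np.zeros((b, heads, p, p))
    for bi in range(b):
        for h in range(heads):
            sl = slice(h * d_k, (h + 1) * d_k)
            # attention over token positions: sequences are columns
            _, w = naive_attention(q[bi][sl].T, k[bi][sl].T, q[bi][sl].T, 1.0 / np.sqrt(d_k))
            ygs[bi, h] = w
    out_list = []
    for t, vp, op in zip(normed, module.v_projs, module.out_projs):
        v = _chan_proj(t, vp.weight.data, vp.bias.data)
        ci = v.shape[1]
        ch = ci // heads
        out = np.zeros_like(v)
        for bi in range(b):
            for h in range(heads):
                rows = slice(h * ch, (h + 1) * ch)
                for pp in range(p):
                    for qq in range(p):
                        out[bi, rows, pp] += ygs[bi, h, pp, qq] * v[bi, rows, qq]
        out_list.append(_chan_proj(out, op.weight.data, op.bias.data))
    return ygs, out_list


def naive_lca(module, f):
    """pool -> circular 1D channel conv -> sigmoid -> gate, with loops."""
    b, c, h, w = f.shape
    weight = module.conv.weight.data
    bias = float(module.conv.bias.data[0])
    k = len(weight)
    half = k // 2
    gap = np.zeros((b, c))
    for bi in range(b):
        for ci in range(c):
            gap[bi, ci] = f[bi, ci].mean()
    ylc = np.zeros((b, c))
    for bi in range(b):
        for ci in range(c):
            s = bias
            for j in range(k):
                s += weight[j] * gap[bi, (ci - half + j) % c]
            ylc[bi, ci] = 1.0 / (1.0 + np.exp(-s))
    fcl = np.empty_like(f)
    for bi in range(b):
        for ci in range(c):
            fcl[bi, ci] = f[bi, ci] * ylc[bi, ci] + f[bi, ci]
    return ylc.reshape(b, c, 1, 1), fcl


def naive_conv2d(x, weight, bias, padding=0, dilation=1):
    b, c, h, w = x.shape
    oc, _, kh, kw = weight.shape
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    oh = h + 2 * padding - (kh - 1) * dilation
    ow = w + 2 * padding - (kw - 1) * dilation
    out = np.zeros((b, oc, oh, ow))
    for bi in range(b):
        for o in range(oc):
            for i in range(oh):
                for j in range(ow):
                    s = bias[o]
                    for ci in range(c):
                        for u in range(kh):
                            for v in range(kw):
                                s += weight[o, ci, u, v] * xp[bi, ci, i + u * dilation, j + v * dilation]
                    out[bi, o, i, j] = s
    return out


def naive_depthwise_conv2d(x, weight, bias, padding=0, dilation=1):
    b, c, h, w = x.shape
    _, kh, kw = weight.shape
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    oh = h + 2 * padding - (kh - 1) * dilation
    ow = w + 2 * padding - (kw - 1) * dilation
    out = np.zeros((b, c, oh, ow))
    for bi in range(b):
        for ci in range(c):
            for i in range(oh):
                for j in range(ow):
                    s = bias[ci]
                    for u in range(kh):
                        for v in range(kw):
                            s += weight[ci, u, v] * xp[bi, ci, i + u * dilation, j + v * dilation]
                    out[bi, ci, i, j] = s
    return out


def naive_lsa(module, f):
    """1x1 reduce -> dilated depthwise branches -> concat -> 1x1 -> sigmoid."""
    r = naive_conv2d(f, module.reduce.weight.data, module.reduce.bias.data)
    b1 = naive_depthwise_conv2d(r, module.branch1.weight.data, module.branch1.bias.data, 1, 1)
    b2 = naive_depthwise_conv2d(r, module.branch2.weight.data, module.branch2.bias.data, 4, 2)
    b3 = naive_depthwise_conv2d(r, module.branch3.weight.data, module.branch3.bias.data, 9, 3)
    cat = np.concatenate([r, b1, b2, b3], axis=1)
    logits = naive_conv2d(cat, module.out.weight.data, module.out.bias.data)
    yls = 1.0 / (1.0 + np.exp(-logits))
    fsl = f * yls
    if module.residual:
        fsl = fsl + f
    return yls, fsl


def naive_channel_mix(fcl, ygc, context=None):
    """Explicit channel-mixing loop for combine_glca."""
    if context is None:
        context = fcl
    b, co, ci = ygc.shape
    out = np.array(fcl, dtype=np.float64, copy=True)
    for bi in range(b):
        for i in range(co):
            acc = np.zeros(fcl.shape[2:])
            for j in range(ci):
                acc += ygc[bi, i, j] * context[bi, j]
            out[bi, i] = acc + fcl[bi, i]
    return out


def naive_spatial_mix(fsl, ygs):
    """Explicit position-mixing loop for combine_glsa (3D or per-head 4D map)."""
    b, c = fsl.shape[:2]
    p = int(np.prod(fsl.shape[2:]))
    flat = fsl.reshape(b, c, p).astype(np.float64)
    out = flat.copy()
    if ygs.ndim == 3:
        for bi in range(b):
            for ci in range(c):
                for pp in range(p):
                    acc = 0.0
                    for qq in range(p):
                        acc += ygs[bi, pp, qq] * flat[bi, ci, qq]
                    out[bi, ci, pp] += acc
    else:
        heads = ygs.shape[1]
        ch = c // heads
        for bi in range(b):
            for h in range(heads):
                for ci in range(h * ch, (h + 1) * ch):
                    for pp in range(p):
                        acc = 0.0
                        for qq in range(p):
                            acc += ygs[bi, h, pp, qq] * flat[bi, ci, qq]
                        out[bi, ci, pp] += acc
    return out.reshape(fsl.shape)


def naive_msd(pred, truth, label, spacing=(1.0, 1.0, 1.0)):
    """Brute-force all-pairs symmetric mean surface distance."""
    def boundary(mask):
        pts = []
        d, h, w = mask.shape
        for z in range(d):
            for y in range(h):
                for x in range(w):
                    if not mask[z, y, x]:
                        continue
                    for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                       (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                        zz, yy, xx = z + dz, y + dy, x + dx
                        if not (0 <= zz < d and 0 <= yy < h and 0 <= xx < w) or not mask[zz, yy, xx]:
                            pts.append((z, y, x))
                            break
        return np.array(pts, dtype=np.float64)

    a = boundary(pred == label) * np.asarray(spacing)
    b = boundary(truth == label) * np.asarray(spacing)
    if len(a) == 0 or len(b) == 0:
        return float("nan")

    def directed(src, dst):
        total = 0.0
        for p in src:
            best = min(np.sqrt(((p - q) ** 2).sum()) for q in dst)
            total += best
        return total / len(src)

    return 0.5 * (directed(a, b) + directed(b, a))


def wilcoxon_exact_p(a, b):
    """Exact two-sided signed-rank p by enumerating all sign assignments."""
    from itertools import product

    diffs = np.asarray(a, dtype=np.float64) - np.asarray(b, dtype=np.float64)
    diffs = diffs[diffs != 0]
    n = len(diffs)
    ranks = _rank(np.abs(diffs))
    w_plus = ranks[diffs > 0].sum()
    stat = min(w_plus, n * (n + 1) / 2 - w_plus)
    count = 0
    total = 0
    for signs in product((0, 1), repeat=n):
        wp = sum(r for s, r in zip(signs, ranks) if s)
        st = min(wp, n * (n + 1) / 2 - wp)
        total += 1
        if st <= stat + 1e-12:
            count += 1
    return count / total


def _rank(x):
    """Average ranks (ties shared), 1-based."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x), dtype=np.float64)
    i = 0
    sorted_x = x[order]
    while i < len(x):
        j = i
        while j + 1 < len(x) and sorted_x[j + 1] == sorted_x[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks
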