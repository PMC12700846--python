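"""Attention submodules against loop oracles, plus contracts and reductions."""

import numpy as np
import pytest

from glcsa import nn
from glcsa.attention import (FusionWeights, GLCSABlock, GLCSAConfig,
                             GlobalChannelAttention, GlobalSpatialAttention,
                             LocalChannelAttention, LocalSpatialAttention,
                             MultiscaleEmbedding, SliceInteraction, combine_glca,
                             combine_glsa, fuse_maps, multi_head_attention,
                             scaled_dot_attention)
from glcsa.errors import ConfigError
from glcsa.nn import Tensor
from glcsa.synthetic import feature_fixture

from .conftest import assert_allclose
from .oracles import (naive_attention, naive_channel_mix, naive_gca, naive_gsa,
                      naive_lca, naive_lsa, naive_multihead, naive_spatial_mix)


def rng64(seed=0):
    return np.random.default_rng(seed)


def tokens_fixture(channels, p, b=2, seed=0):
    r = rng64(seed)
    return [Tensor(r.standard_normal((b, c, p))) for c in channels]


class TestScaledDotAttention:
    def test_singleton(self):
        q = Tensor(np.array([[2.0]]))
        out, w = scaled_dot_attention(q, q, Tensor(np.array([[5.0]])), 1.0)
        assert_allclose(w.data, [[1.0]], 1e-12)
        assert_allclose(out.data, [[5.0]], 1e-12)

    def test_equal_logits_uniform(self):
        q = Tensor(np.zeros((1, 3)))
        k = Tensor(rng64(1).standard_normal((4, 3)))
        v = Tensor(np.eye(4))
        _, w = scaled_dot_attention(q, k, v, 1.0)
        assert_allclose(w.data, np.full((1, 4), 0.25), 1e-12)

    def test_matches_naive(self):
        r = rng64(2)
        q, k, v = (r.standard_normal((3, 4)) for _ in range(3))
        out, w = scaled_dot_attention(Tensor(q), Tensor(k), Tensor(v), 0.7)
        no, nw = naive_attention(q, k, v, 0.7)
        assert_allclose(out.data, no, 1e-6)
        assert_allclose(w.data, nw, 1e-6)

    def test_multihead_matches_naive(self):
        r = rng64(3)
        q, k, v = (r.standard_normal((3, 4)) for _ in range(3))
        out, _ = multi_head_attention(Tensor(q), Tensor(k), Tensor(v), heads=2)
        no, _ = naive_multihead(q, k, v, heads=2)
        assert_allclose(out.data, no, 1e-6)

    def test_nonconformable(self):
        with pytest.raises(ValueError):
            scaled_dot_attention(Tensor(np.zeros((2, 3))), Tensor(np.zeros((2, 4))),
                                 Tensor(np.zeros((2, 4))), 1.0)

    def test_bad_scale(self):
        q = Tensor(np.zeros((1, 1)))
        with pytest.raises(ValueError):
            scaled_dot_attention(q, q, q, 0.0)


class TestEmbedding:
    def _feats(self, channels, h, b=2, seed=0, dtype=np.float64):
        r = rng64(seed)
        return [Tensor(r.standard_normal((b, c, h >> i, h >> i)).astype(dtype))
                for i, c in enumerate(channels)]

    def test_per_stage_patch_size(self):
        # Ps=8 at stage 2 pools with kernel 4
        cfg = GLCSAConfig(ps=8)
        emb = MultiscaleEmbedding([2, 4], cfg, rng64(0), dtype=np.float64)
        feats = self._feats([2, 4], 32)
        tokens, grid = emb(feats)
        assert grid == (4, 4)
        assert tokens[0].shape == (2, 2, 16) and tokens[1].shape == (2, 4, 16)

    def test_shared_token_count(self):
        cfg = GLCSAConfig(ps=8)
        emb = MultiscaleEmbedding([1, 2, 4, 8], cfg, rng64(0), dtype=np.float64)
        feats = self._feats([1, 2, 4, 8], 128)
        tokens, _ = emb(feats)
        assert all(t.shape[-1] == 256 for t in tokens)  # (128/8)^2

    def test_constant_stage_identity_projection(self):
        cfg = GLCSAConfig(ps=4)
        emb = MultiscaleEmbedding([3], cfg, rng64(0), dtype=np.float64)
        emb.projs[0].weight.data[:] = 1.0
        emb.projs[0].bias.data[:] = 0.0
        feats = [Tensor(np.full((2, 3, 8, 8), 2.5))]
        tokens, _ = emb(feats)
        assert_allclose(tokens[0].data, np.full((2, 3, 4), 2.5), 1e-12)

    def test_global_mode_runs(self):
        cfg = GLCSAConfig(ps=8, embedding_mode="global")
        emb = MultiscaleEmbedding([2, 4], cfg, rng64(0), dtype=np.float64)
        tokens, grid = emb(self._feats([2, 4], 32))
        assert grid == (4, 4) and tokens[1].shape == (2, 4, 16)

    def test_non_integer_patch_size(self):
        cfg = GLCSAConfig(ps=2)
        emb = MultiscaleEmbedding([1, 1, 1], cfg, rng64(0))
        with pytest.raises(ConfigError):
            emb(self._feats([1, 1, 1], 16, dtype=np.float32))


class TestGlobalChannelAttention:
    def test_matches_naive(self):
        toks = tokens_fixture([3, 5], p=4, b=2, seed=4)
        gca = GlobalChannelAttention([3, 5], heads=1, rng=rng64(5), dtype=np.float64)
        ygc, out = gca(toks)
        n_ygc, n_out = naive_gca(gca, [t.data for t in toks])
        for a, b in zip(ygc, n_ygc):
            assert_allclose(a.data, b, 1e-6)
        for a, b in zip(out, n_out):
            assert_allclose(a.data, b, 1e-6)

    def test_multihead_matches_naive(self):
        toks = tokens_fixture([2, 4], p=6, b=2, seed=6)
        gca = GlobalChannelAttention([2, 4], heads=2, rng=rng64(7), dtype=np.float64)
        ygc, out = gca(toks)
        n_ygc, n_out = naive_gca(gca, [t.data for t in toks])
        for a, b in zip(out, n_out):
            assert_allclose(a.data, b, 1e-6)

    def test_rows_sum_to_one(self):
        toks = tokens_fixture([4, 8], p=9, b=3, seed=8)
        gca = GlobalChannelAttention([4, 8], heads=1, rng=rng64(9), dtype=np.float64)
        ygc, _ = gca(toks)
        for y in ygc:
            assert_allclose(y.data.sum(axis=-1), np.ones(y.shape[:-1]), 1e-5)

    def test_single_channel_singleton_softmax(self):
        toks = tokens_fixture([1], p=4, b=1, seed=10)
        gca = GlobalChannelAttention([1], heads=1, rng=rng64(11), dtype=np.float64)
        ygc, out = gca(toks)
        assert_allclose(ygc[0].data, np.ones((1, 1, 1)), 1e-12)

    def test_mismatched_tokens(self):
        gca = GlobalChannelAttention([2, 3], heads=1, rng=rng64(0))
        with pytest.raises(ConfigError):
            gca(tokens_fixture([2], p=4))


class TestGlobalSpatialAttention:
    def test_matches_naive(self):
        toks = tokens_fixture([2, 4], p=3, b=2, seed=12)
        gsa = GlobalSpatialAttention([2, 4], heads=2, rng=rng64(13), dtype=np.float64)
        ygs, out = gsa(toks)
        n_ygs, n_out = naive_gsa(gsa, [t.data for t in toks])
        assert_allclose(ygs.data, n_ygs, 1e-6)
        for a, b in zip(out, n_out):
            assert_allclose(a.data, b, 1e-6)

    def test_rows_sum_to_one(self):
        toks = tokens_fixture([4, 4], p=5, b=2, seed=14)
        gsa = GlobalSpatialAttention([4, 4], heads=4, rng=rng64(15), dtype=np.float64)
        ygs, _ = gsa(toks)
        assert ygs.shape == (2, 4, 5, 5)
        assert_allclose(ygs.data.sum(axis=-1), np.ones((2, 4, 5)), 1e-5)

    def test_p1_degenerate(self):
        toks = tokens_fixture([4], p=1, b=2, seed=16)
        gsa = GlobalSpatialAttention([4], heads=2, rng=rng64(17), dtype=np.float64)
        ygs, out = gsa(toks)
        assert_allclose(ygs.data, np.ones((2, 2, 1, 1)), 1e-12)

    def test_indivisible_heads_rejected(self):
        with pytest.raises(ConfigError):
            GlobalSpatialAttention([3, 5], heads=4, rng=rng64(0))

    def test_default_heads_is_four(self):
        assert GLCSAConfig().glsa_heads == 4
        assert GLCSAConfig().glca_heads == 1


class TestLocalChannelAttention:
    def test_matches_naive(self):
        f = feature_fixture(2, 8, 4, 4, seed=18)
        lca = LocalChannelAttention(3, rng64(19), dtype=np.float64)
        ylc, fcl = lca(f)
        n_ylc, n_fcl = naive_lca(lca, f.data)
        assert_allclose(ylc.data, n_ylc, 1e-6)
        assert_allclose(fcl.data, n_fcl, 1e-6)

    def test_zero_conv_gives_half(self):
        f = feature_fixture(2, 4, 3, 3, seed=20)
        lca = LocalChannelAttention(3, rng64(21), dtype=np.float64)
        lca.conv.weight.data[:] = 0.0
        lca.conv.bias.data[:] = 0.0
        ylc, fcl = lca(f)
        assert_allclose(ylc.data, np.full((2, 4, 1, 1), 0.5), 1e-12)
        assert_allclose(fcl.data, 1.5 * f.data, 1e-12)

    def test_map_shape_and_range(self):
        f = feature_fixture(3, 6, 5, 5, seed=22)
        ylc, _ = LocalChannelAttention(5, rng64(23), dtype=np.float64)(f)
        assert ylc.shape == (3, 6, 1, 1)
        assert np.all(ylc.data > 0) and np.all(ylc.data < 1)

    def test_even_kernel_rejected(self):
        with pytest.raises(ConfigError):
            LocalChannelAttention(4, rng64(0))

    def test_grid_window(self):
        f = feature_fixture(2, 4, 8, 8, seed=24)
        lca = LocalChannelAttention(3, rng64(25), window="grid", grid=4, dtype=np.float64)
        ylc, fcl = lca(f)
        assert ylc.shape == (2, 4, 4, 4)
        assert fcl.shape == f.shape


class TestLocalSpatialAttention:
    def test_matches_naive(self):
        f = feature_fixture(2, 8, 6, 6, seed=26)
        lsa = LocalSpatialAttention(8, rng64(27), dtype=np.float64)
        yls, fsl = lsa(f)
        n_yls, n_fsl = naive_lsa(lsa, f.data)
        assert_allclose(yls.data, n_yls, 1e-6)
        assert_allclose(fsl.data, n_fsl, 1e-6)

    def test_zero_convs_give_half_map(self):
        f = feature_fixture(2, 4, 5, 5, seed=28)
        lsa = LocalSpatialAttention(4, rng64(29), dtype=np.float64)
        for mod in (lsa.reduce, lsa.branch1, lsa.branch2, lsa.branch3, lsa.out):
            mod.weight.data[:] = 0.0
            mod.bias.data[:] = 0.0
        yls, fsl = lsa(f)
        assert_allclose(yls.data, np.full((2, 1, 5, 5), 0.5), 1e-12)
        assert_allclose(fsl.data, 0.5 * f.data, 1e-12)  # no residual by default

    def test_map_shape(self):
        f = feature_fixture(3, 4, 7, 5, seed=30)
        yls, _ = LocalSpatialAttention(4, rng64(31), dtype=np.float64)(f)
        assert yls.shape == (3, 1, 7, 5)
        assert np.all(yls.data > 0) and np.all(yls.data < 1)

    def test_effective_receptive_extent(self):
        # 7x7 kernel at dilation 3 spans (7-1)*3+1 = 19 pixels
        assert (7 - 1) * 3 + 1 == 19
        f = feature_fixture(1, 2, 19, 19, seed=32)
        lsa = LocalSpatialAttention(2, rng64(33), dtype=np.float64)
        yls, _ = lsa(f)  # 'same' padding keeps the extent
        assert yls.shape == (1, 1, 19, 19)

    def test_residual_flag(self):
        f = feature_fixture(1, 4, 4, 4, seed=34)
        r = rng64(35)
        lsa = LocalSpatialAttention(4, r, residual=True, dtype=np.float64)
        yls, fsl = lsa(f)
        assert_allclose(fsl.data, f.data * yls.data + f.data, 1e-12)


class TestCombine:
    def test_glca_zero_map(self):
        f = feature_fixture(2, 3, 4, 4, seed=36)
        ygc = Tensor(np.zeros((2, 3, 3)))
        assert_allclose(combine_glca(f, ygc).data, f.data, 1e-12)

    def test_glca_identity_doubles(self):
        f = feature_fixture(2, 3, 4, 4, seed=37)
        ygc = Tensor(np.tile(np.eye(3), (2, 1, 1)))
        assert_allclose(combine_glca(f, ygc).data, 2 * f.data, 1e-12)

    def test_glca_matches_loop(self):
        f = feature_fixture(2, 4, 3, 3, seed=38)
        ygc = Tensor(rng64(39).random((2, 4, 4)))
        assert_allclose(combine_glca(f, ygc).data, naive_channel_mix(f.data, ygc.data), 1e-6)

    def test_glca_multiscale_context(self):
        f = feature_fixture(2, 3, 2, 2, seed=40)
        ctx = feature_fixture(2, 7, 2, 2, seed=41)
        ygc = Tensor(rng64(42).random((2, 3, 7)))
        got = combine_glca(f, ygc, context=ctx)
        assert_allclose(got.data, naive_channel_mix(f.data, ygc.data, ctx.data), 1e-6)

    def test_glsa_zero_map(self):
        f = feature_fixture(2, 3, 2, 2, seed=43)
        ygs = Tensor(np.zeros((2, 4, 4)))
        assert_allclose(combine_glsa(f, ygs).data, f.data, 1e-12)

    def test_glsa_identity_doubles(self):
        f = feature_fixture(2, 3, 2, 2, seed=44)
        ygs = Tensor(np.tile(np.eye(4), (2, 1, 1)))
        assert_allclose(combine_glsa(f, ygs).data, 2 * f.data, 1e-12)

    def test_glsa_matches_loop(self):
        f = feature_fixture(2, 4, 2, 3, seed=45)
        ygs = Tensor(rng64(46).random((2, 6, 6)))
        assert_allclose(combine_glsa(f, ygs).data, naive_spatial_mix(f.data, ygs.data), 1e-6)

    def test_glsa_per_head_matches_loop(self):
        f = feature_fixture(2, 4, 2, 2, seed=47)
        ygs = Tensor(rng64(48).random((2, 2, 4, 4)))
        assert_allclose(combine_glsa(f, ygs).data, naive_spatial_mix(f.data, ygs.data), 1e-6)

    def test_shape_mismatch(self):
        f = feature_fixture(1, 2, 2, 2, seed=49)
        with pytest.raises(ValueError):
            combine_glca(f, Tensor(np.zeros((1, 3, 3))))
        with pytest.raises(ValueError):
            combine_glsa(f, Tensor(np.zeros((1, 5, 5))))


class TestSliceInteraction:
    def test_b1_value_path(self):
        sim = SliceInteraction(4, heads=2, rng=rng64(50), dtype=np.float64)
        f = feature_fixture(1, 4, 3, 3, seed=51)
        out = sim(f)
        x = f.data.reshape(1, 4, 9).transpose(2, 0, 1)
        expected = (x @ sim.v.weight.data + sim.v.bias.data).transpose(1, 2, 0).reshape(f.shape)
        assert_allclose(out.data, expected, 1e-9)

    def test_identical_slices_symmetry(self):
        sim = SliceInteraction(4, heads=2, rng=rng64(52), dtype=np.float64)
        one = rng64(53).standard_normal((1, 4, 3, 3))
        f = Tensor(np.repeat(one, 5, axis=0))
        out = sim(f).data
        for i in range(1, 5):
            assert_allclose(out[i], out[0], 1e-9)

    def test_permutation_equivariance(self):
        sim = SliceInteraction(6, heads=3, rng=rng64(54), dtype=np.float64)
        f = feature_fixture(5, 6, 2, 2, seed=55)
        perm = np.array([3, 0, 4, 1, 2])
        out_direct = sim(f).data[perm]
        out_permuted = sim(Tensor(f.data[perm])).data
        assert_allclose(out_direct, out_permuted, 1e-9)

    def test_la2_per_slice(self):
        sim = SliceInteraction(4, heads=2, rng=rng64(56), la2=True, dtype=np.float64)
        f = feature_fixture(3, 4, 2, 2, seed=57)
        out = sim(f).data
        for i in range(3):
            single = sim(Tensor(f.data[i:i + 1])).data
            assert_allclose(out[i:i + 1], single, 1e-9)


class TestFusion:
    def test_zero_raw_is_uniform(self):
        fw = FusionWeights(dtype=np.float64)
        fl, fg, f = (feature_fixture(1, 2, 2, 2, seed=s) for s in (58, 59, 60))
        out = fuse_maps(fl, fg, f, fw)
        assert_allclose(out.data, (fl.data + fg.data + f.data) / 3, 1e-9)

    def test_saturated_softmax(self):
        fw = FusionWeights(dtype=np.float64)
        fw.raw.data[:] = [20.0, 0.0, 0.0]
        fl, fg, f = (feature_fixture(1, 2, 2, 2, seed=s) for s in (61, 62, 63))
        out = fuse_maps(fl, fg, f, fw)
        assert_allclose(out.data, fl.data, 1e-6)

    def test_weights_on_simplex(self):
        fw = FusionWeights(dtype=np.float64)
        fw.raw.data[:] = [3.0, -1.0, 0.5]
        w = fw.normalized
        assert abs(w.sum() - 1.0) < 1e-6
        assert np.all(w >= 0) and np.all(w <= 1)

    def test_convex_hull(self):
        fw = FusionWeights(dtype=np.float64)
        fw.raw.data[:] = rng64(64).standard_normal(3)
        fl, fg, f = (feature_fixture(1, 3, 3, 3, seed=s) for s in (65, 66, 67))
        out = fuse_maps(fl, fg, f, fw).data
        lo = np.minimum(np.minimum(fl.data, fg.data), f.data)
        hi = np.maximum(np.maximum(fl.data, fg.data), f.data)
        assert np.all(out >= lo - 1e-9) and np.all(out <= hi + 1e-9)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            fuse_maps(feature_fixture(1, 2, 2, 2), feature_fixture(1, 2, 2, 2),
                      feature_fixture(1, 2, 3, 3), FusionWeights())


def small_block(cfg=None, channels=(4, 8), seed=1, dtype=np.float64):
    cfg = cfg or GLCSAConfig(ps=4, glsa_heads=2, glca_heads=1)
    return GLCSABlock(list(channels), cfg, np.random.default_rng(seed), dtype=dtype)


def block_feats(channels=(4, 8), h=16, b=3, seed=2, dtype=np.float64):
    r = np.random.default_rng(seed)
    return [Tensor(r.standard_normal((b, c, h >> i, h >> i)).astype(dtype))
            for i, c in enumerate(channels)]


class TestBlock:
    def test_output_shapes_match_skips(self):
        block = small_block()
        feats = block_feats()
        outs = block(feats)
        for o, f in zip(outs, feats):
            assert o.shape == f.shape

    def test_four_stage_128_shapes(self):
        # n=4 stages on a 128x128 backbone: outputs (C_i, 128/2^(i-1), ...)
        channels = [8, 16, 32, 64]
        cfg = GLCSAConfig(ps=8, glsa_heads=4)
        block = GLCSABlock(channels, cfg, np.random.default_rng(0), dtype=np.float32)
        r = np.random.default_rng(1)
        feats = [Tensor(r.standard_normal((1, c, 128 >> i, 128 >> i)).astype(np.float32))
                 for i, c in enumerate(channels)]
        outs = block(feats)
        assert [tuple(o.shape) for o in outs] == [
            (1, 8, 128, 128), (1, 16, 64, 64), (1, 32, 32, 32), (1, 64, 16, 16)]

    @pytest.mark.parametrize("order", ["glca_first", "glsa_first"])
    @pytest.mark.parametrize("fusion", ["sequential", "sum", "parallel"])
    def test_ablation_switches_run(self, order, fusion):
        cfg = GLCSAConfig(ps=4, glsa_heads=2, attention_order=order, module_fusion=fusion)
        block = small_block(cfg)
        outs = block(block_feats())
        for o in outs:
            assert np.all(np.isfinite(o.data))

    def test_only_one_path(self):
        for kw in ({"enable_glca": False}, {"enable_glsa": False}):
            cfg = GLCSAConfig(ps=4, glsa_heads=2, **kw)
            outs = small_block(cfg)(block_feats())
            assert all(np.all(np.isfinite(o.data)) for o in outs)

    def test_attention_disabled_reduces_to_token_path(self):
        cfg = GLCSAConfig(ps=4, enable_glca=False, enable_glsa=False, sim_enabled=False)
        block = small_block(cfg)
        for proj in block.up_projs:
            proj.weight.data[:] = 1.0
            proj.bias.data[:] = 0.0
        feats = block_feats()
        outs = block(feats)
        tokens, (hp, wp) = block.embed(feats)
        for out, tok, f in zip(outs, tokens, feats):
            b, c = tok.shape[0], tok.shape[1]
            manual = nn.gelu(nn.layer_norm(tok, axis=-1)).reshape(b, c, hp, wp)
            manual = nn.bilinear_resize(manual, (f.shape[2], f.shape[3]))
            assert_allclose(out.data, manual.data, 1e-9)

    def test_la2_mode_runs(self):
        cfg = GLCSAConfig(ps=4, glsa_heads=2, local_mode="la2")
        outs = small_block(cfg)(block_feats())
        assert all(np.all(np.isfinite(o.data)) for o in outs)

    def test_finite_on_image_range_inputs(self):
        # inputs in [0, 255] across 100 random initializations
        cfg = GLCSAConfig(ps=4, glsa_heads=2)
        for seed in range(100):
            block = GLCSABlock([2, 4], cfg, np.random.default_rng(seed), dtype=np.float32)
            r = np.random.default_rng(seed + 1000)
            feats = [Tensor((r.random((2, c, 8 >> i, 8 >> i)) * 255).astype(np.float32))
                     for i, c in enumerate((2, 4))]
            outs = block(feats)
            assert all(np.all(np.isfinite(o.data)) for o in outs)

    def test_sim_disabled_slice_independence(self):
        cfg = GLCSAConfig(ps=4, glsa_heads=2, sim_enabled=False)
        block = small_block(cfg)
        one = np.random.default_rng(3).standard_normal((1, 4, 16, 16))
        two = np.random.default_rng(4).standard_normal((1, 8, 8, 8))
        rep = [Tensor(np.repeat(one, 4, axis=0)), Tensor(np.repeat(two, 4, axis=0))]
        outs = block(rep)
        for o in outs:
            for i in range(1, 4):
                assert_allclose(o.data[i], o.data[0], 1e-9)

    def test_sim_permutation_equivariance_of_block(self):
        block = small_block()
        feats = block_feats(b=4, seed=5)
        perm = np.array([2, 0, 3, 1])
        outs = block(feats)
        outs_p = block([Tensor(f.data[perm]) for f in feats])
        for o, op in zip(outs, outs_p):
            assert_allclose(o.data[perm], op.data, 1e-8)

    def test_gradient_coverage(self):
        block = small_block()
        feats = block_feats(b=2, seed=6)
        outs = block(feats)
        loss = None
        for o in outs:
            term = (o * o).mean()
            loss = term if loss is None else loss + term
        loss.backward()
        for name, p in block.named_parameters():
            assert p.grad is not None, f"no gradient for {name}"
            assert np.any(p.grad != 0), f"zero gradient for {name}"

    def test_stage_shape_mismatch_rejected(self):
        block = small_block()
        feats = block_feats()
        feats[1] = Tensor(np.zeros((3, 8, 5, 5)))
        with pytest.raises(ConfigError):
            block(feats)

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            GLCSAConfig(ps=6).validate()
        with pytest.raises(ConfigError):
            GLCSAConfig(lca_kernel=2).validate()
        with pytest.raises(ConfigError):
            GLCSAConfig(module_fusion="nope").validate()
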