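"""The multi-scale residual block (recursion oracle), FM/TBM networks."""

import numpy as np
import pytest

from trxgeom.model_res2net import (
    FULL,
    TINY,
    ConfigurationError,
    NetworkConfig,
    Res2NetBlock,
    Res2NetFM,
    Res2NetTBM,
    load_fm,
    make_optimizer,
    save_checkpoint,
    symmetrize,
)
from trxgeom.template_attention import TemplateFeatureStack

SMALL = NetworkConfig(fm_groups=((1, 8), (1, 8)),
                      tbm_groups=((1, 8), (1, 8), (1, 8), (1, 8)),
                      attention_dim=4)


def conv3_same(x, W):
    """Direct 3x3 same-padding convolution, loop implementation."""
    cout, cin, _, _ = W.shape
    H, Wd = x.shape[1], x.shape[2]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
    y = np.zeros((cout, H, Wd))
    for o in range(cout):
        for c in range(cin):
            for a in range(3):
                for b in range(3):
                    y[o] += W[o, c, a, b] * xp[c, a:a + H, b:b + Wd]
    return y


class TestBlock:
    def test_recursion_matches_direct_evaluation(self, rng):
        """Hand-set kernels, normalization off: the block's split stage obeys
        y1=x1, y2=K2(x2), y3=K3(x3+y2), y4=K4(x4+y3)."""
        blk = Res2NetBlock(4, scale=4, rng=rng, norm=False,
                           activation="linear")
        # identity 1x1 reduce/expand, zero biases; expansion residual off
        blk.reduce.W.v = np.eye(4)[:, :, None, None].astype(float)
        blk.reduce.b.v[...] = 0.0
        blk.expand.W.v = np.eye(4)[:, :, None, None].astype(float)
        blk.expand.b.v[...] = 0.0
        for conv in blk.convs:
            conv.b.v[...] = 0.0
            conv.W.v = rng.normal(size=conv.W.v.shape)

        x = rng.normal(size=(4, 8, 8))
        got = blk.forward(x) - x  # remove the residual addition

        xs = [x[i:i + 1] for i in range(4)]
        y1 = xs[0]
        y2 = conv3_same(xs[1], blk.convs[0].W.v)
        y3 = conv3_same(xs[2] + y2, blk.convs[1].W.v)
        y4 = conv3_same(xs[3] + y3, blk.convs[2].W.v)
        want = np.concatenate([y1, y2, y3, y4], axis=0)
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_zero_expansion_is_identity(self, rng):
        blk = Res2NetBlock(8, scale=4, rng=rng)
        blk.expand.W.v[...] = 0.0
        blk.expand.b.v[...] = 0.0
        x = rng.normal(size=(8, 6, 6))
        np.testing.assert_array_equal(blk.forward(x), x)

    def test_spatial_shape_preserved(self, rng):
        for dilation in (1, 2, 4):
            blk = Res2NetBlock(8, dilation=dilation, rng=rng)
            x = rng.normal(size=(8, 11, 11))
            assert blk.forward(x).shape == x.shape

    def test_indivisible_channels_rejected(self):
        with pytest.raises(ConfigurationError):
            Res2NetBlock(6, scale=4)


class TestFM:
    def test_head_shapes_and_normalization(self, rng):
        net = Res2NetFM(SMALL, seed=0)
        feats = rng.normal(size=(7, 7, 526))
        post, intermediate = net.forward(feats)
        assert post.dist.shape == (7, 7, 37)
        assert post.omega.shape == (7, 7, 25)
        assert post.theta.shape == (7, 7, 25)
        assert post.phi.shape == (7, 7, 13)
        post.check_normalized(atol=1e-10)
        assert intermediate.shape == (8, 7, 7)
        for head in post.heads().values():
            assert (head > 0).all()  # softmax range

    def test_inference_deterministic(self, rng):
        feats = rng.normal(size=(6, 6, 526))
        a = Res2NetFM(SMALL, seed=3).predict(feats)
        b = Res2NetFM(SMALL, seed=3).predict(feats)
        for name in ("dist", "omega", "theta", "phi"):
            np.testing.assert_array_equal(a.heads()[name], b.heads()[name])

    def test_wrong_channel_count_rejected(self, rng):
        with pytest.raises(ValueError, match="channels"):
            Res2NetFM(SMALL).forward(rng.normal(size=(5, 5, 100)))

    def test_profiles_instantiate_and_full_filter_range(self):
        tiny = Res2NetFM(TINY)
        assert len(tiny.groups) == 2
        full = Res2NetFM(FULL)
        assert len(full.groups) == 4
        counts = full.trunk_filter_counts()
        assert all(64 <= c <= 512 for c in counts)

    def test_full_profile_depth_about_50_conv_layers(self):
        # 10 blocks x (reduce + three 3x3 + expand) + input + projections
        assert Res2NetFM(FULL).n_conv_layers() in range(48, 58)

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        net = Res2NetFM(SMALL, seed=9)
        feats = rng.normal(size=(5, 5, 526))
        before = net.predict(feats)
        save_checkpoint(net, tmp_path / "fm.npz")
        back = load_fm(tmp_path / "fm.npz")
        after = back.predict(feats)
        np.testing.assert_array_equal(before.dist, after.dist)


class TestTBM:
    def make_stack(self, rng, n, L):
        return TemplateFeatureStack(features=rng.random((n, L, L, 100)),
                                    s_pair=rng.random((n, L, L)))

    def test_six_groups_counting_reuse(self):
        tbm = Res2NetTBM(Res2NetFM(SMALL), SMALL)
        assert tbm.n_groups_total == 6
        assert len(tbm.groups) == 4

    def test_frozen_groups_bitwise_unchanged_by_training(self, rng):
        fm = Res2NetFM(SMALL, seed=1)
        tbm = Res2NetTBM(fm, SMALL, seed=2)
        frozen_before = [p.v.copy() for p in fm.reused_parameters()]
        L = 6
        stack = self.make_stack(rng, 2, L)
        feats = rng.normal(size=(L, L, 526))
        labels = {n: rng.integers(0, nb, size=(L, L)) for n, nb in
                  zip(("dist", "omega", "theta", "phi"), (37, 25, 25, 13))}
        mask = ~np.eye(L, dtype=bool)
        opt = make_optimizer(tbm, lr=1e-2)
        for _ in range(3):
            opt.zero_grad()
            tbm.loss_and_grad(feats, stack, labels, mask)
            opt.step()
        for before, p in zip(frozen_before, fm.reused_parameters()):
            np.testing.assert_array_equal(before, p.v)
        # gradients never even accumulate on the frozen parameters
        assert all((p.g == 0).all() for p in fm.reused_parameters())

    def test_zero_template_map_is_msa_deterministic(self, rng):
        fm = Res2NetFM(SMALL, seed=1)
        tbm = Res2NetTBM(fm, SMALL, seed=2)
        feats = rng.normal(size=(5, 5, 526))
        zeros = np.zeros((5, 5, 100))
        a = tbm.forward(feats, zeros)
        b = tbm.forward(feats, zeros)
        np.testing.assert_array_equal(a.dist, b.dist)
        a.check_normalized(atol=1e-10)

    def test_length_mismatch_rejected(self, rng):
        tbm = Res2NetTBM(Res2NetFM(SMALL), SMALL)
        with pytest.raises(ValueError, match="match"):
            tbm.forward(rng.normal(size=(5, 5, 526)), np.zeros((4, 4, 100)))


class TestSymmetrize:
    def rand_post(self, rng, L=5):
        from trxgeom.containers import GeometryPosterior

        def head(nb):
            x = rng.random((L, L, nb))
            return x / x.sum(-1, keepdims=True)

        return GeometryPosterior(dist=head(37), omega=head(25),
                                 theta=head(25), phi=head(13))

    def test_symmetric_input_unchanged(self, rng):
        p = self.rand_post(rng)
        p.dist = (p.dist + p.dist.transpose(1, 0, 2)) / 2
        p.omega = (p.omega + p.omega.transpose(1, 0, 2)) / 2
        s = symmetrize(p)
        np.testing.assert_allclose(s.dist, p.dist, atol=1e-15)

    def test_output_symmetric_and_normalized(self, rng):
        p = self.rand_post(rng)
        theta_before = p.theta.copy()
        s = symmetrize(p)
        np.testing.assert_array_equal(s.dist, s.dist.transpose(1, 0, 2))
        np.testing.assert_array_equal(s.omega, s.omega.transpose(1, 0, 2))
        np.testing.assert_array_equal(s.theta, theta_before)
        s.check_normalized(atol=1e-12)
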