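"""Projection, graph reasoning, reprojection and CGA-CRF fusion contracts."""

import numpy as np
import pytest

from hdcseg.autograd import Tensor, sigmoid
from hdcseg.interaction import (CGACRFFusion, ContextBranch, FeatureInteraction,
                                GraphReasoner, InteractionConfig, Projector,
                                reproject)
from hdcseg.blocks import GAMConfig
from hdcseg.nn import count_parameters

from conftest import gradcheck


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class TestProjector:
    def test_constant_input_gives_constant_nodes(self, rng):
        proj = Projector(4, nodes=3, node_channels=2, rng=rng)
        x = Tensor(np.full((1, 4, 4, 4, 4), 1.5, dtype=np.float32))
        xp, a = proj(x)
        # assignment weights sum to 1 over space, so each node feature is the
        # (constant) channel-reduced value
        np.testing.assert_allclose(a.data.sum(axis=2), 1.0, atol=1e-6)
        expected = proj.reduce(x).data[0, :, 0, 0, 0]
        for k in range(3):
            np.testing.assert_allclose(xp.data[0, k], expected, atol=1e-5)

    def test_single_node_uniform_weights_is_spatial_mean(self, rng):
        proj = Projector(2, nodes=1, node_channels=2, rng=rng)
        proj.assign.weight.data[:] = 0.0  # uniform softmax
        proj.assign.bias.data[:] = 0.0
        x = Tensor(rng.normal(size=(1, 2, 3, 3, 3)).astype(np.float32))
        xp, _ = proj(x)
        reduced = proj.reduce(x).data[0].reshape(2, -1).mean(axis=1)
        np.testing.assert_allclose(xp.data[0, 0], reduced, atol=1e-5)

    def test_matches_dense_weighted_sum_oracle(self, rng):
        proj = Projector(3, nodes=4, node_channels=2, rng=rng, dtype=np.float64)
        x = Tensor(rng.normal(size=(1, 3, 4, 4, 4)))
        xp, a = proj(x)
        xt = proj.reduce(x).data[0].reshape(2, -1)
        for k in range(4):
            want = (a.data[0, k][None, :] * xt).sum(axis=1)
            np.testing.assert_allclose(xp.data[0, k], want, atol=1e-6)

    def test_rejects_zero_nodes(self):
        with pytest.raises(ValueError):
            Projector(4, nodes=0, node_channels=2)


class TestGraphReasoner:
    def test_identity_adjacency_forces_half(self, rng):
        """With A = I the smoothing (I - A) annihilates the nodes, so the
        sigmoid sees 0 and every output is exactly 0.5."""
        gr = GraphReasoner(nodes=3, node_channels=2, rng=rng)
        gr.adjacency.data = np.eye(3, dtype=np.float32)
        xp = Tensor(rng.normal(size=(1, 3, 2)).astype(np.float32))
        out = gr(xp)
        np.testing.assert_allclose(out.data, 0.5, atol=1e-7)

    def test_hand_computed_2x2(self):
        gr = GraphReasoner(nodes=2, node_channels=2)
        gr.adjacency.data = np.array([[0.5, 0.0], [0.25, 0.0]], dtype=np.float32)
        gr.weight.data = np.array([[1.0, 2.0], [0.0, 1.0]], dtype=np.float32)
        xp = np.array([[[1.0, 0.0], [0.0, 1.0]]], dtype=np.float32)
        # (I - A) X = [[0.5, 0], [-0.25, 1]]; times W = [[0.5, 1.0], [-0.25, 0.5]]
        want = _sigmoid(np.array([[0.5, 1.0], [-0.25, 0.5]]))
        np.testing.assert_allclose(gr(Tensor(xp)).data[0], want, atol=1e-6)

    def test_outputs_strictly_in_unit_interval(self, rng):
        gr = GraphReasoner(nodes=4, node_channels=3, rng=rng)
        gr.adjacency.data = rng.normal(size=(4, 4)).astype(np.float32)
        out = gr(Tensor(rng.normal(size=(2, 4, 3)).astype(np.float32))).data
        assert np.all(out > 0) and np.all(out < 1)

    def test_dimension_mismatch_rejected(self, rng):
        gr = GraphReasoner(nodes=4, node_channels=3, rng=rng)
        with pytest.raises(ValueError):
            gr(Tensor(np.zeros((1, 5, 3), dtype=np.float32)))


class TestReproject:
    def test_identical_nodes_give_constant_field(self, rng):
        a = Tensor(rng.random(size=(1, 3, 8)).astype(np.float32) + 0.1)
        xg = Tensor(np.tile(np.array([[2.0, -1.0]], dtype=np.float32), (3, 1))[None])
        out = reproject(xg, a, (2, 2, 2))
        np.testing.assert_allclose(out.data[0, 0], 2.0, atol=1e-6)
        np.testing.assert_allclose(out.data[0, 1], -1.0, atol=1e-6)

    def test_matches_dense_oracle(self, rng):
        a = Tensor(rng.random(size=(1, 4, 27)).astype(np.float64) + 0.05)
        xg = Tensor(rng.normal(size=(1, 4, 3)))
        out = reproject(xg, a, (3, 3, 3)).data[0]
        abar = a.data[0] / a.data[0].sum(axis=0, keepdims=True)
        want = (abar.T @ xg.data[0]).T.reshape(3, 3, 3, 3)
        np.testing.assert_allclose(out, want, atol=1e-9)

    def test_one_node_roundtrip_identity_on_constants(self, rng):
        proj = Projector(2, nodes=1, node_channels=2, rng=rng)
        x = Tensor(np.full((1, 2, 2, 2, 2), 0.7, dtype=np.float32))
        xp, a = proj(x)
        out = reproject(xp, a, (2, 2, 2))
        np.testing.assert_allclose(out.data, proj.reduce(x).data, atol=1e-5)


class TestCGACRF:
    def test_zero_iterations_returns_xa_exactly(self, rng):
        fuse = CGACRFFusion(4, iters=0, rng=rng)
        xg = Tensor(rng.normal(size=(1, 4, 3, 3, 3)).astype(np.float32))
        xa = Tensor(rng.normal(size=(1, 4, 3, 3, 3)).astype(np.float32))
        np.testing.assert_array_equal(fuse(xg, xa).data, xa.data)

    def test_saturated_closed_gate_returns_xa(self, rng):
        fuse = CGACRFFusion(4, iters=3, rng=rng)
        fuse.gate.weight.data[:] = 0.0
        fuse.gate.bias.data[:] = -50.0  # sigmoid -> 0: keep H_{t-1}
        xg = Tensor(rng.normal(size=(1, 4, 3, 3, 3)).astype(np.float32))
        xa = Tensor(rng.normal(size=(1, 4, 3, 3, 3)).astype(np.float32))
        np.testing.assert_allclose(fuse(xg, xa).data, xa.data, atol=1e-6)

    def test_two_iterations_match_unrolled_oracle(self, rng):
        fuse = CGACRFFusion(2, iters=2, rng=rng, dtype=np.float64)
        xg = Tensor(rng.normal(size=(1, 2, 3, 3, 3)))
        xa = Tensor(rng.normal(size=(1, 2, 3, 3, 3)))
        out = fuse(xg, xa).data
        # independent unrolled trace using raw conv arithmetic
        from hdcseg.autograd import concat, conv3d
        h = xa
        for _ in range(2):
            pre = conv3d(concat([h, xg], axis=1), fuse.gate.weight, fuse.gate.bias)
            g = 1.0 / (1.0 + np.exp(-pre.data))
            m = conv3d(xg, fuse.message.weight, fuse.message.bias).data
            h = Tensor(g * m + (1 - g) * h.data)
        np.testing.assert_allclose(out, h.data, atol=1e-6)

    def test_shape_mismatch_rejected(self, rng):
        fuse = CGACRFFusion(4, rng=rng)
        with pytest.raises(ValueError, match="shape"):
            fuse(Tensor(np.zeros((1, 4, 2, 2, 2), dtype=np.float32)),
                 Tensor(np.zeros((1, 4, 4, 4, 4), dtype=np.float32)))


class TestContextBranch:
    def test_shape_preserved(self, rng):
        cb = ContextBranch(8, rng=rng)
        x = Tensor(rng.normal(size=(1, 8, 4, 4, 4)).astype(np.float32))
        assert cb(x).shape == x.shape

    def test_zero_weight_gam_quarter_scales_xc(self, rng):
        cb = ContextBranch(8, gam_cfg=GAMConfig(8, 4, 3), rng=rng)
        for p in cb.gam.parameters():
            p.data = np.zeros_like(p.data)
        cb.gam.spatial.layers[1].weight.data[:] = 1.0
        x = Tensor(rng.normal(size=(1, 8, 4, 4, 4)).astype(np.float32))
        xc = cb.conv(x).data
        np.testing.assert_allclose(cb(x).data, 0.25 * xc, atol=1e-6)


class TestFeatureInteraction:
    CFG = InteractionConfig(channels=8, nodes=4, node_channels=4, crf_iters=2,
                            gam=GAMConfig(8, 4, 3))

    def test_output_concatenates_skip(self, rng):
        fi = FeatureInteraction(self.CFG, rng=rng)
        x = Tensor(rng.normal(size=(1, 8, 4, 4, 4)).astype(np.float32))
        y = fi(x)
        assert y.shape == (1, 16, 4, 4, 4)
        # the untouched skip feature rides along unchanged
        np.testing.assert_array_equal(y.data[:, 8:], x.data)

    def test_deterministic_under_seed(self):
        x = np.random.default_rng(0).normal(size=(1, 8, 4, 4, 4)).astype(np.float32)
        a = FeatureInteraction(self.CFG, rng=np.random.default_rng(5))(Tensor(x)).data
        b = FeatureInteraction(self.CFG, rng=np.random.default_rng(5))(Tensor(x)).data
        np.testing.assert_array_equal(a, b)

    def test_parameter_count_is_sum_of_parts(self, rng):
        fi = FeatureInteraction(self.CFG, rng=rng)
        parts = [fi.projector, fi.reasoner, fi.embed, fi.context, fi.fuse]
        assert count_parameters(fi) == sum(count_parameters(p) for p in parts)

    def test_end_to_end_gradients(self, rng):
        fi = FeatureInteraction(self.CFG, rng=rng, dtype=np.float64)
        x = rng.normal(size=(1, 8, 4, 4, 4))

        def loss():
            y = fi(Tensor(x))
            return (y * y).sum().item()

        fi.zero_grad()
        y = fi(Tensor(x))
        (y * y).sum().backward()
        named = dict(fi.named_parameters())
        picks = [named[k] for k in ["projector.assign.weight", "reasoner.adjacency",
                                    "reasoner.weight", "context.conv.layers.0.weight",
                                    "fuse.gate.weight", "embed.layers.0.weight"]]
        gradcheck(loss, picks, rng, n_coords=2, rtol=1e-3)
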