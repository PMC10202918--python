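"""Relevance propagation, GradCAM and guided backprop against literal
per-node oracles on tiny fixed-weight networks."""

import numpy as np
import pytest

from cortexcam import explain, nn


def lrp_oracle_dense_chain(weights, biases, gammas, x, eps=1e-9):
    """Literal node-by-node relevance propagation for a chain of affine
    layers with ReLU between them (none after the last).

    The forward pass runs in float32 (the network's working precision, so
    the redistribution starts from identical activations); the node-by-
    node redistribution itself is evaluated in float64.  ``gammas[l]`` is
    the LRP-gamma value for layer l (0 = LRP-0).  Returns (input
    relevance, output score).
    """
    acts = [np.asarray(x, dtype=np.float32)]
    for li, (W, b) in enumerate(zip(weights, biases)):
        z = acts[-1] @ W.astype(np.float32) + b.astype(np.float32)
        acts.append(np.maximum(z, 0) if li < len(weights) - 1 else z)
    acts = [a.astype(float) for a in acts]
    R = acts[-1].copy()  # seed with the output score
    for li in reversed(range(len(weights))):
        W = weights[li] + gammas[li] * np.maximum(weights[li], 0)
        b = biases[li] + gammas[li] * np.maximum(biases[li], 0)
        a = acts[li]
        R_low = np.zeros_like(a)
        for k in range(W.shape[1]):
            zk = sum(a[j] * W[j, k] for j in range(W.shape[0])) + b[k]
            denom = zk + eps * (1.0 if zk >= 0 else -1.0)
            for j in range(W.shape[0]):
                R_low[j] += a[j] * W[j, k] / denom * R[k]
        R = R_low
    return R, acts[-1]


def dense_net(weights, biases, input_shape):
    rng = np.random.default_rng(0)
    layers = [nn.Flatten()]
    for li, (W, b) in enumerate(zip(weights, biases)):
        d = nn.Dense(W.shape[0], W.shape[1], rng=rng)
        d.w[...] = W
        d.b[...] = b
        layers.append(d)
        if li < len(weights) - 1:
            layers.append(nn.ReLU())
    return nn.Sequential(layers)


class TestLrp:
    def test_single_linear_layer_exact(self):
        """One linear unit without bias: R_j = w_j x_j exactly."""
        W = np.array([[0.5], [-1.5], [2.0], [0.25]], dtype=np.float32)
        net = dense_net([W], [np.zeros(1, np.float32)], (2, 2))
        x = np.array([[1.0, -2.0], [3.0, 0.5]], dtype=np.float32)
        r = explain.lrp(net, x, explain.PropagationRules(gamma=0.0, eps=1e-12))
        assert np.allclose(r.values.ravel(), W[:, 0] * x.ravel(), atol=1e-7)

    def test_conservation_bias_free(self):
        """Total input relevance equals the pre-sigmoid score on a
        bias-free ReLU net."""
        rng = np.random.default_rng(4)
        W1 = rng.standard_normal((4, 3)).astype(np.float32)
        W2 = rng.standard_normal((3, 1)).astype(np.float32)
        net = dense_net([W1, W2], [np.zeros(3, np.float32), np.zeros(1, np.float32)], (2, 2))
        x = rng.standard_normal((2, 2)).astype(np.float32)
        r = explain.lrp(net, x, explain.PropagationRules(gamma=0.0, eps=1e-12))
        logit = float(net.forward(x.reshape(1, 2, 2, 1))[0, 0])
        assert abs(r.values.sum() - logit) < 1e-6

    @pytest.mark.parametrize("gamma", [0.0, 0.25])
    def test_matches_literal_oracle(self, gamma):
        """2-3-1 net with biases: node-by-node oracle to 1e-9."""
        rng = np.random.default_rng(7)
        W1 = rng.standard_normal((2, 3)).astype(np.float32)
        b1 = rng.standard_normal(3).astype(np.float32) * 0.1
        W2 = rng.standard_normal((3, 1)).astype(np.float32)
        b2 = np.zeros(1, np.float32)
        net = dense_net([W1, W2], [b1, b2], (2, 1))
        x = rng.standard_normal(2).astype(np.float32)
        # dense layers use LRP-0 in the implementation; oracle with gamma=0
        r = explain.lrp(net, x.reshape(2, 1), explain.PropagationRules(gamma=gamma))
        ref, _ = lrp_oracle_dense_chain(
            [W1.astype(float), W2.astype(float)],
            [b1.astype(float), b2.astype(float)],
            [0.0, 0.0],
            x.astype(float),
        )
        assert np.abs(r.values.ravel() - ref).max() < 1e-9

    def test_conv_gamma_matches_materialized_oracle(self):
        """Tiny conv net: materialize the convolution as a dense matrix and
        run the literal oracle with the gamma rule on it."""
        rng = np.random.default_rng(9)
        conv = nn.Conv(2, 1, 2, rng=rng)
        conv.b[...] = 0.0
        dense = nn.Dense(18, 1, rng=rng)
        dense.b[...] = 0.0
        net = nn.Sequential([conv, nn.ReLU(), nn.Flatten(), dense])
        x = rng.standard_normal((3, 3)).astype(np.float32)

        # conv as an 9 -> 18 matrix, probed column by column
        M = np.zeros((9, 18))
        for j in range(9):
            e = np.zeros((1, 3, 3, 1), dtype=np.float32)
            e.ravel()[j] = 1.0
            M[j] = conv.conv_raw(e, conv.w, None).reshape(-1)
        gamma = 0.25
        ref, _ = lrp_oracle_dense_chain(
            [M, dense.w.astype(float)],
            [np.zeros(18), np.zeros(1)],
            [gamma, 0.0],  # gamma on the conv layer, LRP-0 on the dense
            x.ravel().astype(float),
        )
        r = explain.lrp(net, x, explain.PropagationRules(gamma=gamma))
        assert np.abs(r.values.ravel() - ref).max() < 1e-9

    def test_batchnorm_folding_preserves_forward(self):
        rng = np.random.default_rng(11)
        conv = nn.Conv(2, 1, 2, rng=rng)
        bn = nn.BatchNorm(2)
        x = rng.standard_normal((4, 6, 6, 1)).astype(np.float32)
        bn.forward(conv.forward(x), train=True)  # give BN real stats
        w_eff, b_eff = explain.fold_batchnorm(conv, bn)
        direct = bn.forward(conv.forward(x), train=False)
        folded = conv.conv_raw(x, w_eff.astype(np.float32), b_eff.astype(np.float32))
        assert np.abs(direct - folded).max() < 1e-4

    def test_unsupported_layer_named_in_error(self):
        class Odd(nn.Layer):
            def forward(self, x, train=False):
                return x

        net = nn.Sequential([nn.Flatten(), Odd()])
        with pytest.raises(ValueError, match="Odd"):
            explain.lrp(net, np.zeros((2, 2)))


def pooled_conv_net(seed=5):
    """Conv(1->2) -> ReLU -> MaxPool(2,2) -> Flatten -> Dense(8,1)."""
    rng = np.random.default_rng(seed)
    conv = nn.Conv(2, 1, 2, rng=rng)
    dense = nn.Dense(8, 1, rng=rng)
    return nn.Sequential([conv, nn.ReLU(), nn.MaxPool((2, 2)), nn.Flatten(), dense])


class TestGradCam:
    def test_zero_gradients_zero_map(self):
        net = pooled_conv_net()
        net.layers[-1].w[...] = 0.0  # output blind to features
        x = np.random.default_rng(0).standard_normal((4, 4)).astype(np.float32)
        cam = explain.grad_cam(net, x, target_layer=2)
        assert not cam.values.any()
        assert cam.values.shape == (2, 2)

    def test_hand_evaluated_two_feature_maps(self):
        """Linear head makes the gradient analytic: dy/dA = w, so the map
        is ReLU(sum_n mean(w_n) * A_n)."""
        net = pooled_conv_net()
        x = np.random.default_rng(1).standard_normal((4, 4)).astype(np.float32)
        out = net.forward(x[None, ..., None], record=True)
        A = net.activations[3][0]  # pool output, (2, 2, 2)
        w = net.layers[-1].w[:, 0].reshape(2, 2, 2)
        wn = w.mean(axis=(0, 1))
        ref = np.maximum((wn * A).sum(axis=-1), 0.0)
        cam = explain.grad_cam(net, x, target_layer=2)
        assert np.abs(cam.values - ref).max() < 1e-6

    def test_nonnegative(self):
        net = pooled_conv_net(seed=8)
        x = np.random.default_rng(2).standard_normal((4, 4)).astype(np.float32)
        cam = explain.grad_cam(net, x)
        assert (cam.values >= 0).all()

    def test_bad_target_layer(self):
        net = pooled_conv_net()
        with pytest.raises(ValueError):
            explain.grad_cam(net, np.zeros((4, 4)), target_layer=99)


class TestGuidedBackprop:
    def test_equals_plain_bp_when_all_positive(self):
        """With positive weights, inputs and upstream gradients every gate
        is open and GBP coincides with the plain gradient."""
        rng = np.random.default_rng(3)
        conv = nn.Conv(2, 1, 1, rng=rng)
        conv.w[...] = np.abs(conv.w)
        dense = nn.Dense(16, 1, rng=rng)
        dense.w[...] = np.abs(dense.w)
        net = nn.Sequential([conv, nn.ReLU(), nn.Flatten(), dense])
        x = np.abs(rng.standard_normal((4, 4))).astype(np.float32)

        g = explain.guided_backprop(net, x)
        net.forward(x[None, ..., None], record=True)
        plain = net.backward(np.ones((1, 1), dtype=np.float32))[0, ..., 0]
        assert np.abs(g.values - plain).max() < 1e-7

    def test_differs_from_bp_on_negative_upstream(self):
        rng = np.random.default_rng(12)
        net = pooled_conv_net(seed=12)
        x = rng.standard_normal((4, 4)).astype(np.float32)
        g = explain.guided_backprop(net, x)
        net.forward(x[None, ..., None], record=True)
        plain = net.backward(np.ones((1, 1), dtype=np.float32))[0, ..., 0]
        # guided map never keeps a path that plain BP kills at the ReLU
        assert g.values.shape == plain.shape
        assert not np.allclose(g.values, plain)

    def test_requires_relu(self):
        rng = np.random.default_rng(0)
        net = nn.Sequential([nn.Flatten(), nn.Dense(4, 1, rng=rng)])
        with pytest.raises(ValueError):
            explain.guided_backprop(net, np.zeros((2, 2)))


class TestGuidedGradCam:
    def test_zero_cam_zero_ggcam(self):
        net = pooled_conv_net()
        net.layers[-1].w[...] = 0.0
        x = np.random.default_rng(0).standard_normal((4, 4)).astype(np.float32)
        gg = explain.guided_grad_cam(net, x, target_layer=2)
        assert not gg.values.any()

    def test_product_of_constituents(self):
        net = pooled_conv_net(seed=21)
        x = np.random.default_rng(5).standard_normal((4, 4)).astype(np.float32)
        cam = explain.grad_cam(net, x, target_layer=2)
        gbp = explain.guided_backprop(net, x)
        up = explain.upsample_to(cam.values, gbp.values.shape)
        gg = explain.guided_grad_cam(net, x, target_layer=2)
        assert np.abs(gg.values - up * gbp.values).max() < 1e-9

    def test_identity_upsampling_gives_gbp(self):
        """Without pooling the feature map matches the input shape; a map
        of ones turns GGCAM into the bare GBP gradient."""
        rng = np.random.default_rng(6)
        conv = nn.Conv(2, 1, 1, rng=rng)
        dense = nn.Dense(16, 1, rng=rng)
        net = nn.Sequential([conv, nn.ReLU(), nn.Flatten(), dense])
        x = rng.standard_normal((4, 4)).astype(np.float32)
        gbp = explain.guided_backprop(net, x)
        cam = explain.grad_cam(net, x, target_layer=1)
        gg_manual = explain.upsample_to(cam.values, (4, 4)) * gbp.values
        assert np.array_equal(explain.upsample_to(cam.values, (4, 4)), cam.values)
        gg = explain.guided_grad_cam(net, x, target_layer=1)
        assert np.abs(gg.values - gg_manual).max() < 1e-12


class TestLocalizationSanity:
    def test_single_pixel_linear_model(self):
        """A model reading exactly one pixel puts every method's argmax on
        that pixel."""
        W = np.zeros((16, 1), dtype=np.float32)
        W[9, 0] = 2.0
        rng = np.random.default_rng(0)
        d = nn.Dense(16, 1, rng=rng)
        d.w[...] = W
        d.b[...] = 0.0
        net = nn.Sequential([nn.Flatten(), d])
        x = np.abs(rng.standard_normal((4, 4))).astype(np.float32) + 0.5
        r = explain.lrp(net, x, explain.PropagationRules(gamma=0.0))
        assert np.argmax(np.abs(r.values)) == 9

        relu_net = nn.Sequential([nn.Flatten(), d, nn.ReLU(),
                                  _identity_dense(rng)])
        g = explain.guided_backprop(relu_net, x)
        assert np.argmax(np.abs(g.values)) == 9


def _identity_dense(rng):
    d = nn.Dense(1, 1, rng=rng)
    d.w[...] = 1.0
    d.b[...] = 0.0
    return d
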