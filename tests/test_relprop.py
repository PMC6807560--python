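"""Relevance propagation: epsilon rule, pooling routing, oracles, invariants."""

import numpy as np
import pytest

from relvox.layers import Conv3D, Dense, Flatten, MaxPool3D, Network, Sigmoid
from relvox.relprop import (
    RelpropConfig,
    gradient_times_input,
    lrp_explain,
    propagate_elementwise,
    propagate_linear,
    propagate_maxpool,
)

from conftest import make_dense_net


def brute_force_dense_lrp(net, x_flat, epsilon=0.0):
    """Independent double-sum evaluation of the epsilon rule on an all-dense
    network: explicit loops over every (i, j) index pair, starting from the
    logit.  Written against the formula, not against the implementation."""
    # forward, recording each dense layer's input
    a = np.asarray(x_flat, dtype=float)
    dense_inputs = []
    for layer in net.layers:
        if isinstance(layer, Dense):
            dense_inputs.append(a.copy())
            a = layer.W @ a + layer.b
        elif isinstance(layer, Flatten):
            a = a.reshape(-1)
        elif isinstance(layer, Sigmoid):
            logit = float(a[0])
    R = np.array([logit])
    for layer, x in zip(
        [l for l in reversed(net.layers) if isinstance(l, Dense)], reversed(dense_inputs)
    ):
        W = layer.W
        n_out, n_in = W.shape
        R_new = np.zeros(n_in)
        for i in range(n_in):
            for j in range(n_out):
                z_j = 0.0
                for k in range(n_in):
                    z_j += x[k] * W[j, k]
                denom = z_j + epsilon * (1.0 if z_j >= 0 else -1.0)
                R_new[i] += x[i] * W[j, i] / denom * R[j]
        R = R_new
    return R


class TestPropagateLinear:
    def test_two_input_dense_shares(self):
        # x=(2,4), w=(0.5,0.25): z=2, contributions (1,1); upstream R=2 -> (1,1)
        layer = Dense(2, 1)
        layer.W = np.array([[0.5, 0.25]])
        x = np.array([2.0, 4.0])
        R = propagate_linear(layer, x, np.array([2.0]), RelpropConfig(epsilon=0.0))
        np.testing.assert_allclose(R, [1.0, 1.0])

    def test_epsilon_leaks_relevance(self):
        layer = Dense(2, 1)
        layer.W = np.array([[0.5, 0.25]])
        x = np.array([2.0, 4.0])
        R = propagate_linear(layer, x, np.array([2.0]), RelpropConfig(epsilon=0.001))
        np.testing.assert_allclose(R, np.array([1.0, 1.0]) * (2.0 / 2.001))
        assert R.sum() < 2.0

    def test_zero_denominator_raises_at_epsilon_zero(self):
        layer = Dense(2, 1)
        layer.W = np.array([[1.0, -1.0]])
        x = np.array([1.0, 1.0])  # z = 0 exactly
        with pytest.raises(ZeroDivisionError):
            propagate_linear(layer, x, np.array([1.0]), RelpropConfig(epsilon=0.0))

    def test_conv_conserves_without_bias(self, rng):
        conv = Conv3D(2, 3, kernel_size=3)
        conv.init_weights(rng)
        x = rng.normal(size=(2, 4, 4, 4))
        out = conv.forward(x)
        R_up = rng.normal(size=out.shape)
        R = propagate_linear(conv, x, R_up, RelpropConfig(epsilon=0.0))
        np.testing.assert_allclose(R.sum(), R_up.sum(), rtol=1e-9)

    def test_bias_policies_differ_only_with_bias(self, rng):
        layer = Dense(3, 2)
        layer.W = rng.normal(size=(2, 3))
        layer.b = np.array([0.5, -0.2])
        x = rng.normal(size=3)
        R_up = np.array([1.0, 1.0])
        r_discard = propagate_linear(layer, x, R_up, RelpropConfig(bias_policy="discard"))
        r_absorb = propagate_linear(layer, x, R_up, RelpropConfig(bias_policy="absorb"))
        assert not np.allclose(r_discard, r_absorb)
        # discard ignores the bias entirely: conserves at epsilon=0
        r0 = propagate_linear(layer, x, R_up, RelpropConfig(epsilon=0.0, bias_policy="discard"))
        np.testing.assert_allclose(r0.sum(), R_up.sum(), rtol=1e-9)


class TestPropagateMaxpool:
    def test_winner_take_all(self):
        pool = MaxPool3D()
        x = np.zeros((1, 2, 2, 2))
        x[0, 0, 1, 0] = 0.9
        x[0, 0, 0, 0] = 0.2
        x[0, 1, 0, 0] = 0.5
        R = propagate_maxpool(pool, x, np.array([[[[1.0]]]]))
        assert R[0, 0, 1, 0] == 1.0
        assert R.sum() == 1.0

    def test_tie_goes_to_first_in_scan_order(self):
        pool = MaxPool3D()
        x = np.full((1, 2, 2, 2), 0.7)  # all tied
        R = propagate_maxpool(pool, x, np.array([[[[2.5]]]]))
        assert R[0, 0, 0, 0] == 2.5
        assert R.sum() == 2.5

    def test_conservation_random_tensor(self, rng):
        pool = MaxPool3D()
        x = rng.normal(size=(3, 6, 8, 4))
        out = pool.forward(x)
        R_up = rng.normal(size=out.shape)
        R = propagate_maxpool(pool, x, R_up)
        np.testing.assert_allclose(R.sum(), R_up.sum(), rtol=1e-12)


def test_elementwise_identity_and_flatten(rng):
    flat = Flatten()
    x = rng.normal(size=(2, 3, 3, 3))
    flat.forward(x)
    R_up = rng.normal(size=54)
    R = propagate_elementwise(flat, x, R_up)
    assert R.shape == x.shape
    np.testing.assert_allclose(R.sum(), R_up.sum())


class TestLrpExplain:
    def test_single_weight_identity_net(self):
        # dense with w=1 on a single voxel: all relevance lands there
        d = Dense(8, 1)
        d.W = np.zeros((1, 8))
        d.W[0, 3] = 1.0
        net = Network([Flatten(), d, Sigmoid()], (2, 2, 2))
        x = np.arange(1.0, 9.0).reshape(2, 2, 2)
        hm = lrp_explain(net, x, RelpropConfig(epsilon=0.0))
        _, logit, _ = net.forward(x)
        assert hm.data.reshape(-1)[3] == pytest.approx(logit)
        assert np.count_nonzero(hm.data) == 1

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        widths = [int(rng.integers(2, 5)), int(rng.integers(2, 5)), 1]
        net = make_dense_net(widths, rng, bias=False)
        x = rng.normal(size=(widths[0], 1, 1))
        for eps in (0.0, 0.001):
            hm = lrp_explain(net, x, RelpropConfig(epsilon=eps))
            expected = brute_force_dense_lrp(net, x.reshape(-1), epsilon=eps)
            np.testing.assert_allclose(hm.data.reshape(-1), expected, rtol=1e-10, atol=1e-12)

    def test_conservation_on_conv_net(self, rng):
        net = _tiny_conv_net(rng)
        x = rng.random((8, 8, 8))
        _, logit, _ = net.forward(x)
        hm = lrp_explain(net, x, RelpropConfig(epsilon=0.0))
        np.testing.assert_allclose(hm.total(), logit, rtol=1e-6)

    def test_sign_semantics_weight_negation(self, rng):
        net = _tiny_conv_net(rng)
        x = rng.random((8, 8, 8))
        hm = lrp_explain(net, x, RelpropConfig(epsilon=0.0))
        dense = [l for l in net.layers if isinstance(l, Dense)][-1]
        dense.W = -dense.W
        hm_neg = lrp_explain(net, x, RelpropConfig(epsilon=0.0))
        assert hm_neg.start_score == pytest.approx(-hm.start_score)
        np.testing.assert_allclose(hm_neg.data, -hm.data, rtol=1e-9, atol=1e-12)

    def test_epsilon_monotone_total_on_single_layer(self, rng):
        layer = Dense(5, 3)
        layer.W = rng.normal(size=(3, 5))
        x = rng.normal(size=5)
        R_up = np.abs(rng.normal(size=3))
        totals = []
        for eps in (0.0, 0.01, 0.1, 1.0):
            R = propagate_linear(layer, x, R_up, RelpropConfig(epsilon=eps))
            totals.append(abs(R.sum()))
        assert all(a >= b - 1e-12 for a, b in zip(totals, totals[1:]))

    def test_start_from_sigmoid_scales_seed(self, rng):
        net = _tiny_conv_net(rng)
        x = rng.random((8, 8, 8))
        score, logit, _ = net.forward(x)
        hm = lrp_explain(net, x, RelpropConfig(epsilon=0.0, start_from="sigmoid"))
        np.testing.assert_allclose(hm.total(), score, rtol=1e-6)


class TestGradientTimesInput:
    def test_single_dense_layer_equals_wx(self, rng):
        d = Dense(4, 1)
        d.W = rng.normal(size=(1, 4))
        net = Network([Flatten(), d, Sigmoid()], (4, 1, 1))
        x = rng.normal(size=(4, 1, 1))
        gi = gradient_times_input(net, x)
        np.testing.assert_allclose(gi.data.reshape(-1), d.W[0] * x.reshape(-1))
        hm = lrp_explain(net, x, RelpropConfig(epsilon=0.0))
        np.testing.assert_allclose(gi.data, hm.data, rtol=1e-12)

    def test_deep_linear_net_equals_lrp(self, rng):
        # activation-free (dense-only) stack: g*i == LRP(eps=0) within 1e-6
        net = make_dense_net([6, 4, 3, 1], rng, bias=False)
        x = rng.normal(size=(6, 1, 1))
        gi = gradient_times_input(net, x)
        hm = lrp_explain(net, x, RelpropConfig(epsilon=0.0))
        np.testing.assert_allclose(gi.data, hm.data, rtol=1e-6, atol=1e-10)

    def test_zero_input_gives_zero_map(self, rng):
        net = _tiny_conv_net(rng)
        gi = gradient_times_input(net, np.zeros((8, 8, 8)))
        np.testing.assert_allclose(gi.data, 0.0)


def _tiny_conv_net(rng):
    """conv(2 filters)+ELU+pool -> flatten -> dense(1) -> sigmoid, bias-free."""
    from relvox.layers import ELU

    conv = Conv3D(1, 2, kernel_size=3)
    conv.init_weights(rng)
    pool = MaxPool3D()
    dense = Dense(2 * 4 * 4 * 4, 1)
    dense.init_weights(rng)
    return Network([conv, ELU(), pool, Flatten(), dense, Sigmoid()], (8, 8, 8))
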