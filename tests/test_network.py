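"""CNN engine: architecture, forward correctness, gradients, training contract."""

from dataclasses import replace

import numpy as np
import pytest

from relvox.evaluation import SplitSpec
from relvox.layers import (
    Conv3D,
    Dense,
    ELU,
    Flatten,
    MaxPool3D,
    Network,
    Sigmoid,
    build_network,
    load_network,
    save_network,
)
from relvox.phantoms import PhantomConfig, generate_cohort
from relvox.training import (
    TrainConfig,
    apply_augment,
    augment,
    bce_loss,
    draw_augment_params,
    finetune,
    l2_penalty,
    lr_schedule,
    prepare_inputs,
    train,
)


class TestArchitecture:
    def test_default_has_four_64filter_convs(self):
        net = build_network((32, 32, 32))
        convs = net.conv_layers()
        assert len(convs) == 4
        assert all(c.out_channels == 64 and c.k == 3 for c in convs)
        assert sum(isinstance(l, MaxPool3D) for l in net.layers) == 4

    def test_filter_override(self):
        net = build_network((32, 32, 32), filters=8)
        assert all(c.out_channels == 8 for c in net.conv_layers())

    def test_shape_walk_ends_scalar(self):
        net = build_network((32, 32, 32), filters=4)
        shapes = net.shape_walk()
        assert shapes[0] == (1, 32, 32, 32)
        assert shapes[-1] == (1,)

    def test_alternative_pooling_placement(self):
        net = build_network((32, 32, 32), filters=4, pool_placement="every")
        assert sum(isinstance(l, MaxPool3D) for l in net.layers) == 4
        assert net.shape_walk()[-1] == (1,)

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            build_network((8, 8, 8), filters=4)

    def test_checkpoint_round_trip(self, tmp_path, rng):
        net = build_network((16, 16, 16), filters=2, seed=5)
        x = rng.random((16, 16, 16))
        score, logit, _ = net.forward(x)
        path = str(tmp_path / "ckpt.npz")
        save_network(net, path)
        back = load_network(path)
        s2, l2, _ = back.forward(x)
        assert s2 == pytest.approx(score)
        assert back.meta["filters"] == 2


class TestForward:
    def test_zero_weights_give_half_score(self):
        net = build_network((16, 16, 16), filters=2, seed=0)
        for layer in net.trainable():
            for _, w, _ in layer.params():
                w[...] = 0.0
        score, logit, _ = net.forward(np.random.default_rng(0).random((16, 16, 16)))
        assert logit == 0.0
        assert score == 0.5

    def test_hand_computed_toy_conv_net(self):
        # one 1x1x1 conv (w=2, b=0.5) + ELU + 2x2x2 pool + dense(sum) on a
        # 2-cubed input: every step done by hand
        conv = Conv3D(1, 1, kernel_size=1)
        conv.W = np.full((1, 1, 1, 1, 1), 2.0)
        conv.b = np.array([0.5])
        dense = Dense(1, 1)
        dense.W = np.array([[1.0]])
        net = Network([conv, ELU(), MaxPool3D(), Flatten(), dense, Sigmoid()], (2, 2, 2))
        x = np.array([[[0.1, 0.2], [0.3, 0.4]], [[0.5, 0.6], [0.7, 0.8]]])
        # conv: 2x+0.5 -> max = 2*0.8+0.5 = 2.1 (ELU identity for positives)
        score, logit, _ = net.forward(x)
        assert logit == pytest.approx(2.1)
        assert score == pytest.approx(1 / (1 + np.exp(-2.1)))

    def test_eval_forward_deterministic(self, rng):
        net = build_network((16, 16, 16), filters=2, seed=1)
        x = rng.random((16, 16, 16))
        s1, _, _ = net.forward(x)
        s2, _, _ = net.forward(x)
        assert s1 == s2

    def test_trace_reproduces_forward(self, rng):
        net = build_network((16, 16, 16), filters=2, seed=2)
        x = rng.random((16, 16, 16))
        _, _, trace = net.forward(x, record=True)
        assert len(trace) == len(net.layers)
        for layer, xin, xout in zip(net.layers, trace.inputs, trace.outputs):
            np.testing.assert_array_equal(layer.forward(xin), xout)

    def test_shape_mismatch_rejected(self):
        net = build_network((16, 16, 16), filters=2)
        with pytest.raises(ValueError, match="shape"):
            net.forward(np.zeros((8, 8, 8)))


class TestGradients:
    def test_finite_difference_match(self, rng):
        net = build_network((16, 16, 16), filters=2, seed=7)
        x = rng.random((16, 16, 16))
        label = 1

        def loss():
            s, _, _ = net.forward(x)
            return bce_loss(s, label)

        net.zero_grad()
        s, _, _ = net.forward(x)
        net.backward_logit(s - label)
        h = 1e-5
        for layer in net.trainable():
            for name, w, g in layer.params():
                flat, gflat = w.reshape(-1), g.reshape(-1)
                for k in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                    orig = flat[k]
                    flat[k] = orig + h
                    lp = loss()
                    flat[k] = orig - h
                    lm = loss()
                    flat[k] = orig
                    fd = (lp - lm) / (2 * h)
                    assert abs(fd - gflat[k]) <= 1e-4 * max(1.0, abs(fd))


@pytest.fixture(scope="module")
def tiny_setup():
    config = replace(
        PhantomConfig(),
        grid_shape=(16, 16, 16),
        noise_sd=0.0,
        lesion_count_mean=(0.0, 6.0),
        lesion_radius_range=(1.0, 2.0),
    )
    cohort = generate_cohort(config, 8, seed=3)
    X, y, ids = prepare_inputs(cohort)
    split = SplitSpec(tuple(ids[:12]), tuple(ids[12:16]), ())
    return cohort, X, y, ids, split


class TestTraining:
    def test_separable_cohort_reaches_perfect_training_accuracy(self, tiny_setup):
        cohort, X, y, ids, split = tiny_setup
        net = build_network((16, 16, 16), filters=4, dropout_p=0.0, seed=3)
        cfg = TrainConfig(
            learning_rate=3e-3, lr_decay=0.0, max_epochs=40, early_stop_patience=40,
            l2_lambda=0.0, batch_size=4, seed=3,
        )
        net, hist = train(net, cohort, split, cfg, X=X, y=y)
        idm = {s: i for i, s in enumerate(ids)}
        preds = [net.forward(X[idm[s]])[0] > 0.5 for s in split.train_ids]
        labels = [y[idm[s]] for s in split.train_ids]
        assert all(int(p) == int(l) for p, l in zip(preds, labels))

    def test_early_stop_after_patience(self, tiny_setup):
        cohort, X, y, ids, split = tiny_setup
        net = build_network((16, 16, 16), filters=2, seed=1)
        # freeze learning so validation loss can never improve after epoch 0
        cfg = TrainConfig(learning_rate=1e-30, max_epochs=50, early_stop_patience=1, seed=1)
        net, hist = train(net, cohort, split, cfg, X=X, y=y)
        assert hist.stopped_epoch == 1  # epoch 0 sets the best; epoch 1 stops

    def test_l2_penalty_matches_independent_sum(self, rng):
        net = build_network((16, 16, 16), filters=2, seed=4)
        convs = net.conv_layers()
        expected = 0.01 * (np.sum(convs[2].W**2) + np.sum(convs[3].W**2))
        assert l2_penalty(net, 0.01, (2, 3)) == pytest.approx(expected)
        assert l2_penalty(net, 0.0, (2, 3)) == 0.0

    def test_lr_schedule_closed_form(self):
        for step in (0, 1, 10, 500):
            assert lr_schedule(5e-4, 0.002, step) == pytest.approx(5e-4 / (1 + 0.002 * step))

    def test_training_bit_reproducible(self, tiny_setup):
        cohort, X, y, ids, split = tiny_setup
        outs = []
        for _ in range(2):
            net = build_network((16, 16, 16), filters=2, seed=9)
            cfg = TrainConfig(learning_rate=1e-3, max_epochs=3, early_stop_patience=3, seed=9)
            net, _ = train(net, cohort, split, cfg, X=X, y=y)
            outs.append(np.concatenate([w.ravel() for w in net.get_weights()]))
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_nonfinite_loss_aborts(self, tiny_setup):
        cohort, X, y, ids, split = tiny_setup
        net = build_network((16, 16, 16), filters=2, seed=1)
        for layer in net.trainable():
            for _, w, _ in layer.params():
                w[...] = np.float64(1e200)  # force overflow
        cfg = TrainConfig(learning_rate=1e-3, max_epochs=2, early_stop_patience=2, seed=1)
        with pytest.raises((FloatingPointError, ValueError)):
            train(net, cohort, split, cfg, X=X, y=y)


class TestFinetune:
    def test_zero_epochs_returns_pretrained_weights(self, tiny_setup_module):
        cohort, X, y, ids, split = tiny_setup_module
        pre = build_network((16, 16, 16), filters=2, seed=11)
        cfg = TrainConfig(max_epochs=0, seed=1)
        out, _ = finetune(pre, cohort, split, cfg, X=X, y=y)
        for a, b in zip(pre.get_weights(), out.get_weights()):
            np.testing.assert_array_equal(a, b)

    def test_architecture_mismatch_rejected(self, tiny_setup_module):
        cohort, X, y, ids, split = tiny_setup_module
        pre = build_network((32, 32, 32), filters=2, seed=1)
        with pytest.raises(ValueError, match="mismatch"):
            finetune(pre, cohort, split, TrainConfig(max_epochs=1))


@pytest.fixture(scope="module")
def tiny_setup_module():
    config = replace(PhantomConfig(), grid_shape=(16, 16, 16), lesion_radius_range=(1.0, 2.0))
    cohort = generate_cohort(config, 4, seed=3)
    X, y, ids = prepare_inputs(cohort)
    split = SplitSpec(tuple(ids[:6]), tuple(ids[6:8]), ())
    return cohort, X, y, ids, split


class TestAugment:
    def test_identity_transform(self, rng):
        x = rng.random((8, 8, 8))
        np.testing.assert_array_equal(apply_augment(x, False, 0, 0), x)

    def test_double_flip_is_identity(self, rng):
        x = rng.random((8, 8, 8))
        np.testing.assert_array_equal(
            apply_augment(apply_augment(x, True, 0, 0), True, 0, 0), x
        )

    def test_translation_inverse_on_interior_support(self):
        x = np.zeros((10, 10, 10))
        x[3:7, 3:7, 3:7] = np.random.default_rng(0).random((4, 4, 4))
        fwd = apply_augment(x, False, 2, -1)
        back = apply_augment(fwd, False, -2, 1)
        np.testing.assert_array_equal(back, x)

    def test_mask_receives_identical_transform(self, rng):
        x = rng.random((8, 8, 8))
        mask = (x > 0.5).astype(np.uint8)
        out, mout = augment(x, np.random.default_rng(5), mask=mask)
        # wherever the transformed volume is above threshold, the mask agrees
        flip, t0, t1 = draw_augment_params(np.random.default_rng(5))
        np.testing.assert_array_equal(out, apply_augment(x, flip, t0, t1))
        np.testing.assert_array_equal(mout, apply_augment(mask, flip, t0, t1))

    def test_translations_bounded_by_two_voxels(self):
        rng = np.random.default_rng(0)
        draws = [draw_augment_params(rng) for _ in range(200)]
        assert all(-2 <= t0 <= 2 and -2 <= t1 <= 2 for _, t0, t1 in draws)
        assert 0.3 < np.mean([f for f, _, _ in draws]) < 0.7
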