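"""Compact CNN: loss, architecture, training, LR range test, self-training."""

import math

import numpy as np
import pytest

from cvmstage import model as M
from cvmstage import nn


def random_probs(rng, n, k=6):
    return rng.dirichlet(np.ones(k), size=n)


class TestCategoricalCrossEntropy:
    def test_perfect_prediction_zero_loss(self):
        y = M.one_hot(np.array([1, 3, 6]))
        assert M.categorical_cross_entropy(y, y) == pytest.approx(0.0)

    def test_uniform_prediction_is_ln6(self):
        y = M.one_hot(np.array([2, 5]))
        p = np.full((2, 6), 1 / 6)
        assert M.categorical_cross_entropy(y, p) == pytest.approx(math.log(6))

    def test_half_probability_is_ln2(self):
        y = M.one_hot(np.array([1]))
        p = np.array([[0.5, 0.1, 0.1, 0.1, 0.1, 0.1]])
        assert M.categorical_cross_entropy(y, p) == pytest.approx(math.log(2))

    def test_sum_reduction_scales_with_n(self):
        y = M.one_hot(np.array([1, 1, 1]))
        p = np.tile([0.5, 0.1, 0.1, 0.1, 0.1, 0.1], (3, 1))
        s = M.categorical_cross_entropy(y, p, reduction="sum")
        assert s == pytest.approx(3 * math.log(2))

    def test_agrees_with_scalar_double_loop(self):
        """Vectorized loss vs brute-force double loop, 100 random inputs."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(1, 12))
            y = M.one_hot(rng.integers(1, 7, size=n))
            p = random_probs(rng, n)
            expected = 0.0
            for i in range(n):
                for j in range(6):
                    if y[i, j]:
                        expected -= math.log(max(p[i, j], 1e-12))
            got = M.categorical_cross_entropy(y, p, reduction="sum")
            assert got == pytest.approx(expected, abs=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(M.ContractError):
            M.categorical_cross_entropy(np.eye(6)[:2], np.full((3, 6), 1 / 6))

    def test_non_stochastic_rows_rejected(self):
        y = M.one_hot(np.array([1]))
        with pytest.raises(M.ContractError):
            M.categorical_cross_entropy(y, np.full((1, 6), 0.3))


class TestArchitecture:
    def test_default_has_five_conv_and_one_dense_block(self):
        net = M.build_model(M.ModelConfig(), seed=0)
        assert sum(isinstance(l, nn.Conv2D) for l in net.layers) == 5
        # dense block + classification head
        assert sum(isinstance(l, nn.Dense) for l in net.layers) == 2

    def test_output_is_probability_vector(self, rng):
        cfg = M.ModelConfig(input_side=32,
                            conv_blocks=M.small_conv_blocks(),
                            dense_width=32)
        net = M.build_model(cfg, seed=1)
        probs = M.predict_proba(net, rng.random((3, 32, 32)))
        assert probs.shape == (3, 6)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_parameter_count_matches_hand_arithmetic(self):
        """Layer-by-layer count for one small configuration."""
        cfg = M.ModelConfig(
            input_side=16,
            conv_blocks=(M.ConvBlockSpec(4, 3, 2, 0.0),
                         M.ConvBlockSpec(8, 3, 2, 0.0)),
            dense_width=10, n_classes=6)
        net = M.build_model(cfg, seed=0)
        conv1 = 3 * 3 * 1 * 4 + 4          # W + b
        bn1 = 4 + 4                        # gamma + beta
        conv2 = 3 * 3 * 4 * 8 + 8
        bn2 = 8 + 8
        flat = 4 * 4 * 8                   # 16 -> 8 -> 4 spatial
        dense1 = flat * 10 + 10
        bn3 = 10 + 10
        dense2 = 10 * 6 + 6
        assert net.n_params == conv1 + bn1 + conv2 + bn2 + dense1 + bn3 + dense2

    def test_pooling_cascade_exhaustion_rejected(self):
        with pytest.raises(ValueError):
            M.ModelConfig(input_side=16,
                          conv_blocks=tuple(M.ConvBlockSpec(4, 3, 2, 0.0)
                                            for _ in range(5)))

    def test_duplicate_images_get_identical_rows(self, rng):
        cfg = M.ModelConfig(input_side=32, conv_blocks=M.small_conv_blocks(),
                            dense_width=16)
        net = M.build_model(cfg, seed=2)
        img = rng.random((32, 32), dtype=np.float32)
        probs = M.predict_proba(net, np.stack([img, img]))
        np.testing.assert_array_equal(probs[0], probs[1])

    def test_checkpoint_round_trip(self, tmp_path, rng):
        cfg = M.ModelConfig(input_side=32, conv_blocks=M.small_conv_blocks(),
                            dense_width=16)
        net = M.build_model(cfg, seed=3)
        x = rng.random((4, 32, 32))
        before = M.predict_proba(net, x)
        M.save_checkpoint(net, tmp_path / "ckpt.npz", {"seed": 3})
        restored, meta = M.load_checkpoint(tmp_path / "ckpt.npz")
        np.testing.assert_array_equal(M.predict_proba(restored, x), before)
        assert meta["seed"] == 3


class TestTraining:
    def small_setup(self, tiny_train_data, seed=0):
        cfg = M.ModelConfig(input_side=32, conv_blocks=M.small_conv_blocks(),
                            dense_width=64)
        return M.build_model(cfg, seed=seed), tiny_train_data

    def test_zero_learning_rate_changes_nothing(self, tiny_train_data):
        net, data = self.small_setup(tiny_train_data)
        before = [p.copy() for l in net.layers for p in l.params.values()]
        tc = M.TrainConfig(optimizer="sgd", learning_rate=0.0, epochs=1,
                           seed=0, restore_best=False, refresh_bn=False)
        net, hist = M.train(net, data["train"], None, tc)
        after = [p for l in net.layers for p in l.params.values()]
        for b, a in zip(before, after):
            np.testing.assert_array_equal(b, a)
        assert len(hist) == 1

    def test_identical_seeds_identical_histories(self, tiny_train_data):
        histories = []
        for _ in range(2):
            net, data = self.small_setup(tiny_train_data, seed=5)
            tc = M.TrainConfig(epochs=2, seed=9)
            _, hist = M.train(net, data["train"], data["val"], tc)
            histories.append(hist)
        assert histories[0].train_loss == histories[1].train_loss
        assert histories[0].val_accuracy == histories[1].val_accuracy

    def test_loss_decreases_and_train_set_learned(self):
        """On clean zero-noise data the network fits the training set far
        beyond chance (full separation needs benchmark-scale data; this is
        the reduced-size sanity check)."""
        from cvmstage import synthdata

        gen = synthdata.GeneratorConfig(
            image_size=64, n_per_class=15, noise_sd=0, rotation_jitter=0,
            scale_jitter=0, gradient_amplitude=0, seed=21)
        samples = synthdata.generate_samples(gen)
        train = synthdata.samples_to_arrays(samples, "train")
        net = M.build_model(
            M.ModelConfig(input_side=64, conv_blocks=M.small_conv_blocks(),
                          dense_width=64), seed=0)
        tc = M.TrainConfig(epochs=30, batch_size=8, seed=1,
                           restore_best=False)
        net, hist = M.train(net, train, None, tc)
        assert hist.train_loss[-1] < 0.5 * hist.train_loss[0]
        _, acc = M.evaluate(net, *train)
        assert acc >= 0.6  # chance level is 1/6
        assert len(hist) == tc.epochs
        assert all(0 <= a <= 1 for a in hist.train_accuracy)

    def test_history_length_and_finiteness(self, tiny_train_data):
        net, data = self.small_setup(tiny_train_data)
        tc = M.TrainConfig(epochs=2, seed=3)
        _, hist = M.train(net, data["train"], data["val"], tc)
        frame = hist.to_frame()
        assert len(frame) == 2
        assert np.isfinite(frame[["train_loss", "val_loss"]].to_numpy()).all()


class TestLRRangeTest:
    def test_schedule_hits_bounds_and_is_geometric(self, tiny_train_data):
        cfg = M.ModelConfig(input_side=32, conv_blocks=M.small_conv_blocks(),
                            dense_width=16)
        net = M.build_model(cfg, seed=0)
        res = M.lr_range_test(net, tiny_train_data["train"], (1e-1, 1e1),
                              n_steps=13)
        lrs = np.array(res.learning_rates)
        assert lrs[0] == pytest.approx(0.1)
        assert lrs[-1] == pytest.approx(10.0)
        ratios = lrs[1:] / lrs[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-10)

    def test_two_steps_gives_exactly_the_bounds(self, tiny_train_data):
        cfg = M.ModelConfig(input_side=32, conv_blocks=M.small_conv_blocks(),
                            dense_width=16)
        net = M.build_model(cfg, seed=0)
        res = M.lr_range_test(net, tiny_train_data["train"], (1e-3, 1.0),
                              n_steps=2)
        assert res.learning_rates == (pytest.approx(1e-3), pytest.approx(1.0))

    def test_model_state_restored_after_sweep(self, tiny_train_data):
        cfg = M.ModelConfig(input_side=32, conv_blocks=M.small_conv_blocks(),
                            dense_width=16)
        net = M.build_model(cfg, seed=0)
        x = tiny_train_data["train"][0][:4]
        before = M.predict_proba(net, x)
        M.lr_range_test(net, tiny_train_data["train"], (1e-2, 1.0), n_steps=8)
        np.testing.assert_array_equal(M.predict_proba(net, x), before)

    def test_invalid_bounds_rejected(self, tiny_train_data):
        cfg = M.ModelConfig(input_side=32, conv_blocks=M.small_conv_blocks(),
                            dense_width=16)
        net = M.build_model(cfg, seed=0)
        with pytest.raises(M.ContractError):
            M.lr_range_test(net, tiny_train_data["train"], (1.0, 0.1), 10)
        with pytest.raises(M.ContractError):
            M.lr_range_test(net, tiny_train_data["train"], (0.1, 1.0), 1)


class TestSelectLR:
    def test_known_steepest_descent_point(self):
        """Analytic loss curve whose steepest drop is at a known index."""
        lrs = tuple(0.1 * (100 ** (k / 19)) for k in range(20))
        losses = [2.0] * 20
        # steepest smoothed decrease ending at index 10
        for i, drop in [(8, 0.1), (9, 0.5), (10, 1.0), (11, 0.3)]:
            losses[i] = losses[i - 1] - drop
        for i in range(12, 20):
            losses[i] = losses[11]
        res = M.LRRangeResult(lrs, tuple(losses))
        got = M.select_lr(res, smooth_window=1)
        assert got == pytest.approx(lrs[10])

    def test_flat_loss_warns_and_returns_lower_bound(self):
        res = M.LRRangeResult((0.1, 0.3, 1.0), (1.0, 1.0, 1.0))
        with pytest.warns(UserWarning):
            assert M.select_lr(res) == pytest.approx(0.1)

    def test_two_point_result_returns_drop_point(self):
        res = M.LRRangeResult((0.1, 1.0), (2.0, 1.0))
        assert M.select_lr(res, smooth_window=1) == pytest.approx(1.0)


class TestSelfTraining:
    def make_net(self):
        cfg = M.ModelConfig(input_side=32, conv_blocks=M.small_conv_blocks(),
                            dense_width=16)
        return M.build_model(cfg, seed=0)

    def test_threshold_validation(self, tiny_train_data):
        net = self.make_net()
        with pytest.raises(M.ContractError):
            M.self_training_update(net, tiny_train_data["train"],
                                   tiny_train_data["val"], prob_threshold=1.5)

    def test_empty_pool_is_noop_with_notice(self, tiny_train_data):
        net = self.make_net()
        empty = (np.empty((0, 32, 32)), np.empty((0,), dtype=int))
        tr, pool, log = M.self_training_update(
            net, tiny_train_data["train"], empty, 0.9)
        assert len(pool[1]) == 0
        assert "notice" in log[0]

    def test_exactly_the_qualifying_subset_moves(self, tiny_train_data):
        """Enumerate the pool against the rule with the model's own
        probabilities and check the move set matches."""
        net = self.make_net()
        xt, yt = tiny_train_data["train"]
        xp, yp = tiny_train_data["val"]
        probs = M.predict_proba(net, xp)
        pred = probs.argmax(axis=1) + 1
        conf = probs.max(axis=1)
        thr = float(np.median(conf))  # guarantees a nontrivial split
        expected = set(np.flatnonzero((pred == yp) & (conf >= thr)))
        new_train, new_pool, log = M.self_training_update(
            net, (xt, yt), (xp, yp), thr)
        moved = {e["pool_index"] for e in log if "pool_index" in e}
        assert moved == expected
        assert len(new_train[1]) == len(yt) + len(expected)
        assert len(new_pool[1]) == len(yp) - len(expected)

    def test_impossible_threshold_moves_nothing(self, tiny_train_data):
        net = self.make_net()
        xp, yp = tiny_train_data["val"]
        probs_max = M.predict_proba(net, xp).max(axis=1)
        if np.all(probs_max < 1.0):
            _, new_pool, log = M.self_training_update(
                net, tiny_train_data["train"], (xp, yp), 1.0)
            assert len(new_pool[1]) == len(yp)
            assert not [e for e in log if "pool_index" in e]
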