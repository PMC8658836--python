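import numpy as np
import pytest

from parsiopt.multitask_net import (
    TaskLabelMatrix,
    TrainingConfig,
    activate,
    gradients,
    init_weights,
    masked_bce_loss,
    predict,
    train,
)
from parsiopt.search_space import ArchitectureConfig


def tiny_arch(**over):
    base = {
        "neurons_layer1": 6, "neurons_layer2": 0, "neurons_layer3": 0,
        "dropout": 0.0, "learning_rate": 1e-2, "epochs": 5,
        "activation": "relu", "optimizer": "sgd", "penalty": "none",
    }
    base.update(over)
    return ArchitectureConfig.from_mapping(base)


class TestActivations:
    def test_sigmoid_at_zero(self):
        assert activate("sigmoid", np.array(0.0)) == 0.5

    @pytest.mark.parametrize(
        "kind,z,expected",
        [
            ("relu", -3.0, 0.0),
            ("relu", 2.0, 2.0),
            ("elu", 1.0, 1.0),
            ("tanh", 0.0, 0.0),
        ],
    )
    def test_pointwise_values(self, kind, z, expected):
        assert activate(kind, np.array(z)) == pytest.approx(expected)

    def test_elu_lower_limit(self):
        assert activate("elu", np.array(-50.0)) == pytest.approx(-1.0)

    def test_ranges(self, rng):
        z = rng.normal(scale=5, size=1000)
        assert np.all((activate("sigmoid", z) > 0) & (activate("sigmoid", z) < 1))
        assert np.all(activate("relu", z) >= 0)
        assert np.all(np.abs(activate("tanh", z)) < 1)
        assert np.all(activate("elu", z) >= -1)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            activate("swish", np.array(1.0))


class TestTaskLabelMatrix:
    def test_rejects_row_with_no_labels(self):
        vals = np.array([[1.0, 0.0], [np.nan, np.nan]])
        with pytest.raises(ValueError):
            TaskLabelMatrix(vals)

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError):
            TaskLabelMatrix(np.array([[0.5]]))


class TestMaskedBce:
    def test_hand_computed_two_sample_loss(self):
        labels = TaskLabelMatrix(np.array([[1.0], [0.0]]))
        p = np.array([[0.8], [0.4]])
        expected = -(np.log(0.8) + np.log(0.6)) / 2
        assert masked_bce_loss(p, labels) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.3669, abs=1e-4)

    def test_perfect_predictions_near_zero(self):
        labels = TaskLabelMatrix(np.array([[1.0, 0.0]]))
        p = np.array([[1.0, 0.0]])
        assert masked_bce_loss(p, labels) < 1e-6

    def test_all_missing_task_is_ignored(self, rng):
        y = rng.integers(0, 2, (10, 2)).astype(float)
        p3 = rng.random((10, 3))
        y3 = np.column_stack([y, np.full(10, np.nan)])
        loss3 = masked_bce_loss(p3, TaskLabelMatrix(y3))
        loss2 = masked_bce_loss(p3[:, :2], TaskLabelMatrix(y))
        assert loss3 == pytest.approx(loss2, rel=1e-12)

    def test_all_missing_errors(self):
        labels = TaskLabelMatrix(np.full((2, 1), np.nan), allow_empty_rows=True)
        with pytest.raises(ValueError):
            masked_bce_loss(np.full((2, 1), 0.5), labels)

    def test_l2_penalty_added(self, rng):
        w = init_weights(4, (3,), 1, rng)
        labels = TaskLabelMatrix(np.array([[1.0]]))
        p = np.array([[0.5]])
        base = masked_bce_loss(p, labels, w, "none", 0.0)
        pen = masked_bce_loss(p, labels, w, "L2", 0.1)
        assert pen == pytest.approx(base + 0.1 * w.l2(), rel=1e-12)


def _numeric_grad(X, labels, w, penalty, pw, idx_iter, eps=1e-6):
    out = []
    for arr, idx in idx_iter:
        orig = arr[idx]
        arr[idx] = orig + eps
        lp = masked_bce_loss(predict(X, w), labels, w, penalty, pw)
        arr[idx] = orig - eps
        lm = masked_bce_loss(predict(X, w), labels, w, penalty, pw)
        arr[idx] = orig
        out.append((lp - lm) / (2 * eps))
    return np.array(out)


class TestGradients:
    @pytest.mark.parametrize("act", ["sigmoid", "relu", "tanh", "elu"])
    @pytest.mark.parametrize("penalty", ["none", "L1", "L2"])
    def test_backprop_matches_finite_differences(self, act, penalty, rng):
        X = rng.random((5, 7))
        yv = rng.integers(0, 2, (5, 3)).astype(float)
        yv[rng.random((5, 3)) < 0.3] = np.nan
        yv[~np.isfinite(yv).any(axis=1), 0] = 1.0
        labels = TaskLabelMatrix(yv)
        w = init_weights(7, (6, 4), 3, rng, hidden_activation=act, std=0.3)
        _, dW, db = gradients(X, labels, w, penalty=penalty, penalty_weight=1e-3)
        picks = []
        analytic = []
        for li in range(w.n_layers):
            for arr, g in ((w.W[li], dW[li]), (w.b[li], db[li])):
                for _ in range(3):
                    idx = tuple(int(rng.integers(0, s)) for s in arr.shape)
                    picks.append((arr, idx))
                    analytic.append(g[idx])
        numeric = _numeric_grad(X, labels, w, penalty, 1e-3, picks)
        analytic = np.array(analytic)
        denom = np.maximum(np.abs(numeric), 1e-4)
        assert np.max(np.abs(numeric - analytic) / denom) <= 1e-5

    def test_masking_leaves_gradients_unchanged(self, rng):
        X = rng.random((6, 5))
        yv = rng.integers(0, 2, (6, 2)).astype(float)
        labels = TaskLabelMatrix(yv)
        w = init_weights(5, (4,), 2, rng)
        loss_a, dW_a, _ = gradients(X, labels, w)
        # append all-missing rows and an all-missing column
        X2 = np.vstack([X, rng.random((2, 5))])
        y2 = np.vstack([yv, np.full((2, 2), np.nan)])
        y2 = np.column_stack([y2, np.full(8, np.nan)])
        w2 = init_weights(5, (4,), 3, rng)
        w2.W[:-1] = [m.copy() for m in w.W[:-1]]
        w2.b[:-1] = [b.copy() for b in w.b[:-1]]
        w2.W[-1][:, :2] = w.W[-1]
        w2.b[-1][:2] = w.b[-1]
        labels2 = TaskLabelMatrix(y2, allow_empty_rows=True)
        loss_b, dW_b, _ = gradients(X2, labels2, w2)
        assert loss_b == pytest.approx(loss_a, rel=1e-12)
        np.testing.assert_allclose(dW_b[0], dW_a[0], rtol=1e-12)


class TestTraining:
    def test_zero_epochs_returns_initial_weights(self, rng):
        X = rng.random((10, 8))
        labels = TaskLabelMatrix(rng.integers(0, 2, (10, 1)).astype(float))
        arch = tiny_arch()
        cfg = TrainingConfig(epochs=0, seed=4)
        w = train(X, labels, arch, cfg)
        w_init = init_weights(8, (6,), 1, np.random.default_rng(4),
                              hidden_activation="relu")
        for a, b in zip(w.W, w_init.W):
            np.testing.assert_array_equal(a, b)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train(
                np.empty((0, 4)),
                TaskLabelMatrix(np.empty((0, 1))),
                tiny_arch(),
                TrainingConfig(),
            )

    def test_identical_seeds_identical_loss_trajectories(self, rng):
        X = rng.random((40, 10))
        labels = TaskLabelMatrix(rng.integers(0, 2, (40, 2)).astype(float))
        arch = tiny_arch(optimizer="adam", dropout=0.1)
        traj = []
        for _ in range(2):
            losses = []
            cfg = TrainingConfig(
                epochs=3, optimizer="adam", dropout=0.1, batch_size=16, seed=9
            )
            train(X, labels, arch, cfg, record_loss=losses)
            traj.append(losses)
        assert traj[0] == traj[1]

    @pytest.mark.parametrize("opt", ["sgd", "adam", "rmsprop", "adagrad"])
    def test_every_optimizer_reduces_loss(self, opt, rng):
        X = rng.random((60, 12))
        w_true = rng.normal(size=12)
        y = (X @ w_true > np.median(X @ w_true)).astype(float)[:, None]
        labels = TaskLabelMatrix(y)
        arch = tiny_arch(optimizer=opt, learning_rate=1e-2, epochs=30)
        losses = []
        cfg = TrainingConfig(
            epochs=30, learning_rate=1e-2, optimizer=opt, batch_size=60, seed=0
        )
        train(X, labels, arch, cfg, record_loss=losses)
        assert losses[-1] < losses[0]

    def test_l2_penalty_shrinks_weights(self, rng):
        X = rng.random((50, 10))
        labels = TaskLabelMatrix(rng.integers(0, 2, (50, 1)).astype(float))
        arch_free = tiny_arch(epochs=20)
        arch_pen = tiny_arch(epochs=20, penalty="L2")
        cfg_free = TrainingConfig(epochs=20, learning_rate=1e-2, seed=5)
        cfg_pen = TrainingConfig(
            epochs=20, learning_rate=1e-2, penalty="L2", penalty_weight=0.05,
            seed=5,
        )
        w_free = train(X, labels, arch_free, cfg_free)
        w_pen = train(X, labels, arch_pen, cfg_pen)
        assert w_pen.l2() < w_free.l2()


class TestPredict:
    def test_zero_weights_give_half_probabilities(self, rng):
        w = init_weights(4, (3,), 2, rng)
        for m in w.W:
            m[:] = 0.0
        X = rng.random((5, 4))
        np.testing.assert_allclose(predict(X, w), 0.5)

    def test_probability_range(self, rng):
        w = init_weights(6, (5, 4), 3, rng, std=1.0)
        p = predict(rng.random((20, 6)), w)
        assert np.all((p > 0) & (p < 1))

    def test_shape_mismatch_rejected(self, rng):
        w = init_weights(6, (5,), 1, rng)
        with pytest.raises(ValueError):
            predict(rng.random((3, 7)), w)


class TestDropout:
    def test_inverted_dropout_preserves_expected_preactivation(self, rng):
        """Monte-Carlo over masks: the expected output-layer pre-activation
        under inverted dropout equals the no-dropout pre-activation."""
        X = rng.random((1, 30))
        w = init_weights(30, (20,), 1, rng, std=0.5)
        hidden = activate("relu", X @ w.W[0] + w.b[0])
        ref = hidden @ w.W[1] + w.b[1]
        rate = 0.5
        acc = np.zeros_like(ref)
        n = 10_000
        for _ in range(n):
            keep = (rng.random(hidden.shape) >= rate) / (1 - rate)
            acc += (hidden * keep) @ w.W[1] + w.b[1]
        assert np.abs(acc / n - ref).max() <= 0.02 * np.abs(ref).max()
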