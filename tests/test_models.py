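"""Model construction, training mechanics, the SVM baseline, prediction."""

import numpy as np
import pytest

from dbmca import nn
from dbmca.models import (
    SvmConfig,
    TrainConfig,
    _DualNet,
    build_dbmca,
    default_cnn_branch,
    default_dnn_branch,
    early_stopping_trace,
    flatten_input,
    predict,
    small_cnn_branch,
    small_dnn_branch,
    train_model,
    train_svm,
)


@pytest.fixture(scope="module")
def tiny_task():
    """Trivially separable two-class 16 px task (blob size 3 vs 8 px)."""
    rng = np.random.default_rng(0)
    n = 60
    images = np.zeros((n, 16, 16))
    masks = np.zeros((n, 16, 16))
    labels = np.zeros(n, dtype=np.int64)
    for i in range(n):
        r = 2 if i % 2 == 0 else 5
        labels[i] = 0 if i % 2 == 0 else 1
        rr, cc = np.mgrid[0:16, 0:16]
        blob = (rr - 8) ** 2 + (cc - 8) ** 2 <= r**2
        masks[i][blob] = 1.0
        images[i] = 0.1 + 0.02 * rng.standard_normal((16, 16))
        images[i][blob] = 0.8
    return images, masks, labels


def _tiny_cnn():
    return default_cnn_branch(output_width=8, filters=(4, 4, 8, 8), dense_units=16)


def _tiny_dnn():
    return default_dnn_branch(output_width=8, hidden=16)


class TestSpecs:
    def test_fused_width_is_additive(self):
        spec = build_dbmca(default_cnn_branch(output_width=128),
                           default_dnn_branch(output_width=64))
        assert spec.fused_width == 192

    def test_inconsistent_fused_width_rejected(self):
        from dbmca.models import ModelSpec

        with pytest.raises(ValueError):
            ModelSpec(image_branch=default_cnn_branch(output_width=8),
                      mask_branch=default_dnn_branch(output_width=8),
                      fused_width=99)

    def test_branch_step_counts(self):
        # four-stage CNN pattern in 19 named steps, dense branch in 7
        assert len(default_cnn_branch().layers) == 19
        assert len(default_dnn_branch().layers) == 7

    def test_zeroed_head_gives_uniform_probabilities(self):
        spec = build_dbmca(_tiny_cnn(), _tiny_dnn())
        net = _DualNet(spec, (16, 16), np.random.default_rng(0))
        for p in net.head.params():
            p[...] = 0.0
        probs = net.forward(np.zeros((3, 16, 16)), np.zeros((3, 16, 16)))
        assert np.allclose(probs, 1 / 6)

    def test_probabilities_form_a_simplex(self):
        spec = build_dbmca(_tiny_cnn(), _tiny_dnn())
        net = _DualNet(spec, (16, 16), np.random.default_rng(1))
        x = np.random.default_rng(2).random((5, 16, 16))
        probs = net.forward(x, x)
        assert (probs >= 0).all()
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)


class TestFlatten:
    def test_512_grid_gives_262144(self):
        assert flatten_input(np.zeros((512, 512))).shape == (262144,)

    def test_row_major_order(self):
        v = flatten_input(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert list(v) == [1.0, 2.0, 3.0, 4.0]

    def test_reshape_inverts(self):
        g = np.random.default_rng(0).random((7, 5))
        assert np.array_equal(flatten_input(g).reshape(7, 5), g)

    def test_non_2d_rejected(self):
        with pytest.raises(ValueError):
            flatten_input(np.zeros(10))


class TestEarlyStopping:
    def test_patience_rule_hand_simulated(self):
        # losses [1.0, 0.9, 0.95, 0.96], patience 2 -> stop at 4, best at 2
        assert early_stopping_trace([1.0, 0.9, 0.95, 0.96], 2) == (4, 2)

    def test_monotone_improvement_runs_to_end(self):
        assert early_stopping_trace([3, 2, 1], 2) == (3, 3)

    def test_training_history_obeys_patience(self, tiny_task):
        images, _, labels = tiny_task
        cfg = TrainConfig(max_epochs=30, early_stopping_patience=2, seed=0)
        m = train_model(_tiny_cnn(), images, labels, cfg)
        losses = [h["val_loss"] for h in m.history]
        assert early_stopping_trace(losses, 2) == (m.stopped_epoch, m.best_epoch)
        assert len(m.history) <= 30


class TestTraining:
    def test_same_seed_identical_history(self, tiny_task):
        images, masks, labels = tiny_task
        cfg = TrainConfig(max_epochs=4, early_stopping_patience=4, seed=5)
        spec = build_dbmca(_tiny_cnn(), _tiny_dnn())
        h1 = train_model(spec, (images, masks), labels, cfg).history
        h2 = train_model(spec, (images, masks), labels, cfg).history
        assert h1 == h2

    def test_separable_task_learned(self, tiny_task):
        images, masks, labels = tiny_task
        cfg = TrainConfig(max_epochs=30, early_stopping_patience=6, seed=1)
        m = train_model(build_dbmca(_tiny_cnn(), _tiny_dnn()), (images, masks), labels, cfg)
        y, probs = predict(m, (images, masks))
        assert (y == labels).mean() >= 0.95
        assert probs.shape == (len(labels), 6)

    def test_prediction_deterministic_dropout_off(self, tiny_task):
        images, masks, labels = tiny_task
        cfg = TrainConfig(max_epochs=2, early_stopping_patience=2, seed=2)
        m = train_model(build_dbmca(_tiny_cnn(), _tiny_dnn()), (images, masks), labels, cfg)
        _, p1 = predict(m, (images, masks))
        _, p2 = predict(m, (images, masks))
        assert np.array_equal(p1, p2)

    def test_single_class_rejected(self, tiny_task):
        images, _, labels = tiny_task
        with pytest.raises(ValueError):
            train_model(_tiny_cnn(), images, np.zeros_like(labels), TrainConfig(seed=0))

    def test_out_of_range_labels_rejected(self, tiny_task):
        images, _, labels = tiny_task
        bad = labels.copy()
        bad[0] = 7
        with pytest.raises(ValueError):
            train_model(_tiny_cnn(), images, bad, TrainConfig(seed=0))

    def test_batch_prediction_length(self, tiny_task):
        images, _, labels = tiny_task
        m = train_model(_tiny_dnn(), images, labels,
                        TrainConfig(max_epochs=2, early_stopping_patience=2, seed=3))
        y, _ = predict(m, images[:17])
        assert len(y) == 17

    def test_argmax_tie_breaks_to_lowest_class(self):
        probs = np.array([[0.3, 0.3, 0.1, 0.1, 0.1, 0.1]])
        assert probs.argmax(axis=1)[0] == 0


class TestSvm:
    def test_config_mirrors_liblinear_flags(self):
        cfg = SvmConfig()
        assert cfg.C == 4.0 and cfg.tolerance == 1e-3 and cfg.multiclass == "ovr"

    def test_separable_two_class(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.1, 0.0], [1.0, 0.9]])
        y = np.array([0, 1, 0, 1])
        m = train_svm(X, y)
        pred, probs = predict(m, X)
        assert (pred == y).all() and probs is None

    def test_duplicated_data_same_decision(self):
        # separable clusters: the (near-hard-margin) solution is set by the
        # support vectors, so duplicating every point keeps the decision rule
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0.0, 0.1, (10, 4)), rng.normal(3.0, 0.1, (10, 4))])
        y = np.repeat([0, 1], 10)
        m1 = train_svm(X, y)
        m2 = train_svm(np.vstack([X, X]), np.concatenate([y, y]))
        grid = rng.normal(1.5, 1.5, (50, 4))
        assert np.array_equal(predict(m1, grid)[0], predict(m2, grid)[0])

    def test_ovr_argmax_matches_per_class_score_oracle(self):
        # 6-point, 3-class set; prediction must equal argmax over the three
        # fitted binary decision scores
        X = np.array([[0, 0], [0.2, 0], [2, 2], [2.2, 2], [0, 4], [0.2, 4.2]])
        y = np.array([0, 0, 1, 1, 2, 2])
        m = train_svm(X, y)
        est = m.network
        scores = est.decision_function(X)
        oracle = est.classes_[scores.argmax(axis=1)]
        pred, _ = predict(m, X)
        assert np.array_equal(pred, oracle)

    def test_width_mismatch_rejected(self):
        X = np.random.default_rng(0).random((10, 4))
        y = np.arange(10) % 2
        m = train_svm(X, y)
        with pytest.raises(ValueError):
            predict(m, np.zeros((3, 5)))


class TestNnEngine:
    def test_conv_backward_matches_numeric_gradient(self):
        rng = np.random.default_rng(0)
        conv = nn.Conv2D(1, 2, rng)
        x = rng.random((1, 1, 5, 5)).astype(nn.DTYPE)
        out = conv.forward(x, train=False, rng=rng)
        g = np.ones_like(out)
        conv.backward(g)
        # numeric check on one weight
        eps = 1e-3
        i, j = 3, 1
        w0 = conv.W[i, j]
        conv.W[i, j] = w0 + eps
        up = conv.forward(x, train=False, rng=rng).sum()
        conv.W[i, j] = w0 - eps
        dn = conv.forward(x, train=False, rng=rng).sum()
        conv.W[i, j] = w0
        assert conv.dW[i, j] == pytest.approx((up - dn) / (2 * eps), rel=1e-2)

    def test_maxpool_routes_gradient_to_argmax(self):
        pool = nn.MaxPool2()
        x = np.array([[[[1.0, 2.0], [3.0, 4.0]]]], dtype=nn.DTYPE)
        out = pool.forward(x, train=False, rng=None)
        assert out[0, 0, 0, 0] == 4.0
        gx = pool.backward(np.ones_like(out))
        assert gx[0, 0, 1, 1] == 1.0 and gx.sum() == 1.0
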