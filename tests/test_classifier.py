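"""Splitting, normalization, network mechanics, SGDM, and metrics."""

import numpy as np
import pytest

from epncc import classify, network
from epncc.classify import NormStats, f_measure, report_from_confusion
from epncc.exceptions import ParameterError
from epncc.network import (ClassifierModel, TrainConfig, conv_branch_forward,
                           cross_entropy, softmax, sgdm_step)


# ---- split -------------------------------------------------------------

def test_split_reproduces_experiment_counts():
    labels = np.repeat([0, 1, 2], [320, 200, 260])  # 780 windows
    train, test = classify.split_dataset(780, 0.7, labels, seed=0)
    assert train.size == 546
    assert test.size == 234
    # stratified: 70% of each class in train
    assert [np.sum(labels[train] == c) for c in range(3)] == [224, 140, 182]


def test_split_small_case_and_disjointness():
    labels = np.repeat([0, 1], [5, 5])
    train, test = classify.split_dataset(10, 0.7, labels, seed=1)
    assert train.size == 7 and test.size == 3
    assert np.intersect1d(train, test).size == 0
    assert np.union1d(train, test).size == 10


def test_split_rejects_tiny_classes_and_bad_fraction():
    with pytest.raises(ParameterError):
        classify.split_dataset(3, 0.7, np.array([0, 0, 1]), seed=0)
    with pytest.raises(ParameterError):
        classify.split_dataset(10, 1.5, np.zeros(10, dtype=int), seed=0)


# ---- fusion / normalization -------------------------------------------

def test_train_stream_standardized_to_zero_mean_unit_variance():
    rng = np.random.default_rng(0)
    x = rng.normal(3.0, 2.0, size=(50, 8))
    stats = NormStats.fit(x)
    z = stats.apply(x)
    assert np.max(np.abs(z.mean(axis=0))) < 1e-10
    np.testing.assert_allclose(z.std(axis=0), 1.0, rtol=1e-8)


def test_constant_coordinate_maps_to_zero_via_floor():
    x = np.ones((20, 3)) * 5.0
    z = NormStats.fit(x).apply(x)
    assert np.all(z == 0.0)


def test_test_stream_uses_train_statistics():
    rng = np.random.default_rng(1)
    train = rng.normal(0.0, 1.0, size=(40, 4))
    test = rng.normal(2.0, 3.0, size=(10, 4))
    stats = (NormStats.fit(train), NormStats.fit(train))
    with_train_stats, _ = classify.fuse_features(test, test, stats)
    self_normed = NormStats.fit(test).apply(test)
    assert not np.allclose(with_train_stats, self_normed)


# ---- conv branch -------------------------------------------------------

def test_conv_branch_length_arithmetic():
    out = conv_branch_forward(np.random.default_rng(0).normal(size=450))
    assert out.shape == (107, 64)   # 450 ->223 ->111 ->109 ->107


def test_zero_input_zero_bias_gives_zero_output():
    out = conv_branch_forward(np.zeros(450), seed=3)
    assert np.all(out == 0.0)


def test_identity_kernel_convolution_reproduces_interior():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(1, 30, 1))
    conv = network._Conv1D(1, 1, kernel=3, stride=1, rng=rng)
    conv.w = np.array([[0.0], [1.0], [0.0]])
    conv.b = np.zeros(1)
    y = conv.forward(x)
    np.testing.assert_allclose(y[0, :, 0], x[0, 1:-1, 0])


def test_conv_gradients_match_finite_differences():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(2, 12, 1))
    conv = network._Conv1D(1, 2, kernel=3, stride=2, rng=rng)
    y = conv.forward(x)
    loss = 0.5 * np.sum(y ** 2)
    dx = conv.backward(y)
    eps = 1e-6
    for idx in [(0, 0, 0), (1, 5, 0), (0, 11, 0)]:
        xp = x.copy()
        xp[idx] += eps
        lp = 0.5 * np.sum(conv.forward(xp) ** 2)
        assert dx[idx] == pytest.approx((lp - loss) / eps, rel=1e-3, abs=1e-6)


def test_input_shorter_than_kernel_errors():
    with pytest.raises(ParameterError):
        network.conv_output_length(3, 5, 2)


# ---- softmax / cross-entropy ------------------------------------------

def test_softmax_is_a_probability_vector():
    rng = np.random.default_rng(4)
    p = softmax(rng.normal(size=(10, 3)) * 50)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
    assert np.all(p > 0)


def test_cross_entropy_analytic_values():
    assert cross_entropy([1.0, 0.0, 0.0], [1, 0, 0]) == pytest.approx(0.0)
    third = np.full(3, 1 / 3)
    for label in np.eye(3):
        assert cross_entropy(third, label) == pytest.approx(np.log(3),
                                                            rel=1e-9)


def test_cross_entropy_matches_oracle_and_rejects_bad_input():
    rng = np.random.default_rng(5)
    for _ in range(10):
        pred = rng.dirichlet(np.ones(3))
        label = np.eye(3)[rng.integers(3)]
        expected = -np.sum(label * np.log(np.clip(pred, 1e-12, 1.0)))
        assert cross_entropy(pred, label) == pytest.approx(expected)
    with pytest.raises(ParameterError):
        cross_entropy([0.9, 0.9, 0.9], [1, 0, 0])


# ---- SGDM --------------------------------------------------------------

def test_sgdm_single_step_on_quadratic():
    theta, v = sgdm_step(np.array(1.0), np.array(1.0), np.array(0.0),
                         lr=0.1, momentum=0.0)
    assert theta == pytest.approx(0.9)


def test_zero_momentum_equals_plain_gradient_descent():
    theta_m, v = np.array(2.0), np.array(0.0)
    theta_gd = np.array(2.0)
    for _ in range(5):
        theta_m, v = sgdm_step(theta_m, theta_m, v, lr=0.1, momentum=0.0)
        theta_gd = theta_gd - 0.1 * theta_gd
        assert theta_m == pytest.approx(theta_gd)


def test_lr_schedule_drops_by_factor():
    cfg = TrainConfig(lr_drop_period_epochs=10)
    assert cfg.lr_at_epoch(1) == 0.01
    assert cfg.lr_at_epoch(10) == 0.01
    assert cfg.lr_at_epoch(11) == pytest.approx(0.007)
    assert cfg.lr_at_epoch(21) == pytest.approx(0.0049)


def test_training_reduces_loss_and_is_deterministic():
    rng = np.random.default_rng(6)
    n = 60
    y = np.eye(3)[np.repeat([0, 1, 2], 20)]
    base = np.repeat([0.0, 2.0, -2.0], 20)[:, None]
    stream = base + rng.normal(0, 0.3, size=(n, 40))
    cfg = TrainConfig(max_epochs=10, seed=1)

    def fit():
        model = ClassifierModel([40], seed=1)
        network.train(model, [stream], y, cfg)
        return model

    m1, m2 = fit(), fit()
    assert m1.history["epoch_loss"][-1] < m1.history["epoch_loss"][0]
    assert m1.history["epoch_loss"] == m2.history["epoch_loss"]
    np.testing.assert_array_equal(m1.fc_w, m2.fc_w)


# ---- metrics -----------------------------------------------------------

def test_f_measure_reported_values():
    assert f_measure(99.0, 100.0) == 99.50
    assert f_measure(97.2, 98.6) == 97.89
    for x in (12.5, 50.0, 97.0):
        assert f_measure(x, x) == pytest.approx(x)
    assert f_measure(0.0, 0.0) == 0.0
    with pytest.raises(ParameterError):
        f_measure(120.0, 50.0)


def test_perfect_confusion_gives_all_100():
    report = report_from_confusion(np.eye(3, dtype=int) * 10)
    assert report.accuracy == 100.0
    assert report.recall == [100.0] * 3
    assert report.precision == [100.0] * 3
    assert report.f_score == [100.0] * 3


def test_confusion_arithmetic_example():
    c = np.array([[8, 1, 1], [0, 9, 1], [0, 0, 10]])
    report = report_from_confusion(c)
    assert report.recall[0] == 80.0
    assert report.precision[0] == 100.0
    assert report.accuracy == 90.0
    assert np.sum(report.confusion) == 30


def test_empty_class_reported_as_none():
    c = np.array([[5, 0, 0], [1, 4, 0], [0, 0, 0]])
    report = report_from_confusion(c)
    assert report.recall[2] is None
    assert report.f_score[2] is None


def test_evaluation_is_order_invariant():
    rng = np.random.default_rng(7)
    model = ClassifierModel([40], seed=2)
    x = rng.normal(size=(30, 40))
    y = np.eye(3)[rng.integers(0, 3, 30)]
    r1 = classify.evaluate(model, [x], y)
    perm = rng.permutation(30)
    r2 = classify.evaluate(model, [x[perm]], y[perm])
    np.testing.assert_array_equal(r1.confusion, r2.confusion)
    assert r1.accuracy == r2.accuracy
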