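"""Training loop, metrics and augmentation behaviour."""

import numpy as np
import pytest

from lorentznet.autodiff import Parameter, Tensor, as_tensor
from lorentznet.lorentz import LorentzManifold, expmap0, geodesic_distance, lorentz_inner
from lorentznet.models import ModelConfig, build_model
from lorentznet.training import (MetricsReport, RiemannianSGD, TrainConfig, augment,
                                 cross_entropy_loss, evaluate, stratified_split,
                                 topk_accuracy, train)


def separable_toy(n_per_class=12, size=8, seed=0):
    """Two classes: bright left half vs bright right half, plus small noise."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0.5, 0.02, size=(2 * n_per_class, 1, size, size))
    X[:n_per_class, :, :, : size // 2] += 0.4
    X[n_per_class:, :, :, size // 2:] += 0.4
    y = np.repeat([0, 1], n_per_class)
    return np.clip(X, 0, 1), y


class TestTopkAccuracy:
    def test_one_hot_logits_give_100(self):
        y = np.array([0, 1, 2])
        logits = np.eye(3)[y]
        assert topk_accuracy(logits, y, 1) == 100.0

    def test_hand_built_two_of_three_in_top2(self):
        logits = np.array([
            [5.0, 4.0, 0.0],   # label 1 in top-2
            [5.0, 0.0, 4.0],   # label 2 in top-2
            [5.0, 4.0, 3.0],   # label 2 NOT in top-2
        ])
        y = np.array([1, 2, 2])
        assert abs(topk_accuracy(logits, y, 2) - 100 * 2 / 3) < 1e-9

    def test_k_equal_n_classes_always_100(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(20, 5))
        y = rng.integers(0, 5, 20)
        assert topk_accuracy(logits, y, 5) == 100.0

    def test_ties_break_to_lowest_class_index(self):
        logits = np.zeros((1, 4))
        assert topk_accuracy(logits, np.array([0]), 1) == 100.0
        assert topk_accuracy(logits, np.array([3]), 1) == 0.0

    def test_label_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            topk_accuracy(np.zeros((1, 3)), np.array([3]), 1)
        with pytest.raises(ValueError, match="exceeds"):
            topk_accuracy(np.zeros((1, 3)), np.array([0]), 4)


class TestEvaluate:
    def test_uniform_logits_cross_entropy_is_log_C(self):
        y = np.random.default_rng(1).integers(0, 7, 50)
        ce = float(cross_entropy_loss(as_tensor(np.zeros((50, 7))), y).data)
        assert abs(ce - np.log(7)) < 1e-12

    def test_uniform_logits_top5_of_10_balanced_classes(self):
        # ties resolve to classes 0..4, so exactly the samples labelled 0-4 hit
        y = np.tile(np.arange(10), 30)
        logits = np.zeros((300, 10))
        assert abs(topk_accuracy(logits, y, 5) - 50.0) < 1e-9

    def test_perfect_model_scores_100(self):
        class Oracle:
            norm_mean, norm_sd = 0.0, 1.0
            def forward(self, X):
                n = len(X)
                labels = X[:, 0, 0, 0].astype(int)
                out = np.zeros((n, 4))
                out[np.arange(n), labels] = 10.0
                return as_tensor(out)
        X = np.zeros((8, 1, 2, 2))
        X[:, 0, 0, 0] = np.arange(8) % 4
        rep = evaluate(Oracle(), (X, np.arange(8) % 4))
        assert rep.top1 == rep.top5 == 100.0
        assert rep.n_eval == 8

    def test_empty_split_rejected(self):
        e = build_model(ModelConfig(n_classes=2, image_size=8), 0)
        with pytest.raises(ValueError, match="empty"):
            evaluate(e, (np.empty((0, 1, 8, 8)), np.empty(0, dtype=int)))


class TestAugment:
    CFG = TrainConfig(rotation_degrees=0.0, flip_prob=0.0)

    def test_no_rotation_no_flip_is_pure_normalization(self):
        rng = np.random.default_rng(2)
        X = rng.random((4, 1, 8, 8))
        out = augment(X, self.CFG, rng, mean=0.25, sd=0.5)
        np.testing.assert_allclose(out, (X - 0.25) / 0.5, atol=1e-12)

    def test_flip_is_an_involution(self):
        cfg = TrainConfig(rotation_degrees=0.0, flip_prob=1.0)
        X = np.random.default_rng(3).random((2, 1, 8, 8))
        once = augment(X, cfg, np.random.default_rng(0))
        twice = augment(once, cfg, np.random.default_rng(0))
        np.testing.assert_allclose(twice, X, atol=1e-12)

    def test_fixed_seed_reproduces_batch(self):
        cfg = TrainConfig(rotation_degrees=15.0, flip_prob=0.5)
        X = np.random.default_rng(4).random((6, 1, 8, 8))
        a = augment(X, cfg, np.random.default_rng(99))
        b = augment(X, cfg, np.random.default_rng(99))
        np.testing.assert_array_equal(a, b)


class TestStratifiedSplit:
    def test_fractions_respected_per_class(self):
        y = np.repeat(np.arange(3), 100)
        split = stratified_split(y, (0.8, 0.1, 0.1), seed=0)
        for c in range(3):
            counts = {s: int(np.sum((split == s) & (y == c)))
                      for s in ("train", "val", "test")}
            assert counts == {"train": 80, "val": 10, "test": 10}


class TestTrain:
    def test_separable_toy_reaches_100(self):
        X, y = separable_toy()
        m = build_model(ModelConfig(geometry="euclidean", n_classes=2, image_size=8), 0)
        cfg = TrainConfig(epochs=5, learning_rate=0.05, batch_size=8, seed=0,
                          rotation_degrees=0.0, flip_prob=0.0)
        m, log = train(m, (X, y), cfg)
        assert log[-1]["train_top1"] == 100.0

    def test_zero_learning_rate_keeps_weights(self):
        X, y = separable_toy()
        m = build_model(ModelConfig(geometry="lorentz", n_classes=2, image_size=8), 1)
        before = [p.data.copy() for p in m.parameters()]
        cfg = TrainConfig(epochs=2, learning_rate=0.0, batch_size=8, seed=0)
        train(m, (X, y), cfg)
        for b, p in zip(before, m.parameters()):
            np.testing.assert_array_equal(b, p.data)

    def test_same_seed_reproduces_loss_curve(self):
        X, y = separable_toy()
        cfg = TrainConfig(epochs=3, learning_rate=0.02, batch_size=8, seed=7)
        logs = []
        for _ in range(2):
            m = build_model(ModelConfig(geometry="lorentz", n_classes=2, image_size=8), 2)
            _, log = train(m, (X, y), cfg)
            logs.append([e["train_loss"] for e in log])
        assert logs[0] == logs[1]

    def test_loss_decreases_from_first_to_last_epoch(self):
        X, y = separable_toy()
        for geometry in ("euclidean", "lorentz"):
            m = build_model(ModelConfig(geometry=geometry, n_classes=2, image_size=8), 3)
            _, log = train(m, (X, y), TrainConfig(epochs=5, learning_rate=0.05,
                                                  batch_size=8, seed=1))
            assert log[-1]["train_loss"] < log[0]["train_loss"]

    def test_too_few_images_rejected(self):
        X = np.zeros((2, 1, 8, 8))
        m = build_model(ModelConfig(n_classes=2, image_size=8), 0)
        with pytest.raises(ValueError, match="2 classes"):
            train(m, (X, np.array([0, 1])), TrainConfig(epochs=1))


class TestRiemannianSGD:
    def test_manifold_parameter_stays_on_hyperboloid_and_converges(self):
        m = LorentzManifold(k=1.0)
        target = expmap0(np.array([0.6, -0.2, 0.4]), m)
        p = Parameter(m.origin(3), name="point", manifold=m)
        opt = RiemannianSGD([p], lr=0.1)
        for _ in range(300):
            # loss = -<p, target>_L, minimized exactly at p = target
            t = Tensor(target)
            flip = np.ones(4); flip[0] = -1.0
            loss = (p * t * Tensor(-flip)).sum()
            opt.zero_grad()
            loss.backward()
            opt.step()
            assert abs(lorentz_inner(p.data, p.data) + 1.0) < 1e-9
        assert geodesic_distance(p.data, target, m) < 1e-2

    def test_euclidean_momentum_matches_closed_form(self):
        # single scalar, f(w) = w^2/2, grad = w: two steps of momentum SGD
        p = Parameter(np.array(1.0), name="w")
        opt = RiemannianSGD([p], lr=0.1, momentum=0.5)
        for _ in range(2):
            loss = (p * p) * 0.5
            opt.zero_grad()
            loss.backward()
            opt.step()
        # step1: v=1, w=0.9; step2: v=0.5*1+0.9=1.4, w=0.9-0.14=0.76
        np.testing.assert_allclose(p.data, 0.76, atol=1e-12)
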