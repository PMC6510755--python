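"""Network engine and training contract: softmax, gradients, shapes,
patient splitting, early stopping, learnability, prediction."""

import numpy as np
import pytest

import petguard.model as pm
from petguard import nn
from petguard.errors import ConfigurationError, EmptyInputError, PredictionError
from petguard.model import (
    EarlyStopping,
    NetworkSpec,
    TrainingConfig,
    build_model,
    load_model,
    predict_batch,
    predict_image,
    save_model,
    softmax,
    split_patients,
    train,
)
from petguard.projection import MIPImage

# frozen 30-digit evaluation of exp(x_i)/sum_j exp(x_j) at (1, 2)
SOFTMAX_1_2 = (0.268941421369995120748840758178, 0.731058578630004879251159241822)


class TestSoftmax:
    def test_symmetry(self):
        assert np.allclose(softmax([0.0, 0.0]), [0.5, 0.5])

    def test_matches_high_precision_oracle(self):
        p = softmax([1.0, 2.0])
        assert abs(p[0] - SOFTMAX_1_2[0]) < 1e-12
        assert abs(p[1] - SOFTMAX_1_2[1]) < 1e-12

    def test_shift_invariance(self):
        assert np.allclose(softmax([1000.0, 1001.0]), softmax([0.0, 1.0]), atol=1e-12)

    def test_sums_to_one_and_positive(self, rng):
        x = rng.normal(size=(5, 7))
        p = softmax(x)
        assert np.allclose(p.sum(axis=-1), 1.0)
        assert np.all(p > 0)

    def test_errors(self):
        with pytest.raises(EmptyInputError):
            softmax([])
        with pytest.raises(ConfigurationError):
            softmax([np.inf, 0.0])


def _numeric_grad(f, x, eps=1e-2):
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        hi = f()
        x[i] = orig - eps
        lo = f()
        x[i] = orig
        g[i] = (hi - lo) / (2 * eps)
        it.iternext()
    return g


class TestGradients:
    def test_conv_backward_matches_finite_differences(self, rng):
        layer = nn.Conv3x3(2, 3, rng)
        x = rng.standard_normal((1, 4, 4, 2)).astype(np.float32)
        R = rng.standard_normal((1, 4, 4, 3)).astype(np.float32)

        def loss():
            return float((layer.forward(x) * R).sum())

        loss()
        dx = layer.backward(R)
        assert np.allclose(dx, _numeric_grad(loss, x), atol=2e-3)
        loss()
        layer.backward(R)
        assert np.allclose(layer.dW, _numeric_grad(loss, layer.W), atol=2e-3)

    def test_lrn_backward_matches_finite_differences(self, rng):
        layer = nn.LRN(radius=1, alpha=0.3, beta=0.75, bias=1.0)
        x = rng.standard_normal((1, 2, 2, 5)).astype(np.float32)
        R = rng.standard_normal((1, 2, 2, 5)).astype(np.float32)

        def loss():
            return float((layer.forward(x) * R).sum())

        loss()
        dx = layer.backward(R)
        assert np.allclose(dx, _numeric_grad(loss, x), atol=2e-3)

    def test_maxpool_routes_gradient_to_maxima(self):
        x = np.array([[[[1.0], [3.0]], [[2.0], [0.5]]]], dtype=np.float32)  # (1,2,2,1)
        pool = nn.MaxPool2()
        y = pool.forward(x)
        assert y[0, 0, 0, 0] == 3.0
        dx = pool.backward(np.ones_like(y))
        assert dx[0, 0, 1, 0] == 1.0
        assert dx.sum() == 1.0


class TestBuildModel:
    def test_softmax_head_normalized_and_pools_reach_8x8(self, rng):
        model = build_model(NetworkSpec(), task="sex", seed=0)
        x = rng.random((2, 64, 64, 1)).astype(np.float32)
        acts = model.net.activations(x)
        # 3 pooling stages: 64 -> 32 -> 16 -> 8 (each stage quarters elements)
        pool_shapes = [a.shape for a, l in zip(acts, model.net.layers) if isinstance(l, nn.MaxPool2)]
        assert pool_shapes[-1][1:3] == (8, 8)
        probs = softmax(acts[-1])
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_linear_head_unbounded_scalar(self, rng):
        model = build_model(NetworkSpec(head="linear"), task="age", seed=0)
        out = model.forward(rng.random((3, 64, 64, 1)).astype(np.float32))
        assert out.shape == (3, 1)

    def test_layer_count_invariants_enforced(self):
        with pytest.raises(ConfigurationError):
            NetworkSpec(filters=(4, 8, 8))
        with pytest.raises(ConfigurationError):
            NetworkSpec(pool_after=(0, 1))
        with pytest.raises(ConfigurationError):
            build_model(NetworkSpec(), task="age")  # softmax head on a regression task


class TestSplitPatients:
    def test_70_30_split_disjoint(self):
        ids = [f"P{i}" for i in range(100)]
        tr, te = split_patients(ids, 0.7, seed=0)
        assert len(tr) == 70 and len(te) == 30
        assert not set(tr) & set(te)

    def test_floor_arithmetic_at_cohort_scale(self):
        ids = [f"P{i}" for i in range(6462)]
        tr, te = split_patients(ids, 0.7, seed=0)
        assert len(tr) == 4523 and len(te) == 1939

    def test_deterministic(self):
        ids = [f"P{i}" for i in range(50)]
        assert split_patients(ids, 0.7, seed=4) == split_patients(ids, 0.7, seed=4)

    def test_bad_fraction(self):
        with pytest.raises(ConfigurationError):
            split_patients(["a", "b"], 1.5, seed=0)


def _labelled_images(n, rng, separable=True):
    """Bright-top vs bright-bottom 64x64 images; trivially separable by the
    mean-intensity-per-half oracle (a logistic fit on that feature is 100%
    accurate), so any sane training run must reach it too."""
    images, labels = [], []
    for i in range(n):
        pix = rng.normal(0.2, 0.05, (64, 64))
        cls = i % 2
        half = slice(0, 32) if cls == 0 else slice(32, 64)
        pix[half, :] += 0.5
        images.append(
            MIPImage(pixels=np.clip(pix, 0, 1).astype(np.float32), angle=0.0, patient_id=f"P{i}")
        )
        labels.append("male" if cls == 0 else "female")
    return images, labels


class TestTraining:
    def test_early_stopping_counts_patience_exactly(self):
        stopper = EarlyStopping(patience=2)
        assert stopper.update(1.0, 1) is False  # best
        assert stopper.update(1.1, 2) is False
        assert stopper.update(1.2, 3) is True  # stops at epoch 3
        assert stopper.best_epoch == 1

    def test_forced_degradation_stops_at_patience_and_restores_best(self, rng, monkeypatch):
        images, labels = _labelled_images(24, rng)
        scripted = [1.0, 0.5, 0.9, 1.2, 1.5, 2.0]
        snapshots = []
        calls = {"k": 0}
        model = build_model(NetworkSpec(dropout_rate=0.0), task="sex", seed=0)

        def fake_eval(m, X, Y):
            snapshots.append(m.net.get_weights())
            k = calls["k"]
            calls["k"] += 1
            return scripted[k], 1.0

        monkeypatch.setattr(pm, "_evaluate_fold", fake_eval)
        cfg = TrainingConfig(seed=0, max_epochs=6, patience=2, restore_best=True)
        train(model, images, labels, cfg)
        # best at epoch 2, then two non-improving epochs -> stop at epoch 4
        assert len(model.history) == 4
        for got, want in zip(model.net.get_weights(), snapshots[1]):
            assert np.array_equal(got, want)

    def test_learnable_synthetic_task_reaches_99_percent(self, rng):
        images, labels = _labelled_images(400, rng)
        model = build_model(NetworkSpec(), task="sex", seed=1)
        cfg = TrainingConfig(seed=1, max_epochs=10, patience=3)
        train(model, images, labels, cfg)
        assert len(model.history) <= 10
        assert model.history["val_acc"].max() >= 0.99
        assert model.history["train_loss"].iloc[-1] <= model.history["train_loss"].iloc[0]

    def test_seeded_training_is_reproducible(self, rng):
        images, labels = _labelled_images(80, rng)
        cfg = TrainingConfig(seed=3, max_epochs=2, patience=2)
        w = []
        for _ in range(2):
            model = build_model(NetworkSpec(), task="sex", seed=3)
            train(model, images, labels, cfg)
            w.append(model.net.get_weights())
        for a, b in zip(*w):
            assert np.array_equal(a, b)

    def test_empty_training_set_rejected(self):
        model = build_model(NetworkSpec(), task="sex", seed=0)
        with pytest.raises(EmptyInputError):
            train(model, [], [], TrainingConfig())


class TestPredict:
    def test_untrained_model_rejected(self, rng):
        model = build_model(NetworkSpec(), task="sex", seed=0)
        im = MIPImage(pixels=np.zeros((64, 64), np.float32), angle=0.0)
        with pytest.raises(PredictionError):
            predict_image(model, im)

    def test_inference_deterministic_and_normalized(self, tiny_trained):
        model = tiny_trained["model"]
        pid = tiny_trained["test_ids"][0]
        im = tiny_trained["mips"][pid][0]
        a, b = predict_image(model, im), predict_image(model, im)
        assert np.array_equal(a, b)
        assert a.sum() == pytest.approx(1.0, abs=1e-9)

    def test_save_load_roundtrip(self, tiny_trained, tmp_path):
        model = tiny_trained["model"]
        pid = tiny_trained["test_ids"][0]
        images = tiny_trained["mips"][pid]
        save_model(model, tmp_path / "m")
        clone = load_model(tmp_path / "m")
        assert np.allclose(predict_batch(model, images), predict_batch(clone, images))
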