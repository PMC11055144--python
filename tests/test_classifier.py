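"""CNN engine gradients, parameter accounting, training and prediction."""

import numpy as np
import pytest

import actimage as ai
from actimage.classifier import (
    ModelSpec,
    TrainConfig,
    build_model,
    conv_parameter_count,
    count_parameters,
    dense_parameter_count,
    load_model,
    predict,
    save_model,
    train,
)
from actimage.nn import (
    Conv2D,
    Dense,
    Flatten,
    MaxPool2,
    ReLU,
    Sequential,
    softmax_cross_entropy,
)

SMALL_SPEC = ModelSpec(input_shape=(24, 24, 3), conv_channels=(4, 8),
                       kernel_sizes=(3, 3), hidden_units=16, n_classes=2)


def _toy_images(n_per_class, shape, seed):
    """Trivially separable bright-vs-dark image classes."""
    rng = np.random.default_rng(seed)
    bright = rng.uniform(0.7, 1.0, (n_per_class, *shape))
    dark = rng.uniform(0.0, 0.3, (n_per_class, *shape))
    x = np.concatenate([bright, dark]).astype(np.float32)
    y = np.array([0] * n_per_class + [1] * n_per_class)
    return x, y


class TestGradients:
    def test_backprop_matches_numerical_gradient(self):
        """End-to-end analytic gradients agree with central differences on a
        tiny conv-pool-dense network."""
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, (2, 8, 7, 2)).astype(np.float32)
        y = np.array([0, 1])
        model = Sequential([
            Conv2D(3, 3, 2, 3, rng), ReLU(), MaxPool2(),
            Flatten(), Dense(3 * 2 * 3, 5, rng), ReLU(), Dense(5, 2, rng),
        ])

        logits = model.forward(x, train=True)
        _, dlogits, _ = softmax_cross_entropy(logits, y)
        model.backward(dlogits)
        analytic = [g.copy() for g in model.grads]

        eps = 1e-2
        for p, g in zip(model.params, analytic):
            flat = p.reshape(-1)
            idx = np.linspace(0, flat.size - 1, min(flat.size, 12)).astype(int)
            for i in idx:
                old = flat[i]
                flat[i] = old + eps
                lp = softmax_cross_entropy(model.forward(x), y)[0]
                flat[i] = old - eps
                lm = softmax_cross_entropy(model.forward(x), y)[0]
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(g.reshape(-1)[i], abs=5e-3)


class TestParameterCounting:
    @pytest.mark.parametrize(
        "kh,kw,cin,cout,expected",
        [(3, 3, 16, 32, 4640), (3, 3, 32, 64, 18496), (1, 1, 1, 1, 2)],
    )
    def test_conv_formula(self, kh, kw, cin, cout, expected):
        assert conv_parameter_count(kh, kw, cin, cout) == expected

    def test_dense_formula(self):
        assert dense_parameter_count(6400, 128) == 819328

    def test_count_matches_instantiated_model(self):
        counts = count_parameters(SMALL_SPEC)
        model = build_model(SMALL_SPEC, seed=0)
        assert counts["total"] == model.n_parameters()
        assert counts["total"] == sum(p.size for p in model.params)

    def test_geometry_too_small_rejected(self):
        bad = ModelSpec(input_shape=(6, 6, 3), conv_channels=(4, 8, 8, 8),
                        kernel_sizes=(5, 3, 3, 3), n_classes=2)
        with pytest.raises(ai.ConfigurationError):
            build_model(bad, seed=0)


class TestTraining:
    def test_separable_classes_reach_perfect_validation(self):
        x, y = _toy_images(20, SMALL_SPEC.input_shape, seed=1)
        config = TrainConfig(epochs=5, batch_size=4, learning_rate=3e-3, seed=0,
                             split="holdout_70_30")
        result = train(x, y, SMALL_SPEC, config)
        assert result.folds[0].history["val_accuracy"][-1] == 1.0

    def test_loss_decreases_over_first_epochs(self):
        x, y = _toy_images(20, SMALL_SPEC.input_shape, seed=2)
        config = TrainConfig(epochs=3, batch_size=4, learning_rate=3e-3, seed=0,
                             split="holdout_70_30")
        result = train(x, y, SMALL_SPEC, config)
        loss = result.folds[0].history["loss"]
        assert all(np.isfinite(loss))
        assert loss[2] < loss[0]

    def test_same_seed_identical_weights_and_history(self):
        x, y = _toy_images(10, SMALL_SPEC.input_shape, seed=3)
        config = TrainConfig(epochs=2, batch_size=8, seed=5, split="holdout_70_30")
        r1 = train(x, y, SMALL_SPEC, config)
        r2 = train(x, y, SMALL_SPEC, config)
        assert r1.folds[0].history == r2.folds[0].history
        for a, b in zip(r1.folds[0].model.params, r2.folds[0].model.params):
            assert np.array_equal(a, b)

    def test_class_smaller_than_fold_count_rejected(self):
        x, y = _toy_images(3, SMALL_SPEC.input_shape, seed=4)
        with pytest.raises(ai.ValidationError):
            train(x, y, SMALL_SPEC, TrainConfig(epochs=1, n_folds=5))

    def test_geometry_mismatch_rejected(self):
        x, y = _toy_images(5, (10, 10, 3), seed=5)
        with pytest.raises(ai.ValidationError):
            train(x, y, SMALL_SPEC, TrainConfig(epochs=1, split="holdout_70_30"))


class TestPredict:
    @pytest.fixture(scope="class")
    def fitted(self):
        x, y = _toy_images(10, SMALL_SPEC.input_shape, seed=6)
        config = TrainConfig(epochs=6, batch_size=4, learning_rate=3e-3, seed=0,
                             split="holdout_70_30")
        return train(x, y, SMALL_SPEC, config).folds[0].model, x, y

    def test_probabilities_sum_to_one(self, fitted):
        model, x, _ = fitted
        probs, _ = predict(model, x)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_training_examples_get_their_labels(self, fitted):
        model, x, y = fitted
        _, labels = predict(model, x)
        assert (labels == y).mean() == 1.0

    def test_permutation_equivariance(self, fitted):
        model, x, _ = fitted
        probs, _ = predict(model, x)
        perm = np.random.default_rng(0).permutation(len(x))
        probs_perm, _ = predict(model, x[perm])
        np.testing.assert_allclose(probs_perm, probs[perm], atol=1e-6)


class TestSerialization:
    def test_save_load_roundtrip(self, tmp_path):
        x, y = _toy_images(6, SMALL_SPEC.input_shape, seed=7)
        config = TrainConfig(epochs=1, batch_size=4, seed=0, split="holdout_70_30")
        model = train(x, y, SMALL_SPEC, config).folds[0].model
        save_model(model, SMALL_SPEC, tmp_path / "model")
        loaded, spec = load_model(tmp_path / "model")
        assert spec == SMALL_SPEC
        p1, _ = predict(model, x)
        p2, _ = predict(loaded, x)
        np.testing.assert_allclose(p1, p2, atol=1e-7)
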