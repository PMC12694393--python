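"""Architecture shape/parameter oracles, training contract, serialization."""

import numpy as np
import pytest

from afedge import cnn
from afedge.cnn import (
    CNN1D,
    ModelConfig,
    TrainConfig,
    build_model,
    count_parameters,
    load_model,
    save_model,
    split_train_val,
    train,
)


def shape_oracle(n: int, kernel: int = 3, pool: int = 2) -> list[int]:
    """Independent valid-padding shape arithmetic for the two conv blocks."""
    lengths = [n]
    for _ in range(2):
        lengths.append(lengths[-1] - kernel + 1)  # valid conv
        lengths.append(lengths[-1] // pool)  # truncating average pool
    return lengths


def parameter_oracle(n: int) -> int:
    """Per-layer parameter arithmetic, independent of the implementation."""
    lengths = shape_oracle(n)
    flat = lengths[-1] * 32
    conv1 = 3 * 1 * 16 + 16
    bn1 = 4 * 16  # gamma, beta, moving mean, moving variance
    conv2 = 3 * 16 * 32 + 32
    bn2 = 4 * 32
    dense = flat * 64 + 64
    out = 64 * 2 + 2
    return conv1 + bn1 + conv2 + bn2 + dense + out


class TestArchitecture:
    @pytest.mark.parametrize("n,flat", [(25, 128), (50, 352), (100, 736)])
    def test_flattened_feature_length(self, n, flat):
        cfg = ModelConfig(n=n)
        assert cfg.flat_features == flat
        assert cfg.flat_features == shape_oracle(n)[-1] * 32

    @pytest.mark.parametrize("n", [25, 50, 100])
    def test_parameter_count_matches_arithmetic_oracle(self, n):
        model = build_model(ModelConfig(n=n), seed=0)
        assert count_parameters(model) == parameter_oracle(n)

    def test_smallest_window_has_10210_parameters(self):
        assert count_parameters(build_model(ModelConfig(n=25))) == 10210

    def test_same_config_always_same_count(self):
        cfg = ModelConfig(n=50)
        assert count_parameters(build_model(cfg, seed=1)) == count_parameters(
            build_model(cfg, seed=99)
        )

    def test_layer_order(self):
        names = [type(l).__name__ for l in build_model(ModelConfig(n=25)).layers]
        assert names == [
            "Conv1D", "BatchNorm", "ReLU", "AvgPool1D", "Dropout",
            "Conv1D", "BatchNorm", "ReLU", "AvgPool1D",
            "Flatten", "Dense", "ReLU", "Dropout", "Dense",
        ]

    def test_too_short_input_errors(self):
        with pytest.raises(ValueError):
            build_model(ModelConfig(n=5))

    def test_same_padding_preserves_conv_length(self):
        cfg = ModelConfig(n=25, padding="same")
        assert cfg.layer_lengths() == (25, 25, 12, 12, 6)
        x = np.random.default_rng(0).uniform(0.5, 1.2, (4, 25))
        probs = build_model(cfg, seed=0).predict_proba(x)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


class TestPredictProba:
    def test_untrained_outputs_are_probabilities(self):
        model = build_model(ModelConfig(n=25), seed=2)
        x = np.random.default_rng(0).uniform(0.4, 1.4, (16, 25))
        probs = model.predict_proba(x)
        assert probs.shape == (16, 2)
        assert probs.min() >= 0 and probs.max() <= 1
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_pure_function_on_duplicated_rows(self):
        model = build_model(ModelConfig(n=25), seed=2)
        x = np.random.default_rng(1).uniform(0.4, 1.4, (1, 25))
        probs = model.predict_proba(np.vstack([x, x]))
        np.testing.assert_array_equal(probs[0], probs[1])

    def test_wrong_window_length_errors(self):
        model = build_model(ModelConfig(n=25))
        with pytest.raises(ValueError):
            model.predict_proba(np.zeros((3, 30)))


def test_backprop_matches_numeric_gradients():
    """Analytic gradients agree with central differences for every layer type."""
    cfg = ModelConfig(n=25, dropout1=0.0, dropout2=0.0)  # keep the loss deterministic
    model = build_model(cfg, seed=1)
    rng = np.random.default_rng(0)
    x = rng.normal(0.8, 0.1, (8, 25, 1))
    y = rng.integers(0, 2, 8)

    def loss():
        return cnn.cross_entropy(
            cnn._softmax(model.forward_logits(x, training=True)), y
        )

    probs = cnn._softmax(model.forward_logits(x, training=True))
    model.backward_from_probs(probs, cnn._one_hot(y, 2))
    eps = 1e-6
    for layer_idx in (0, 1, 5, 10, 13):  # conv1, bn1, conv2, dense, output
        layer = model.layers[layer_idx]
        w, g = layer.params()[0], layer.grads()[0]
        idx = tuple(0 for _ in w.shape)
        w0 = w[idx]
        w[idx] = w0 + eps
        lp = loss()
        w[idx] = w0 - eps
        lm = loss()
        w[idx] = w0
        numeric = (lp - lm) / (2 * eps)
        assert abs(numeric - g[idx]) <= 1e-4 * max(1.0, abs(numeric))


class TestSplitTrainVal:
    def test_honors_80_20(self):
        x = np.zeros((1000, 4))
        y = np.repeat([0, 1], 500)
        x_tr, y_tr, x_va, y_va = split_train_val(x, y, 0.2, seed=0)
        assert len(y_tr) == 800 and len(y_va) == 200

    def test_deterministic(self):
        x = np.arange(100)[:, None].astype(float)
        y = np.tile([0, 1], 50)
        a = split_train_val(x, y, 0.2, seed=5)
        b = split_train_val(x, y, 0.2, seed=5)
        for u, v in zip(a, b):
            np.testing.assert_array_equal(u, v)

    def test_stratified_within_one(self):
        y = np.repeat([0, 1], 500)
        _, y_tr, _, y_va = split_train_val(np.zeros((1000, 2)), y, 0.2, seed=1)
        assert abs((y_va == 0).sum() - (y_va == 1).sum()) <= 1
        assert abs((y_tr == 0).sum() - (y_tr == 1).sum()) <= 1

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            split_train_val(np.zeros((10, 2)), np.zeros(10, dtype=int))


def _separable_set(n_per_class, n, seed):
    """Low-variability (SR-like) vs high-variability (AF-like) windows."""
    rng = np.random.default_rng(seed)
    sr = rng.normal(0.85, 0.02, (n_per_class, n))
    af = np.clip(rng.gamma(20.0, 0.7 / 20.0, (n_per_class, n)), 0.3, 1.8)
    x = np.vstack([sr, af])
    y = np.repeat([0, 1], n_per_class)
    return x, y


@pytest.fixture(scope="module")
def trained():
    x, y = _separable_set(150, 25, seed=0)
    x_tr, y_tr, x_va, y_va = split_train_val(x, y, 0.2, seed=0)
    model = build_model(ModelConfig(n=25), seed=0)
    tc = TrainConfig(seed=0, max_epochs=40)
    tm = train(model, (x_tr, y_tr), (x_va, y_va), tc)
    return tm, (x_va, y_va)


class TestTraining:
    def test_learns_variability_separated_classes(self, trained):
        tm, _ = trained
        x_hold, y_hold = _separable_set(100, 25, seed=99)
        acc = float(np.mean(tm.predict(x_hold) == y_hold))
        assert acc >= 0.95

    def test_early_stopping_bound_and_history(self, trained):
        tm, _ = trained
        assert tm.stopped_epoch <= tm.train_config.max_epochs
        assert len(tm.history["val_loss"]) == tm.stopped_epoch

    def test_restored_weights_reproduce_best_validation_loss(self, trained):
        tm, (x_va, y_va) = trained
        probs = tm.predict_proba(x_va)
        restored = cnn.cross_entropy(probs, y_va)
        assert restored == pytest.approx(min(tm.history["val_loss"]), abs=1e-9)

    def test_constant_window_scores_lower_af_probability(self, trained):
        tm, _ = trained
        constant = np.full((1, 25), 0.85)
        irregular = np.clip(
            np.random.default_rng(5).gamma(15.0, 0.7 / 15.0, (1, 25)), 0.3, 1.8
        )
        p = tm.predict_proba(np.vstack([constant, irregular]))[:, 1]
        assert p[0] < p[1]

    def test_empty_sets_error(self):
        model = build_model(ModelConfig(n=25))
        with pytest.raises(ValueError):
            train(model, (np.empty((0, 25)), np.empty(0, int)),
                  (np.empty((0, 25)), np.empty(0, int)), TrainConfig())


class TestSerialization:
    def test_round_trip_preserves_architecture_and_predictions(self, tmp_path):
        x, y = _separable_set(60, 25, seed=2)
        x_tr, y_tr, x_va, y_va = split_train_val(x, y, 0.2, seed=2)
        tm = train(
            build_model(ModelConfig(n=25), seed=2),
            (x_tr, y_tr), (x_va, y_va), TrainConfig(seed=2, max_epochs=3),
        )
        path = tmp_path / "model.bin"
        save_model(tm, path)
        back = load_model(path)
        assert count_parameters(back.model) == count_parameters(tm.model)
        assert [type(l).__name__ for l in back.model.layers] == [
            type(l).__name__ for l in tm.model.layers
        ]
        # float32 storage: predictions agree to single precision
        np.testing.assert_allclose(
            back.predict_proba(x_va), tm.predict_proba(x_va), atol=1e-5
        )

    def test_serialized_bytes_are_deterministic(self, tmp_path):
        model = build_model(ModelConfig(n=25), seed=3)
        tm = cnn.TrainedModel(model, model.config, TrainConfig())
        p1, p2 = tmp_path / "a.bin", tmp_path / "b.bin"
        save_model(tm, p1)
        save_model(tm, p2)
        assert p1.read_bytes() == p2.read_bytes()
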