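import numpy as np
import pytest

import codelcnn._nn as _nn
from codelcnn.ensemble import (EnsembleConfig, TrainConfig, build_ensemble,
                               forward_proba, load_model, save_model,
                               train_ensemble)
from codelcnn.evaluate import roc_auc
from conftest import make_features


def separable_set(n_per_class, len1, len2, seed, shift=-0.8, sd=0.1):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_per_class):
        out.append(make_features(
            f"p{i}", rng.normal(shift, sd, len1), rng.normal(shift, sd, len2),
            "codel"))
        out.append(make_features(
            f"n{i}", rng.normal(0, sd, len1), rng.normal(0, sd, len2),
            "no_codel"))
    return out


@pytest.fixture(scope="module")
def default_model():
    return build_ensemble()


class TestArchitectureGeometry:
    """Closed-form audit of the default network against its layer specs."""

    def test_head_input_is_2048(self, default_model):
        assert default_model.head_input_dim == 2048
        assert EnsembleConfig().concat_len == 2048

    def test_branch_feature_len_is_1024(self, default_model):
        assert default_model.branch_feature_len == 1024

    def test_pretrain_output_shapes(self, default_model):
        # valid convs + /2 pools: 1869 -> 150x64 and 649 -> 25x64
        assert default_model.pretrain_shapes == ((64, 150), (64, 25))

    def test_forward_feature_lengths(self, default_model, rng):
        f1, f2 = default_model.branch_features(
            rng.normal(size=(2, 1869)), rng.normal(size=(2, 649)))
        assert f1.shape == (2, 1024)
        assert f2.shape == (2, 1024)

    def test_parameter_count_reported(self, default_model):
        n = default_model.parameter_count()
        assert np.isfinite(n) and n > 1_000_000

    def test_impossible_geometry_names_layer(self):
        config = EnsembleConfig(
            branch1_pretrain=(("conv", 2000, 8),))
        with pytest.raises(ValueError, match="branch_a.pre0"):
            build_ensemble(config)


class TestForwardProba:
    def test_probabilities_sum_to_one(self, tiny_model_config, rng):
        model = build_ensemble(tiny_model_config)
        s = make_features("s", rng.normal(size=120), rng.normal(size=60))
        p1, p2 = forward_proba(model, s)
        assert p1 >= 0 and p2 >= 0
        assert p1 + p2 == pytest.approx(1.0, abs=1e-6)

    def test_batch_invariance(self, tiny_model_config, rng):
        model = build_ensemble(tiny_model_config)
        x1 = rng.normal(size=(7, 120))
        x2 = rng.normal(size=(7, 60))
        solo = model.predict_proba(x1[3:4], x2[3:4])[0]
        batched = model.predict_proba(x1, x2)[3]
        np.testing.assert_allclose(solo, batched, atol=1e-6)

    def test_zero_head_gives_half(self, tiny_model_config, rng):
        model = build_ensemble(tiny_model_config)
        model.head.W[...] = 0
        model.head.b[...] = 0
        s = make_features("s", rng.normal(size=120), rng.normal(size=60))
        p1, p2 = forward_proba(model, s)
        assert p1 == pytest.approx(0.5)

    def test_shape_mismatch(self, tiny_model_config, rng):
        model = build_ensemble(tiny_model_config)
        s = make_features("s", rng.normal(size=119), rng.normal(size=60))
        with pytest.raises(ValueError, match="length"):
            forward_proba(model, s)


class TestResidualBlock:
    def test_zero_transform_is_shortcut(self, rng):
        block = _nn.ResidualBlock(8, 4, 8, np.random.default_rng(0))
        for conv in (block.conv1, block.conv2, block.conv3):
            conv.W[...] = 0
            conv.b[...] = 0
        x = rng.normal(size=(3, 8, 20)).astype(np.float32)
        out = block.forward(x)
        np.testing.assert_array_equal(out, np.maximum(x, 0))

    def test_projection_shortcut_on_channel_change(self):
        block = _nn.ResidualBlock(8, 4, 16, np.random.default_rng(0))
        assert block.projection is not None
        block2 = _nn.ResidualBlock(16, 4, 16, np.random.default_rng(0))
        assert block2.projection is None

    def test_output_is_transform_plus_shortcut(self, rng):
        block = _nn.ResidualBlock(4, 4, 4, np.random.default_rng(3))
        x = rng.normal(size=(2, 4, 10)).astype(np.float32)
        h = block.relu1.forward(block.conv1.forward(x))
        h = block.relu2.forward(block.conv2.forward(h))
        h = block.conv3.forward(h)
        np.testing.assert_allclose(block.forward(x), np.maximum(h + x, 0),
                                   atol=1e-6)


class TestGradients:
    """Central-difference check of the from-scratch backward passes."""

    @staticmethod
    def _loss_of(model, x1, x2, y):
        logits = model.forward_logits(x1, x2)
        return _nn.softmax_xent(logits, y)[0]

    def test_numerical_gradcheck(self, rng, monkeypatch):
        monkeypatch.setattr(_nn, "DTYPE", np.float64)  # for a tight check
        config = EnsembleConfig(
            branch1_pretrain=(("conv", 5, 3), ("pool", 2)),
            branch2_pretrain=(("conv", 3, 2), ("pool", 2)),
            residual_specs=((2, 4),),
            residual_iterations=1,
            branch_feature_len=6,
            input_lens=(16, 10),
            seed=11,
        )
        model = build_ensemble(config)
        # jitter every parameter so no pre-activation sits exactly on a
        # ReLU kink (zero-init biases otherwise make the loss one-sidedly
        # differentiable there and central differences disagree)
        for p, _ in model._params_grads():
            p += 0.05 * rng.standard_normal(p.shape)
        x1 = rng.normal(size=(4, 16))
        x2 = rng.normal(size=(4, 10))
        y = np.array([0, 1, 0, 1])

        logits = model.forward_logits(x1, x2, train=True)
        _, grad = _nn.softmax_xent(logits, y)
        for _, g in model._params_grads():
            g[...] = 0
        model.backward(grad)

        rng_idx = np.random.default_rng(0)
        eps = 1e-6
        checked = 0
        for p, g in model._params_grads():
            flat_p, flat_g = p.ravel(), g.ravel()
            for idx in rng_idx.choice(p.size, size=min(4, p.size),
                                      replace=False):
                orig = flat_p[idx]
                flat_p[idx] = orig + eps
                up = self._loss_of(model, x1, x2, y)
                flat_p[idx] = orig - eps
                down = self._loss_of(model, x1, x2, y)
                flat_p[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert flat_g[idx] == pytest.approx(numeric, rel=1e-4,
                                                    abs=1e-7)
                checked += 1
        assert checked > 20


class TestTraining:
    def test_learns_separable_toy(self, tiny_model_config):
        train = separable_set(10, 120, 60, seed=1)
        model = build_ensemble(tiny_model_config)
        train_ensemble(model, train, TrainConfig(epochs=50, seed=2,
                                                 batch_size=8))
        assert model.training_history[-1]["accuracy"] == 1.0
        test = separable_set(10, 120, 60, seed=99)
        x1 = np.stack([s.x1.values for s in test])
        x2 = np.stack([s.x2.values for s in test])
        scores = model.predict_proba(x1, x2)[:, 0]
        auc = roc_auc([s.label == "codel" for s in test], scores).auc
        assert auc == 1.0

    def test_random_labels_no_signal(self, rng, tiny_model_config):
        # featureless noise with random labels: held-out AUC must hover
        # around chance (no structure for the model to generalize from)
        def noise_set(n, seed):
            r = np.random.default_rng(seed)
            return [make_features(f"s{i}", r.normal(size=120),
                                  r.normal(size=60),
                                  "codel" if i % 2 else "no_codel")
                    for i in range(n)]

        model = build_ensemble(tiny_model_config)
        train_ensemble(model, noise_set(16, seed=5),
                       TrainConfig(epochs=10, seed=2, batch_size=8))
        test = noise_set(50, seed=123)
        x1 = np.stack([s.x1.values for s in test])
        x2 = np.stack([s.x2.values for s in test])
        scores = model.predict_proba(x1, x2)[:, 0]
        auc = roc_auc([s.label == "codel" for s in test], scores).auc
        assert 0.25 <= auc <= 0.75

    def test_training_loss_decreases(self, tiny_model_config):
        train = separable_set(8, 120, 60, seed=3)
        model = build_ensemble(tiny_model_config)
        train_ensemble(model, train, TrainConfig(epochs=12, seed=1,
                                                 batch_size=8,
                                                 loss_tol=1e-9))
        losses = [r["loss"] for r in model.training_history]
        # smoothed trend must go down on separable data
        assert np.mean(losses[-3:]) < np.mean(losses[:3])

    def test_empty_training_set(self, tiny_model_config):
        model = build_ensemble(tiny_model_config)
        with pytest.raises(ValueError, match="empty"):
            train_ensemble(model, [], TrainConfig())

    def test_single_class_rejected(self, tiny_model_config):
        train = [s for s in separable_set(4, 120, 60, seed=1)
                 if s.label == "codel"]
        model = build_ensemble(tiny_model_config)
        with pytest.raises(ValueError, match="both classes"):
            train_ensemble(model, train, TrainConfig())

    def test_reproducible_history(self, tiny_model_config):
        train = separable_set(6, 120, 60, seed=4)
        histories = []
        for _ in range(2):
            model = build_ensemble(tiny_model_config)
            train_ensemble(model, train, TrainConfig(epochs=3, seed=9,
                                                     batch_size=4,
                                                     loss_tol=1e-9))
            histories.append([r["loss"] for r in model.training_history])
        np.testing.assert_allclose(histories[0], histories[1], rtol=1e-6)


class TestPersistence:
    def test_save_load_bit_identical(self, tiny_model_config, tmp_path, rng):
        train = separable_set(4, 120, 60, seed=8)
        model = build_ensemble(tiny_model_config)
        train_ensemble(model, train, TrainConfig(epochs=2, seed=1,
                                                 batch_size=4))
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        x1 = rng.normal(size=(5, 120))
        x2 = rng.normal(size=(5, 60))
        np.testing.assert_array_equal(model.predict_proba(x1, x2),
                                      loaded.predict_proba(x1, x2))
        assert loaded.training_history == model.training_history

    def test_loaded_config_matches(self, tiny_model_config, tmp_path):
        model = build_ensemble(tiny_model_config)
        save_model(model, tmp_path / "m.npz")
        assert load_model(tmp_path / "m.npz").config == tiny_model_config


class TestTrainConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"epochs": 0}, {"batch_size": 0}, {"learning_rate": -1},
        {"validation_fraction": 0.9}])
    def test_rejects_bad_values(self, kwargs):
        with pytest.raises(ValueError):
            TrainConfig(**kwargs)
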