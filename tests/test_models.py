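import numpy as np
import pytest

from affectsense.models import (Cnn1dSpec, ConformerSpec, Model, build_cnn,
                                build_conformer, compute_class_weights,
                                fine_tune, train_classifier,
                                train_vad_regressor)
from affectsense.nn import TrainConfig
from affectsense.nn.losses import softmax


class TestBuildCnn:
    def test_output_is_distribution(self, rng):
        model = build_cnn(Cnn1dSpec(input_len=62, n_classes=3), seed=0)
        probs = model.predict_proba(rng.standard_normal((5, 62)))
        assert probs.shape == (5, 3)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_parameter_count_closed_form(self):
        spec = Cnn1dSpec(input_len=62, n_classes=3)
        model = build_cnn(spec, seed=0)
        expected = (
            (3 * 1) * 64 + 64          # conv1 W + b
            + 2 * 64                   # bn1 gamma + beta
            + (3 * 64) * 128 + 128     # conv2 W + b
            + 2 * 128                  # bn2 gamma + beta
            + 128 * 64 + 64            # dense W + b
            + 64 * 3 + 3               # head W + b
        )
        assert model.network.n_params() == expected

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            build_cnn(Cnn1dSpec(input_len=3, n_classes=2), seed=0)

    def test_layer_order(self):
        model = build_cnn(Cnn1dSpec(input_len=62, n_classes=3), seed=0)
        names = [lyr.name for lyr in model.network]
        assert names == ["conv1", "bn1", "pool1", "drop1", "conv2", "bn2",
                         "pool2", "drop2", "gap", "dense", "drop3", "head"]


class TestClassWeights:
    def test_study_counts_example(self):
        labels = np.repeat([0, 1, 2], [10746, 3460, 6142])
        w = compute_class_weights(labels)
        np.testing.assert_allclose(w, [0.6312, 1.9603, 1.1043], atol=1e-4)

    def test_balanced_counts_give_unit_weights(self):
        np.testing.assert_allclose(
            compute_class_weights(np.repeat([0, 1, 2], 50)), np.ones(3))

    def test_weighted_count_identity(self, rng):
        labels = rng.integers(0, 4, 500)
        w = compute_class_weights(labels)
        counts = np.bincount(labels)
        assert (counts * w).sum() == pytest.approx(len(labels))

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="no samples"):
            compute_class_weights(np.array([0, 0, 2, 2]))


class TestTrainingContracts:
    def test_same_seed_reproduces_losses(self, rng):
        x = rng.standard_normal((120, 16))
        y = rng.integers(0, 2, 120)

        def run():
            model = build_cnn(Cnn1dSpec(input_len=16, n_classes=2), seed=3)
            cfg = TrainConfig(lr=1e-3, max_epochs=3, batch_size=32, seed=3)
            _, hist = train_classifier(model, (x[:90], y[:90]),
                                       (x[90:], y[90:]), cfg)
            return hist

        h1, h2 = run(), run()
        np.testing.assert_allclose(h1.train_loss, h2.train_loss, atol=1e-6)
        np.testing.assert_allclose(h1.val_loss, h2.val_loss, atol=1e-6)

    def test_early_stop_restores_best_val_weights(self, rng):
        x = rng.standard_normal((100, 16))
        y = rng.integers(0, 2, 100)
        model = build_cnn(Cnn1dSpec(input_len=16, n_classes=2), seed=1)
        cfg = TrainConfig(lr=5e-2, max_epochs=10, batch_size=25, seed=1,
                          early_stop_patience=3)
        model, hist = train_classifier(model, (x[:80], y[:80]),
                                       (x[80:], y[80:]), cfg)
        from affectsense.nn.losses import softmax_cross_entropy
        out = model.predict_batched(x[80:])
        final_loss, _ = softmax_cross_entropy(out, y[80:])
        assert final_loss == pytest.approx(min(hist.val_loss), abs=1e-9)

    def test_lr_history_non_increasing(self, rng):
        x = rng.standard_normal((80, 16))
        y = rng.integers(0, 2, 80)
        model = build_cnn(Cnn1dSpec(input_len=16, n_classes=2), seed=2)
        cfg = TrainConfig(lr=1e-3, max_epochs=8, batch_size=20, seed=2,
                          plateau_patience=1)
        _, hist = train_classifier(model, (x[:60], y[:60]), (x[60:], y[60:]),
                                   cfg)
        assert all(a >= b for a, b in zip(hist.lr, hist.lr[1:]))
        assert min(hist.lr) >= 1e-6


class TestFineTune:
    @pytest.fixture
    def pretrained_bundle(self, rng):
        model = build_cnn(Cnn1dSpec(input_len=32, n_classes=3), seed=4)
        return model.to_bundle({"source": "pretrain"})

    def test_backbone_loaded_bitwise_new_head_dim(self, pretrained_bundle, rng):
        x = rng.standard_normal((40, 32, 1))
        y = rng.integers(0, 4, 40)
        cfg = TrainConfig(lr=1e-4, max_epochs=0, seed=5)
        model, _ = fine_tune(pretrained_bundle, (x[:30], y[:30]),
                             (x[30:], y[30:]), cfg, n_classes=4, seed=5)
        assert model.spec.n_classes == 4
        assert model.network.get("head").params["W"].shape == (64, 4)
        for name, arr in pretrained_bundle.weights.items():
            if not name.startswith("head/"):
                np.testing.assert_array_equal(
                    model.network.state_items()[name], arr)

    def test_zero_epochs_predictions_deterministic(self, pretrained_bundle, rng):
        x = rng.standard_normal((10, 32, 1))
        y = rng.integers(0, 4, 10)
        cfg = TrainConfig(lr=1e-4, max_epochs=0, seed=6)
        m1, _ = fine_tune(pretrained_bundle, (x, y), (x, y), cfg,
                          n_classes=4, seed=6)
        cfg2 = TrainConfig(lr=1e-4, max_epochs=0, seed=6)
        m2, _ = fine_tune(pretrained_bundle, (x, y), (x, y), cfg2,
                          n_classes=4, seed=6)
        np.testing.assert_array_equal(m1.predict_logits(x), m2.predict_logits(x))

    def test_freeze_backbone_keeps_conv_weights(self, pretrained_bundle, rng):
        x = rng.standard_normal((60, 32, 1))
        y = rng.integers(0, 4, 60)
        cfg = TrainConfig(lr=1e-2, max_epochs=2, batch_size=20, seed=7)
        model, _ = fine_tune(pretrained_bundle, (x[:45], y[:45]),
                             (x[45:], y[45:]), cfg, n_classes=4, seed=7,
                             freeze_backbone=True)
        np.testing.assert_array_equal(model.network.get("conv1").params["W"],
                                      pretrained_bundle.weights["conv1/W"])

    def test_channel_mismatch_rejected(self, pretrained_bundle, rng):
        with pytest.raises(ValueError, match="channel"):
            fine_tune(pretrained_bundle, (rng.standard_normal((4, 32, 2)),
                                          np.zeros(4, int)),
                      (rng.standard_normal((2, 32, 2)), np.zeros(2, int)),
                      TrainConfig(max_epochs=0),
                      n_classes=2, input_channels=2, seed=0)


class TestConformer:
    def test_forward_shapes_and_attention_rows(self, rng):
        model = build_conformer(ConformerSpec(), seed=0)
        out = model.forward(rng.standard_normal((8, 33)))
        assert out.shape == (8, 3)
        for i in range(2):
            attn = model.network.get(f"enc{i}").mha.last_attention
            assert attn.shape == (8, 4, 33, 33)
            np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-6)

    def test_head_divisibility_enforced(self):
        with pytest.raises(ValueError, match="divisible"):
            ConformerSpec(projection_dim=30, n_heads=4)

    def test_targets_outside_unit_interval_rejected(self, rng):
        model = build_conformer(ConformerSpec(), seed=0)
        x = rng.standard_normal((10, 33))
        y = rng.random((10, 3)) + 0.5  # exceeds 1
        with pytest.raises(ValueError, match="outside"):
            train_vad_regressor(model, (x, y), (x, y),
                                TrainConfig(loss="smooth_l1", max_epochs=1))

    def test_checkpoint_round_trip_preserves_predictions(self, rng, tmp_path):
        from affectsense.io_formats import load_checkpoint, save_checkpoint
        model = build_conformer(ConformerSpec(), seed=9)
        x = rng.standard_normal((4, 33))
        path = save_checkpoint(model.to_bundle(), tmp_path / "c.npz")
        back = Model.from_bundle(load_checkpoint(path))
        np.testing.assert_array_equal(back.predict_logits(x),
                                      model.predict_logits(x))
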