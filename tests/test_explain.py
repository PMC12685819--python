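import numpy as np
import pytest

from affectsense.explain import (extract_attention, grad_cam_1d,
                                 grad_cam_multichannel, integrated_gradients,
                                 tsne_embed)
from affectsense.models import (Cnn1dSpec, ConformerSpec, Model, build_cnn,
                                build_conformer)
from affectsense.nn import Conv1D, Dense, GlobalAvgPool1D, Sequential


def _toy_conv_model(n_channels=1, weight_by_channel=None):
    """A hand-traceable net: identity-ish conv -> GAP -> linear head."""
    conv = Conv1D(n_channels, 1, 3, activation="relu", name="conv1")
    w = np.zeros((3 * n_channels, 1))
    if weight_by_channel is None:
        weight_by_channel = [1.0] * n_channels
    for c, wc in enumerate(weight_by_channel):
        w[n_channels + c, 0] = wc  # centre tap only
    conv.params["W"] = w
    conv.params["b"] = np.zeros(1)
    head = Dense(1, 2, name="head")
    head.params["W"] = np.array([[1.0, -1.0]])
    head.params["b"] = np.zeros(2)
    net = Sequential([conv, GlobalAvgPool1D(name="gap"), head])
    spec = Cnn1dSpec(input_len=32, input_channels=n_channels, n_classes=2)
    return Model(net, spec, "cnn1d")


class TestGradCam:
    def test_impulse_localised(self):
        model = _toy_conv_model()
        x = np.zeros(32)
        x[12] = 5.0
        hm = grad_cam_1d(model, x, target_class=0, conv_layer="conv1")
        assert hm.values.shape == (32,)
        assert np.argmax(hm.values) == 12
        assert hm.values.max() == pytest.approx(1.0)
        assert hm.values.min() >= 0.0

    def test_degenerate_constant_activation_returns_zeros(self):
        model = _toy_conv_model()
        hm = grad_cam_1d(model, np.zeros(32), target_class=0,
                         conv_layer="conv1")
        np.testing.assert_array_equal(hm.values, np.zeros(32))

    @pytest.mark.parametrize("input_len", [62, 640])
    def test_heatmap_length_matches_input(self, rng, input_len):
        model = build_cnn(Cnn1dSpec(input_len=input_len, n_classes=3), seed=0)
        hm = grad_cam_1d(model, rng.standard_normal(input_len), 1)
        assert hm.values.shape == (input_len,)
        assert hm.values.min() >= 0.0 and hm.values.max() <= 1.0

    def test_invalid_layer_and_class(self, rng):
        model = build_cnn(Cnn1dSpec(input_len=62, n_classes=3), seed=0)
        with pytest.raises(ValueError, match="not convolutional"):
            grad_cam_1d(model, rng.standard_normal(62), 0, conv_layer="dense")
        with pytest.raises(IndexError):
            grad_cam_1d(model, rng.standard_normal(62), 7)


class TestGradCamMultichannel:
    def test_single_channel_reduces_to_1d(self, rng):
        model = build_cnn(Cnn1dSpec(input_len=64, n_classes=3), seed=1)
        x = rng.standard_normal(64)
        maps = grad_cam_multichannel(model, x, 0)
        hm = grad_cam_1d(model, x, 0)
        assert maps.shape == (1, 64)
        np.testing.assert_allclose(maps[0], hm.values, atol=1e-12)

    def test_global_max_is_one_unless_all_zero(self, rng):
        model = build_cnn(Cnn1dSpec(input_len=32, input_channels=3,
                                    n_classes=2), seed=2)
        maps = grad_cam_multichannel(model, rng.standard_normal((32, 3)), 0)
        assert maps.shape == (3, 32)
        assert maps.max() == pytest.approx(1.0)

    def test_sensitive_channel_attracts_mass(self, rng):
        model = _toy_conv_model(n_channels=2, weight_by_channel=[1.0, 0.0])
        x = np.abs(rng.standard_normal((32, 2))) + 0.5
        maps = grad_cam_multichannel(model, x, 0, conv_layer="conv1")
        assert maps[0].sum() > maps[1].sum()


class TestIntegratedGradients:
    def test_linear_model_closed_form(self, rng):
        head = Dense(8, 2, name="head")
        w = rng.standard_normal((8, 2))
        head.params["W"] = w
        head.params["b"] = np.array([0.3, -0.2])
        from affectsense.nn import Flatten
        net = Sequential([Flatten(name="flatten"), head])
        model = Model(net, Cnn1dSpec(input_len=8, n_classes=2), "cnn1d")
        x = rng.standard_normal(8)
        attr = integrated_gradients(model, x, target=0)
        np.testing.assert_allclose(attr.values, w[:, 0] * x, atol=1e-10)
        assert abs(attr.completeness_gap) < 1e-10

    def test_baseline_input_gives_zero_attribution(self, rng):
        model = build_cnn(Cnn1dSpec(input_len=32, n_classes=3), seed=3)
        attr = integrated_gradients(model, np.zeros(32), target=1)
        np.testing.assert_allclose(attr.values, 0.0, atol=1e-12)

    def test_completeness_gap_shrinks_with_steps(self, rng):
        """Riemann refinement: with nonzero biases the straight path from the
        zero baseline crosses ReLU kinks, so the midpoint-rule gap is nonzero
        and shrinks as the grid is refined."""
        model = build_cnn(Cnn1dSpec(input_len=32, n_classes=3, dropout=0.0),
                          seed=4)
        for name, p in model.network.param_items().items():
            if name.endswith("/b") or name.endswith("beta"):
                p += 0.5 * rng.standard_normal(p.shape)
        mean_gaps = []
        xs = [3.0 * rng.standard_normal(32) for _ in range(6)]
        for steps in (10, 50, 200):
            mean_gaps.append(np.mean([
                abs(integrated_gradients(model, x, target=0, steps=steps)
                    .completeness_gap) for x in xs]))
        assert mean_gaps[2] < mean_gaps[1] < mean_gaps[0]
        # completeness holds at fine resolution, relative to the score change
        x = xs[0]
        fx = model.predict_logits(x)[0, 0]
        f0 = model.predict_logits(np.zeros(32))[0, 0]
        gap = abs(integrated_gradients(model, x, target=0, steps=200)
                  .completeness_gap)
        assert gap <= 1e-2 * max(abs(fx - f0), 1e-6) + 1e-8


class TestAttention:
    def test_shape_and_row_sums_under_default_spec(self, rng):
        model = build_conformer(ConformerSpec(), seed=0)
        attn = extract_attention(model, rng.standard_normal(33))
        assert attn.shape == (2, 4, 33, 33)
        np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-6)

    def test_uniform_logits_give_uniform_rows(self, rng):
        model = build_conformer(ConformerSpec(n_encoder_layers=1), seed=0)
        mha = model.network.get("enc0").mha
        # zero query/key projections -> all attention logits equal
        mha.params["Wq"][:] = 0.0
        mha.params["bq"][:] = 0.0
        mha.params["Wk"][:] = 0.0
        mha.params["bk"][:] = 0.0
        attn = extract_attention(model, rng.standard_normal(33))
        np.testing.assert_allclose(attn, 1.0 / 33.0, atol=1e-12)

    def test_non_conformer_rejected(self, rng):
        model = build_cnn(Cnn1dSpec(input_len=33, n_classes=2), seed=0)
        with pytest.raises(ValueError, match="conformer"):
            extract_attention(model, rng.standard_normal(33))


class TestTsne:
    def test_shape_and_determinism(self, rng):
        feats = rng.standard_normal((100, 16))
        a = tsne_embed(feats, seed=0)
        b = tsne_embed(feats, seed=0)
        assert a.shape == (100, 2)
        np.testing.assert_array_equal(a, b)

    def test_separated_clusters_stay_separated(self, rng):
        from sklearn.metrics import silhouette_score
        a = rng.standard_normal((60, 16))
        b = rng.standard_normal((60, 16)) + 12.0
        feats = np.vstack([a, b])
        labels = np.repeat([0, 1], 60)
        coords = tsne_embed(feats, perplexity=20, seed=1)
        assert silhouette_score(coords, labels) > 0.5

    def test_too_few_samples_for_perplexity(self, rng):
        with pytest.raises(ValueError, match="perplexity"):
            tsne_embed(rng.standard_normal((50, 8)), perplexity=30)
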