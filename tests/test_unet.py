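import numpy as np
import pytest

from dropseg.io import QPIImage
from dropseg.nn.layers import bce_with_logits, sigmoid
from dropseg.nn.unet import (
    UNetConfig,
    UNetModel,
    UNetSegmenter,
    build_unet,
    count_trainable_parameters,
    reduced_config,
    segment,
    train_unet,
)
from dropseg.synthetic import SceneSpec, generate_dataset

TINY = dict(canvas=32, encoder_widths=(4, 8, 16, 32), bottleneck_width=64)


def closed_form_count(widths, bottleneck, in_channels=1):
    """Analytic layer-by-layer parameter sum for the architecture dialect."""

    def conv(kh, kw, cin, cout):
        return (kh * kw * cin + 1) * cout

    total = 0
    cin = in_channels
    for w in widths:
        total += conv(3, 3, cin, w) + conv(3, 3, w, w)
        cin = w
    total += conv(3, 3, widths[-1], bottleneck) + conv(3, 3, bottleneck, bottleneck)
    prev = bottleneck
    for w in reversed(widths):
        total += conv(2, 2, prev, w) + conv(3, 3, 2 * w, w) + conv(3, 3, w, w)
        prev = w
    total += conv(3, 3, widths[0], 2) + conv(1, 1, 2, 1)
    return total


def tiny_scenes(n, seed=0, canvas=32):
    spec = SceneSpec(canvas=canvas, cell_axes=(9.0, 13.0), droplet_count=(1, 3),
                     droplet_radius=(2.0, 4.0))
    return generate_dataset(spec, n, seed=seed)


class TestArchitecture:
    def test_parameter_count_invariant_to_canvas(self):
        small = build_unet(UNetConfig(canvas=64))
        large = build_unet(UNetConfig(canvas=256))
        assert (
            count_trainable_parameters(small)
            == count_trainable_parameters(large)
        )

    @pytest.mark.parametrize(
        "widths,bottleneck",
        [((64, 128, 256, 512), 1024), ((8, 16, 32, 64), 128), ((4, 8, 16, 32), 64)],
    )
    def test_graph_walk_matches_closed_form_sum(self, widths, bottleneck):
        model = build_unet(
            UNetConfig(canvas=64, encoder_widths=widths, bottleneck_width=bottleneck)
        )
        assert count_trainable_parameters(model) == closed_form_count(
            widths, bottleneck
        )

    def test_single_conv_parameter_arithmetic(self):
        from dropseg.nn.layers import Conv2D

        conv = Conv2D(1, 64, 3, np.random.default_rng(0))
        assert conv.n_params == (3 * 3 * 1 + 1) * 64 == 640

    def test_indivisible_canvas_rejected(self):
        with pytest.raises(ValueError):
            UNetConfig(canvas=100)

    def test_invalid_threshold_and_dropout_rejected(self):
        with pytest.raises(ValueError):
            UNetConfig(threshold=0.0)
        with pytest.raises(ValueError):
            UNetConfig(dropout_rate=1.0)

    def test_backprop_matches_finite_differences(self):
        """Spot-check analytic gradients against central differences on a
        tiny float64 network (biases randomized off the ReLU kink)."""
        cfg = UNetConfig(canvas=16, encoder_widths=(2, 3, 4, 5),
                         bottleneck_width=6, dropout_rate=0.0)
        model = UNetModel(cfg, seed=1)
        rng = np.random.default_rng(0)
        for layer in model.conv_layers():
            layer.W = layer.W.astype(np.float64)
            layer.b = rng.normal(0, 0.05, layer.b.shape)
        x = rng.random((1, 16, 16, 1))
        y = (rng.random((1, 16, 16, 1)) < 0.3).astype(np.float64)

        def loss_value():
            return bce_with_logits(model.forward_logits(x, training=False), y)[0]

        z = model.forward_logits(x, training=False)
        _, grad = bce_with_logits(z, y)
        model.backward(grad.astype(np.float64))
        eps = 1e-6
        for layer in (model.enc[0][0], model.upconvs[1], model.out):
            flat, gflat = layer.W.ravel(), layer.dW.ravel()
            for idx in (0, flat.size // 2, flat.size - 1):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = loss_value()
                flat[idx] = orig - eps
                lm = loss_value()
                flat[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                assert gflat[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-9)


class TestSegment:
    def _stub_model(self, bias):
        """All-zero weights; output bias fixes the sigmoid probability."""
        model = build_unet(UNetConfig(**TINY))
        for layer in model.conv_layers():
            layer.W[:] = 0.0
            layer.b[:] = 0.0
        model.out.b[:] = bias
        return model

    def test_probability_below_threshold_gives_empty_mask(self):
        logit = np.log(0.69 / 0.31)
        model = self._stub_model(logit)
        prob, mask = segment(model, QPIImage(pixels=np.random.rand(32, 32)))
        assert prob.max() == pytest.approx(0.69, abs=1e-6)
        assert mask.pixels.sum() == 0

    def test_probability_at_threshold_is_positive(self):
        logit = np.log(0.70 / 0.30)
        model = self._stub_model(logit)
        _, mask = segment(model, QPIImage(pixels=np.random.rand(32, 32)))
        assert np.all(mask.pixels == 1)

    def test_mask_restored_to_original_dimensions(self):
        model = self._stub_model(0.0)
        prob, mask = segment(model, QPIImage(pixels=np.random.rand(20, 27)))
        assert prob.shape == (20, 27)
        assert mask.pixels.shape == (20, 27)

    def test_oversized_image_rejected(self):
        model = self._stub_model(0.0)
        with pytest.raises(ValueError):
            segment(model, QPIImage(pixels=np.random.rand(40, 40)))

    def test_mask_monotone_non_increasing_in_threshold(self, rng):
        model = build_unet(UNetConfig(**TINY), seed=0)
        img = QPIImage(pixels=rng.random((32, 32)))
        prob, _ = segment(model, img)
        assert 0 < prob.min() and prob.max() < 1
        loose = prob >= 0.3
        strict = prob >= 0.8
        assert np.all(strict <= loose)


class TestTraining:
    def test_loss_decreases_on_easy_scenes(self):
        pairs = tiny_scenes(12)
        seg = UNetSegmenter(epochs=8, batch_size=4, seed=0, **TINY)
        seg.fit([p.image for p in pairs], [p.mask for p in pairs])
        rec = seg.train_record_
        assert rec.losses[-1] < rec.losses[0]
        assert len(rec.losses) == 8
        assert all(l >= 0 for l in rec.losses)

    def test_positive_free_labels_collapse_to_all_negative(self):
        """Trained on all-background masks the net learns the constant
        non-lipid answer — the local-optimum failure mode of unbalanced
        training."""
        pairs = tiny_scenes(8)
        blank = [np.zeros((32, 32), dtype=np.uint8) for _ in pairs]
        model = build_unet(UNetConfig(**TINY), seed=0)
        from dropseg.nn.unet import preprocess_image

        imgs = [preprocess_image(p.image, 32)[0] for p in pairs]
        model, _ = train_unet(model, imgs, blank, epochs=5, batch_size=4, seed=0,
                              learning_rate=1e-3)
        for p in pairs:
            _, mask = segment(model, p.image)
            assert mask.pixels.sum() == 0

    def test_identical_seeds_give_identical_histories(self):
        pairs = tiny_scenes(6)
        histories = []
        for _ in range(2):
            seg = UNetSegmenter(epochs=3, batch_size=2, seed=5, **TINY)
            seg.fit([p.image for p in pairs], [p.mask for p in pairs])
            histories.append(seg.train_record_.losses)
        assert histories[0] == histories[1]

    def test_dimension_mismatch_and_empty_dataset_rejected(self):
        model = build_unet(UNetConfig(**TINY))
        with pytest.raises(ValueError):
            train_unet(model, [], [], epochs=1)
        with pytest.raises(ValueError):
            train_unet(
                model, [np.zeros((16, 16))], [np.zeros((16, 16))], epochs=1
            )

    def test_inference_is_deterministic_despite_dropout(self):
        pairs = tiny_scenes(4)
        seg = UNetSegmenter(epochs=2, batch_size=2, seed=0, **TINY)
        seg.fit([p.image for p in pairs], [p.mask for p in pairs])
        a = seg.predict_proba([pairs[0].image])[0]
        b = seg.predict_proba([pairs[0].image])[0]
        np.testing.assert_array_equal(a, b)


class TestPersistence:
    def test_weight_round_trip_preserves_probabilities(self, tmp_path, rng):
        model = build_unet(UNetConfig(**TINY), seed=2)
        img = QPIImage(pixels=rng.random((32, 32)))
        before, _ = segment(model, img)
        path = tmp_path / "weights.npz"
        model.save_weights(str(path))
        loaded = UNetModel.load_weights(str(path))
        after, _ = segment(loaded, img)
        np.testing.assert_array_equal(before, after)

    def test_reduced_config_matches_constructor(self):
        cfg = reduced_config()
        assert cfg.encoder_widths == (8, 16, 32, 64)
        assert cfg.bottleneck_width == 128
        assert cfg.canvas == 64
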