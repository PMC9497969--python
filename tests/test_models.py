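"""Network construction, shape/determinism contracts, schedules, grad-CAM."""

import numpy as np
import pytest

from fluorocad import models as mdl
from fluorocad import nn
from fluorocad.simulate import ChannelLayout, SimConfig, generate_frame

TINY = mdl.BackboneSpec(family="mobile_like", width_multiplier=0.25,
                        depth=3, input_size=32, in_channels=3)


class TestSpecs:
    def test_input_size_must_divide_by_depth_powers(self):
        with pytest.raises(ValueError, match="divisible"):
            mdl.BackboneSpec(input_size=100, depth=3)

    def test_bisenet_needs_deep_backbone(self):
        with pytest.raises(ValueError, match="depth"):
            mdl.SegModelSpec(architecture="bisenet",
                             backbone=mdl.BackboneSpec(depth=3, in_channels=1))

    def test_lr_schedule_decays_by_08_every_10_epochs(self):
        cfg = mdl.TrainConfig(initial_lr=1e-3)
        assert mdl.learning_rate_at_epoch(cfg, 1) == pytest.approx(1e-3)
        assert mdl.learning_rate_at_epoch(cfg, 10) == pytest.approx(1e-3)
        assert mdl.learning_rate_at_epoch(cfg, 11) == pytest.approx(8e-4)
        assert mdl.learning_rate_at_epoch(cfg, 25) == pytest.approx(6.4e-4)


class TestClassifier:
    def test_forward_batch_returns_probabilities(self):
        model = mdl.build_classifier(TINY, seed=0)
        x = np.random.default_rng(0).uniform(0, 1, (4, 32, 32, 3))
        probs = model.predict_proba(x)
        assert probs.shape == (4,)
        assert ((probs >= 0) & (probs <= 1)).all()

    def test_seeded_model_is_deterministic_but_input_sensitive(self):
        m1 = mdl.build_classifier(TINY, seed=5)
        m2 = mdl.build_classifier(TINY, seed=5)
        zeros = np.zeros((1, 32, 32, 3))
        ones = np.ones((1, 32, 32, 3))
        assert m1.predict_proba(zeros) == m2.predict_proba(zeros)
        assert m1.predict_proba(zeros) != m1.predict_proba(ones)

    @pytest.mark.parametrize("family", ["mobile_like", "xception_like"])
    def test_width_multiplier_scales_parameter_count(self, family):
        def count(w):
            spec = mdl.BackboneSpec(family=family, width_multiplier=w,
                                    depth=3, input_size=32, in_channels=3)
            return mdl.build_classifier(spec).num_params()
        assert count(0.5) < count(1.0) < count(2.0)

    def test_predict_suspicious_thresholding(self, desk_classifier,
                                             classifier_phantom):
        model, _, _ = desk_classifier
        prob, flag = mdl.predict_suspicious(model, classifier_phantom.image,
                                            threshold=0.5)
        assert flag == (prob >= 0.5)
        _, strict = mdl.predict_suspicious(model, classifier_phantom.image,
                                           threshold=1.1)
        assert strict is False

    def test_wrong_input_size_rejected(self):
        model = mdl.build_classifier(TINY, seed=0)
        with pytest.raises(ValueError):
            mdl.predict_suspicious(model, np.zeros((64, 64, 3)))


class TestSegmenter:
    def test_unet_output_shape_full_resolution(self):
        bspec = mdl.BackboneSpec(width_multiplier=0.25, depth=3,
                                 input_size=32, in_channels=1)
        model = mdl.build_segmenter(mdl.SegModelSpec(backbone=bspec), seed=0)
        x = mdl._to_nchw([np.random.default_rng(0).uniform(0, 1, (32, 32))])
        out = model.forward_scores(nn.Tensor(x))
        assert out.data.shape == (1, 2, 32, 32)

    def test_bisenet_forward_is_seed_deterministic(self):
        bspec = mdl.BackboneSpec(width_multiplier=0.25, depth=4,
                                 input_size=32, in_channels=1)
        spec = mdl.SegModelSpec(architecture="bisenet", backbone=bspec)
        x = np.random.default_rng(1).uniform(0, 1, (2, 32, 32))
        outs = []
        for _ in range(2):
            model = mdl.build_segmenter(spec, seed=9)
            outs.append(model.forward_scores(
                nn.Tensor(mdl._to_nchw(list(x)))).data)
        assert np.array_equal(outs[0], outs[1])

    def test_constant_image_gives_uniform_interior_prediction(self):
        bspec = mdl.BackboneSpec(width_multiplier=0.25, depth=3,
                                 input_size=96, in_channels=1)
        model = mdl.build_segmenter(mdl.SegModelSpec(backbone=bspec), seed=0)
        model.set_training(False)
        out = model.forward_scores(
            nn.Tensor(mdl._to_nchw([np.full((96, 96), 0.5)]))).data
        # translation invariance of convs: away from the zero-padding halo
        # (stacked 3x3 convs down to 1/8 resolution reach ~35 px inward) the
        # scores must be spatially constant
        interior = out[0, :, 40:-40, 40:-40]
        assert np.allclose(interior, interior[:, :1, :1], atol=1e-4)

    def test_mask_prediction_is_binary_with_background_ties(self):
        bspec = mdl.BackboneSpec(width_multiplier=0.25, depth=3,
                                 input_size=32, in_channels=1)
        model = mdl.build_segmenter(mdl.SegModelSpec(backbone=bspec), seed=0)
        pred = mdl.predict_mask(model, np.zeros((32, 32)))
        assert pred.dtype == bool
        tied = np.argmax(np.zeros((1, 2, 4, 4)), axis=1)
        assert (tied == 0).all()     # ties resolve to background


class TestTraining:
    def test_single_class_training_set_rejected(self):
        model = mdl.build_classifier(TINY, seed=0)
        items = [(np.zeros((32, 32, 3)), 1)] * 4
        with pytest.raises(mdl.DegenerateDataError):
            mdl.train_classifier(model, items, items, mdl.TrainConfig())

    def test_grid_mismatch_rejected(self):
        bspec = mdl.BackboneSpec(width_multiplier=0.25, depth=3,
                                 input_size=32, in_channels=1)
        model = mdl.build_segmenter(mdl.SegModelSpec(backbone=bspec), seed=0)
        bad = [(np.zeros((32, 32)), np.zeros((16, 16), bool))]
        with pytest.raises(ValueError, match="mismatch"):
            mdl.train_segmenter(model, bad, bad, mdl.TrainConfig())

    def test_seeded_first_epoch_loss_reproducible(self):
        rng = np.random.default_rng(3)
        items = ([(rng.uniform(0, 1, (32, 32, 3)), 1) for _ in range(8)]
                 + [(rng.uniform(0, 0.3, (32, 32, 3)), 0) for _ in range(8)])
        losses = []
        for _ in range(2):
            model = mdl.build_classifier(TINY, seed=4)
            _, hist = mdl.train_classifier(
                model, items, items[:4],
                mdl.TrainConfig(max_epochs=1, batch_size=4, seed=11))
            losses.append(hist["train_loss"][0])
        assert losses[0] == losses[1]

    def test_perfect_prediction_loss_hits_entropy_floor(self):
        # logits hugely favoring the correct class -> loss ~ 0
        z = np.zeros((1, 2, 4, 4), np.float32)
        labels = np.random.default_rng(0).integers(0, 2, (1, 4, 4))
        z[0, 1][labels[0] == 1] = 50.0
        z[0, 0][labels[0] == 0] = 50.0
        loss = nn.softmax_cross_entropy(nn.Tensor(z), labels)
        assert float(loss.data) == pytest.approx(0.0, abs=1e-6)


class TestGradCam:
    def test_heatmap_normalized_to_unit_max(self, desk_classifier,
                                            classifier_phantom):
        model, _, _ = desk_classifier
        cam = mdl.grad_cam(model, classifier_phantom.image)
        assert cam.shape == classifier_phantom.image.shape[:2]
        assert cam.min() >= 0.0
        assert cam.max() == pytest.approx(1.0)

    def test_degenerate_constant_input_gives_finite_map(self):
        model = mdl.build_classifier(TINY, seed=0)
        cam = mdl.grad_cam(model, np.zeros((32, 32, 3)))
        assert np.isfinite(cam).all()
        assert cam.min() >= 0.0

    def test_non_conv_model_rejected(self):
        with pytest.raises(mdl.UnsupportedModelError):
            mdl.grad_cam(object(), np.zeros((32, 32, 3)))

    def test_heatmap_localizes_lesions_on_trained_model(self, desk_classifier):
        """On most correctly classified suspicious frames the top-decile
        heatmap mass overlaps the (dilated) lesion."""
        from scipy import ndimage as ndi
        model, _, _ = desk_classifier
        hits, total = 0, 0
        for seed in range(30):
            cfg = SimConfig(size=96, seed=1000 + seed,
                            channel_layout=ChannelLayout.FLUOR_GREEN_REFL_BLUE)
            ph = generate_frame(cfg, "suspicious")
            prob, flag = mdl.predict_suspicious(model, ph.image)
            if not flag:
                continue
            total += 1
            cam = mdl.grad_cam(model, ph.image)
            top = cam >= np.quantile(cam, 0.9)
            dilated = ndi.binary_dilation(ph.lesion_mask, iterations=8)
            if (top & dilated).sum() / top.sum() > 0.3:
                hits += 1
        assert total >= 20
        assert hits / total >= 0.7


class TestCheckpoints:
    def test_roundtrip_preserves_predictions(self, tmp_path):
        model = mdl.build_classifier(TINY, seed=2)
        x = np.random.default_rng(0).uniform(0, 1, (2, 32, 32, 3))
        before = model.predict_proba(x)
        mdl.save_checkpoint(model, tmp_path / "clf")
        loaded = mdl.load_checkpoint(tmp_path / "clf")
        assert np.array_equal(before, loaded.predict_proba(x))

    def test_segmenter_roundtrip(self, tmp_path):
        bspec = mdl.BackboneSpec(width_multiplier=0.25, depth=3,
                                 input_size=32, in_channels=1)
        model = mdl.build_segmenter(mdl.SegModelSpec(backbone=bspec), seed=2)
        img = np.random.default_rng(1).uniform(0, 1, (32, 32))
        mdl.save_checkpoint(model, tmp_path / "seg")
        loaded = mdl.load_checkpoint(tmp_path / "seg")
        assert np.array_equal(mdl.predict_mask(model, img),
                              mdl.predict_mask(loaded, img))
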