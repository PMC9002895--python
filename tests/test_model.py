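"""Feature-merging network: decision rules, schedule, early stop, training."""

import numpy as np
import pytest

from ecgfusion import nn
from ecgfusion.model import (ModelConfig, build_model, classify, fuse_leads,
                             load_checkpoint, lr_at_epoch, save_checkpoint,
                             should_stop, train)


def tiny_config(**kw):
    defaults = dict(backbone="tiny-test", n_handcrafted=4, input_hw=(16, 16),
                    max_epochs=30, seed=0)
    defaults.update(kw)
    return ModelConfig(**defaults)


class TestDecisionRules:
    @pytest.mark.parametrize("x,label", [(0.0, 0), (0.5, 0), (0.51, 1), (1.0, 1)])
    def test_classify_boundary_is_normal(self, x, label):
        assert classify(x) == label

    def test_classify_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            classify(1.2)

    def test_fusion_examples(self):
        assert fuse_leads(0.9, 0.8).y == pytest.approx(1.2)
        assert fuse_leads(0.9, 0.8).label == 1
        assert fuse_leads(0.2, 0.3).y == pytest.approx(0.0)
        assert fuse_leads(0.2, 0.3).label == 0
        confident_single = fuse_leads(0.9, 0.2)
        assert confident_single.y == pytest.approx(0.6)
        assert confident_single.label == 1

    def test_rules_agree_with_grid_enumeration(self):
        grid = np.round(np.arange(0, 1.0001, 0.01), 2)
        for x in grid:
            assert classify(float(x)) == (0 if x <= 0.5 else 1)
        for y1 in grid:
            for y2 in grid:
                fused = fuse_leads(float(y1), float(y2))
                assert fused.label == (1 if y1 + y2 - 0.5 >= 0.5 else 0)

    def test_agreeing_leads_keep_their_label(self):
        grid = np.round(np.arange(0, 1.0001, 0.01), 2)
        for y1 in grid:
            for y2 in grid:
                l1, l2 = classify(float(y1)), classify(float(y2))
                if l1 == l2 and not (y1 == 0.5 or y2 == 0.5):
                    # boundary scores mix the two rules' conventions; skip them
                    assert fuse_leads(float(y1), float(y2)).label == l1

    def test_fusion_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fuse_leads(1.5, 0.2)


class TestArchitecture:
    def test_merged_dimension_rhythm(self):
        m = build_model(tiny_config(n_handcrafted=9))
        assert m.merged_dim == m.backbone_dim + 9

    def test_merged_dimension_heartbeat(self):
        m = build_model(tiny_config(n_handcrafted=11))
        assert m.merged_dim == m.backbone_dim + 11

    @pytest.mark.parametrize("backbone,dim", [
        ("vgg16", 512), ("vgg19", 512), ("resnet18", 512), ("resnet34", 512)])
    def test_standard_backbones_build_and_forward(self, backbone, dim):
        cfg = ModelConfig(backbone=backbone, n_handcrafted=9, input_hw=(32, 32), seed=0)
        m = build_model(cfg)
        assert m.backbone_dim == dim
        out = m.forward(np.random.default_rng(0).random((1, 1, 32, 32)),
                        np.random.default_rng(1).random((1, 9)))
        assert 0.0 <= out[0] <= 1.0

    def test_forward_output_in_unit_interval(self):
        m = build_model(tiny_config())
        rng = np.random.default_rng(2)
        out = m.forward(rng.random((8, 1, 16, 16)) * 10 - 5, rng.random((8, 4)))
        assert np.all((out >= 0) & (out <= 1))

    def test_rgb_mode_accepts_three_channels(self):
        m = build_model(tiny_config(input_mode="rgb"))
        out = m.forward(np.zeros((2, 3, 16, 16)), np.zeros((2, 4)))
        assert out.shape == (2,)

    def test_constant_handcrafted_features_do_not_crash(self):
        m = build_model(tiny_config())
        out = m.forward(np.random.default_rng(3).random((4, 1, 16, 16)),
                        np.full((4, 4), 0.7))
        assert out.shape == (4,)

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError, match="backbone"):
            ModelConfig(backbone="resnet50")

    def test_gradients_match_numerical_differentiation(self):
        cfg = tiny_config(input_hw=(8, 8), dropout_rate=0.0, n_handcrafted=3, seed=1)
        m = build_model(cfg)
        rng = np.random.default_rng(4)
        x, f = rng.random((3, 1, 8, 8)), rng.random((3, 3))
        y = np.array([0.0, 1.0, 1.0])
        _, grad = nn.bce_loss(m.forward(x, f, train=True), y)
        m.backward(grad)
        conv = m.backbone.layers[0]
        i = (2, 4)
        analytic = conv.gw[i]
        eps, orig = 1e-6, conv.w[i]
        conv.w[i] = orig + eps
        up, _ = nn.bce_loss(m.forward(x, f, train=True), y)
        conv.w[i] = orig - eps
        down, _ = nn.bce_loss(m.forward(x, f, train=True), y)
        conv.w[i] = orig
        assert analytic == pytest.approx((up - down) / (2 * eps), rel=1e-4, abs=1e-8)


class TestTrainingProtocol:
    def test_lr_schedule_halves_every_decay_block(self):
        cfg = tiny_config(decay_every=10)
        assert [lr_at_epoch(cfg, e) for e in (1, 10, 11, 20, 21)] == \
            [0.1, 0.1, 0.05, 0.05, 0.025]

    def test_early_stop_on_two_consecutive_drops(self):
        assert should_stop([0.8, 0.9, 0.85, 0.8]) is True
        assert should_stop([0.8, 0.9, 0.85, 0.9, 0.85]) is False
        assert should_stop([0.9, 0.8]) is False

    def test_separable_data_reaches_95_percent_train_accuracy(self):
        rng = np.random.default_rng(3)
        n = 200
        y = np.repeat([0.0, 1.0], n // 2)
        imgs = rng.random((n, 1, 16, 16)) * 0.1
        imgs[y == 1, :, :8, :] += 0.5
        feats = rng.random((n, 4)) * 0.2
        feats[y == 1, 0] += 0.6
        cfg = tiny_config()
        m = build_model(cfg)
        history = train(m, imgs, feats, y, cfg)
        assert history["epochs_run"] <= 30
        assert max(history["train_acc"]) >= 0.95

    def test_training_is_reproducible(self):
        rng = np.random.default_rng(5)
        imgs, feats = rng.random((40, 1, 16, 16)), rng.random((40, 4))
        y = (feats[:, 0] > 0.5).astype(float)
        cfg = tiny_config(max_epochs=3)
        m1, m2 = build_model(cfg), build_model(cfg)
        h1 = train(m1, imgs, feats, y, cfg)
        h2 = train(m2, imgs, feats, y, cfg)
        assert h1["loss"] == h2["loss"]
        assert np.array_equal(m1.head.w, m2.head.w)

    def test_empty_training_set_rejected(self):
        cfg = tiny_config()
        with pytest.raises(ValueError, match="empty"):
            train(build_model(cfg), np.zeros((0, 1, 16, 16)), np.zeros((0, 4)),
                  np.zeros(0), cfg)


def test_checkpoint_round_trip(tmp_path):
    cfg = tiny_config(max_epochs=2)
    m = build_model(cfg)
    rng = np.random.default_rng(6)
    imgs, feats = rng.random((20, 1, 16, 16)), rng.random((20, 4))
    train(m, imgs, feats, (feats[:, 0] > 0.5).astype(float), cfg)
    path = save_checkpoint(m, tmp_path / "ck.json", scaler_json="{}",
                           feature_names=("a", "b", "c", "d"))
    back, meta = load_checkpoint(path)
    assert meta["feature_names"] == ["a", "b", "c", "d"]
    x, f = rng.random((5, 1, 16, 16)), rng.random((5, 4))
    assert np.allclose(back.forward(x, f), m.forward(x, f))
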