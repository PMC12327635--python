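"""U-Net contracts: shapes, determinism, gradient correctness, learning."""

import numpy as np
import pytest

from mangroveseg import (ModelConfig, SceneSpec, TrainConfig, UNet, build_unet,
                         evaluate, generate_scene, hard_labels, patchify,
                         predict_probabilities, split_tiles, train_model)
from mangroveseg.losses import total_loss, total_loss_grad
from mangroveseg.tiling import TileSet
from mangroveseg.unet import preset_config


TINY = ModelConfig(in_channels=3, num_classes=4, encoder_depth=1, base_width=2, seed=0)


def test_output_shape_and_softmax(rng):
    model = build_unet(ModelConfig(encoder_depth=2, base_width=4, seed=1))
    x = rng.random((2, 3, 32, 48)).astype(np.float32)
    probs, _ = model.forward(x)
    assert probs.shape == (2, 6, 32, 48)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)
    assert probs.min() >= 0.0


def test_indivisible_tile_size_rejected(rng):
    model = build_unet(ModelConfig(encoder_depth=3, base_width=2, seed=0))
    with pytest.raises(ValueError, match="divisible"):
        model.forward(rng.random((1, 3, 36, 36)).astype(np.float32))


def test_seeded_parameter_determinism():
    a = build_unet(ModelConfig(encoder_depth=2, base_width=4, seed=5))
    b = build_unet(ModelConfig(encoder_depth=2, base_width=4, seed=5))
    c = build_unet(ModelConfig(encoder_depth=2, base_width=4, seed=6))
    for k in a.params:
        assert np.array_equal(a.params[k], b.params[k])
    assert any(not np.array_equal(a.params[k], c.params[k]) for k in a.params)


def test_inference_deterministic(rng):
    model = build_unet(ModelConfig(encoder_depth=2, base_width=4, seed=2))
    tile = (rng.random((16, 16, 3)) * 255).astype(np.uint8)
    out1 = predict_probabilities(model, [tile])
    out2 = predict_probabilities(model, [tile])
    assert np.array_equal(out1[0], out2[0])
    assert out1[0].shape == (16, 16, 6)
    np.testing.assert_allclose(out1[0].sum(axis=-1), 1.0, atol=1e-5)


def test_backprop_matches_finite_differences(rng, monkeypatch):
    """Analytic gradients vs central differences on a few parameters of
    every layer family of a tiny network, run in float64 so the finite
    differences are exact."""
    from mangroveseg import nn
    monkeypatch.setattr(nn, "DTYPE", np.float64)
    model = build_unet(TINY)
    # zero-initialized biases put dead-ReLU pixels exactly on the kink, where
    # the one-sided subgradient and central differences legitimately differ;
    # jitter them so the check probes a smooth point
    for key, p in model.params.items():
        if key.endswith("_b"):
            model.params[key] = p + rng.normal(0.0, 0.05, size=p.shape)
    x = rng.random((1, 3, 8, 8)).astype(np.float32)
    y = rng.integers(0, 4, (1, 8, 8))
    gt = np.eye(4)[y]

    def loss():
        probs, _ = model.forward(x)
        return total_loss(gt, probs.transpose(0, 2, 3, 1).astype(np.float64))

    probs, caches = model.forward(x)
    _, dpr = total_loss_grad(gt, probs.transpose(0, 2, 3, 1).astype(np.float64))
    grads = model.backward(dpr.transpose(0, 3, 1, 2), caches)
    eps = 1e-6
    for key in ["enc0a_w", "enc0b_b", "bota_w", "botb_w", "up0_w",
                "dec0a_w", "dec0b_b", "head_w", "head_b"]:
        p = model.params[key]
        for _ in range(3):
            idx = tuple(rng.integers(0, s) for s in p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            up = loss()
            p[idx] = orig - eps
            down = loss()
            p[idx] = orig
            fd = (up - down) / (2 * eps)
            assert grads[key][idx] == pytest.approx(fd, rel=1e-3, abs=1e-7), key


def test_overfit_single_tile():
    """Memorization capacity: a mini network driven to near-zero combined
    loss on one repeated color-separable tile."""
    scene, mask = generate_scene(SceneSpec(height=32, width=32, seed=3))
    tiles = patchify(scene, mask, 32)
    train_set = TileSet(images=tiles.images * 8, masks=tiles.masks * 8,
                        origins=tiles.origins * 8, tile_size=32)
    model = build_unet(ModelConfig(encoder_depth=2, base_width=8, seed=0))
    tcfg = TrainConfig(epochs=60, batch_size=8, learning_rate=5e-3,
                       loss="focal+dice", seed=0)
    model, history = train_model(model, train_set, None, tcfg)
    assert history.train_loss[-1] < 0.06
    assert history.train_acc[-1] > 0.98


def test_training_reduces_loss_and_records_history():
    scene, mask = generate_scene(SceneSpec(height=128, width=128, seed=8))
    tiles = patchify(scene, mask, 32)
    split = split_tiles(tiles, ratio=0.75, seed=8)
    tr = tiles.subset(list(split.train_indices))
    va = tiles.subset(list(split.val_indices))
    model = build_unet(ModelConfig(encoder_depth=2, base_width=4, seed=8))
    tcfg = TrainConfig(epochs=5, batch_size=4, loss="focal+dice", seed=8)
    model, history = train_model(model, tr, va, tcfg)
    assert len(history) == 5
    assert len(history.val_loss) == 5
    assert history.train_loss[-1] < history.train_loss[0]


def test_empty_training_set_rejected():
    model = build_unet(TINY)
    empty = TileSet(images=[], masks=[], origins=[], tile_size=8)
    with pytest.raises(ValueError, match="empty"):
        train_model(model, empty, None, TrainConfig(epochs=1))


def test_checkpoint_round_trip(tmp_path, rng):
    model = build_unet(ModelConfig(encoder_depth=2, base_width=4, seed=4))
    path = tmp_path / "model.ckpt.npz"
    model.save(path)
    loaded = UNet.load(path)
    assert loaded.config == model.config
    tile = (rng.random((16, 16, 3)) * 255).astype(np.uint8)
    a = predict_probabilities(model, [tile])[0]
    b = predict_probabilities(loaded, [tile])[0]
    assert np.array_equal(a, b)


def test_presets_are_heterogeneous():
    cfgs = {name: preset_config(name) for name in ("M3", "M10", "M12")}
    sizes = {(c.encoder_depth, c.base_width) for c in cfgs.values()}
    assert len(sizes) == 3
    with pytest.raises(ValueError):
        preset_config("M99")


def test_combined_loss_not_inferior_to_dice_alone():
    """Non-inferiority smoke test: on the standard synthetic benchmark the
    focal+dice objective performs at least as well as dice alone minus 0.05
    mean IoU."""
    scene, mask = generate_scene(SceneSpec(height=256, width=256, seed=21))
    tiles = patchify(scene, mask, 32)
    split = split_tiles(tiles, ratio=0.75, seed=21)
    tr = tiles.subset(list(split.train_indices))
    va = tiles.subset(list(split.val_indices))
    ref = np.concatenate([m.ravel() for m in va.masks])
    scores = {}
    for loss_name in ("dice", "focal+dice"):
        model = build_unet(ModelConfig(encoder_depth=2, base_width=8, seed=21))
        tcfg = TrainConfig(epochs=10, batch_size=8, learning_rate=2e-3,
                           loss=loss_name, seed=21)
        model, _ = train_model(model, tr, va, tcfg)
        probs = predict_probabilities(model, va)
        flat = np.concatenate([p.reshape(-1, 6) for p in probs])
        scores[loss_name] = evaluate(hard_labels(flat), ref, 6).mean_iou
    assert scores["focal+dice"] >= scores["dice"] - 0.05
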