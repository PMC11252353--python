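import numpy as np
import pytest

from fpolcyto import (
    NetConfig,
    PolarizedImagePair,
    TrainConfig,
    build_network,
    generate_sample,
    predict,
    train,
)
from fpolcyto.segnet import AugmentConfig, UNet, augment_sample

from .conftest import desk_phantom_spec


def _tiny_net(seed=0):
    return build_network(NetConfig(levels=3, base_channels=4, seed=seed))


def _tiny_samples(n, seed0=200, size=48):
    out = []
    for i in range(n):
        s = generate_sample(
            desk_phantom_spec(seed0 + i, image_size=size, n_cells=2,
                              cell_radius_range=(4, 6), ambiguous_fraction=0.0)
        )
        out.append((s.pair, s.masks))
    return out


_FAST_AUG = AugmentConfig(rotation_deg=0.0, scale_range=(1.0, 1.0), shear_deg=0.0,
                          random_crop=False)


class TestConfigValidation:
    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            NetConfig(levels=1)

    def test_channel_contract(self):
        with pytest.raises(ValueError):
            NetConfig(in_channels=1)
        with pytest.raises(ValueError):
            NetConfig(out_classes=2)


class TestBuildAndShapes:
    def test_output_shape_matches_input(self):
        net = build_network(NetConfig(levels=5, base_channels=4, seed=0))
        x = np.random.default_rng(0).random((1, 2, 256, 256), dtype=np.float32)
        logits = net.forward(x)
        assert logits.shape == (1, 3, 256, 256)

    def test_wrong_channel_count_rejected(self):
        net = _tiny_net()
        with pytest.raises(ValueError, match="2"):
            net.forward(np.zeros((1, 1, 32, 32), dtype=np.float32))

    def test_indivisible_dimensions_rejected_with_guidance(self):
        net = build_network(NetConfig(levels=5, base_channels=4))
        with pytest.raises(ValueError, match="divisible"):
            net.forward(np.zeros((1, 2, 100, 100), dtype=np.float32))

    def test_seeded_initialization_identical(self):
        a, b = _tiny_net(seed=7), _tiny_net(seed=7)
        for name in a.params:
            np.testing.assert_array_equal(a.params[name], b.params[name])

    def test_different_seeds_differ(self):
        a, b = _tiny_net(seed=1), _tiny_net(seed=2)
        assert any(
            not np.array_equal(a.params[n], b.params[n]) for n in a.params
        )


class TestPredict:
    def test_probabilities_normalized(self):
        net = _tiny_net()
        pair = _tiny_samples(1)[0][0]
        probs = predict(net, pair)
        assert probs.probs.shape == (3, *pair.shape)
        np.testing.assert_allclose(probs.probs.sum(axis=0), 1.0, atol=1e-5)
        assert probs.probs.min() >= 0 and probs.probs.max() <= 1

    def test_deterministic_inference(self):
        net = _tiny_net()
        pair = _tiny_samples(1)[0][0]
        np.testing.assert_array_equal(predict(net, pair).probs, predict(net, pair).probs)


class TestTraining:
    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train(_tiny_net(), [], TrainConfig(epochs=1))

    def test_mask_image_mismatch_rejected(self):
        (pair, _masks) = _tiny_samples(1)[0]
        other = generate_sample(desk_phantom_spec(5, image_size=64, n_cells=1,
                                                  cell_radius_range=(4, 7)))
        with pytest.raises(ValueError, match="mismatch"):
            train(_tiny_net(), [(pair, other.masks)], TrainConfig(epochs=1))

    def test_deterministic_loss_history(self):
        samples = _tiny_samples(2)
        cfg = TrainConfig(batch_size=2, epochs=2, augment=_FAST_AUG, seed=3)
        h1 = train(_tiny_net(seed=4), samples, cfg)
        h2 = train(_tiny_net(seed=4), samples, cfg)
        assert h1 == h2

    def test_single_sample_memorization(self):
        samples = _tiny_samples(1, size=64)
        cfg = TrainConfig(batch_size=1, epochs=60, learning_rate=3e-3,
                          augment=_FAST_AUG, seed=0)
        history = train(_tiny_net(), samples, cfg)
        assert history[-1] < 0.05

    def test_desk_scale_loss_decreases(self, desk_training):
        history = desk_training["history"]
        assert history[-1] < history[0]

    def test_checkpoint_round_trip(self, tmp_path):
        net = _tiny_net(seed=9)
        path = tmp_path / "model.npz"
        net.save(path)
        loaded = UNet.load(path)
        assert loaded.cfg == net.cfg
        for name in net.params:
            np.testing.assert_array_equal(loaded.params[name], net.params[name])


class TestAugmentation:
    def test_identity_chain_preserves_sample(self, rng):
        img = rng.random((2, 32, 32)).astype(np.float32)
        lab = rng.integers(0, 3, size=(32, 32))
        acfg = AugmentConfig(flips=False, rotation_deg=0.0, scale_range=(1.0, 1.0),
                             shear_deg=0.0, random_crop=False)
        out_img, out_lab = augment_sample(img, lab, acfg, rng)
        np.testing.assert_array_equal(out_img, img)
        np.testing.assert_array_equal(out_lab, lab)

    def test_labels_stay_categorical_under_warping(self, rng):
        img = rng.random((2, 64, 64)).astype(np.float32)
        lab = np.zeros((64, 64), dtype=np.int64)
        lab[20:40, 20:40] = 2
        acfg = AugmentConfig(rotation_deg=45.0, scale_range=(0.8, 1.2),
                             shear_deg=10.0, elastic=True, random_crop=False)
        _, out_lab = augment_sample(img, lab, acfg, rng)
        assert set(np.unique(out_lab)).issubset({0, 2})

    def test_random_crop_size(self, rng):
        img = rng.random((2, 64, 64)).astype(np.float32)
        lab = rng.integers(0, 3, size=(64, 64))
        out_img, out_lab = augment_sample(
            img, lab, AugmentConfig(flips=False, rotation_deg=0.0,
                                    scale_range=(1.0, 1.0), shear_deg=0.0),
            rng, crop_size=32,
        )
        assert out_img.shape == (2, 32, 32) and out_lab.shape == (32, 32)
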