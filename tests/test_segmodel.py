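import numpy as np
import pytest

from boxseg3d import (
    VolumeImage,
    NetworkConfig,
    TrainConfig,
    LossSpec,
    ClassWeights,
    build_network,
    lr_at_step,
    train_model,
    predict_mask,
    PhantomSpec,
    generate_phantom,
    clip_and_normalize,
    dsc,
)
from boxseg3d.segmodel import _loss_and_dlogits


SMALL = NetworkConfig(depth=2, base_channels=4, in_shape=(16, 16, 16))


class TestConfigs:
    def test_indivisible_shape_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(depth=3, in_shape=(18, 16, 16))

    def test_train_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(lr_init=0.0)
        with pytest.raises(ValueError):
            TrainConfig(decay_rate=1.5)
        with pytest.raises(ValueError):
            TrainConfig(optimizer="sgd")


class TestNetwork:
    def test_forward_shape_and_finiteness(self):
        model = build_network(SMALL, seed=0)
        out = model.forward(np.zeros((16, 16, 16), dtype=np.float32))
        assert out.shape == (2, 16, 16, 16)
        assert np.isfinite(out).all()

    def test_seeded_init_deterministic(self):
        a = build_network(SMALL, seed=5)
        b = build_network(SMALL, seed=5)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])
        c = build_network(SMALL, seed=6)
        assert any(not np.array_equal(a.params[k], c.params[k]) for k in a.params)

    def test_cpu_forward_under_one_second(self):
        import time

        model = build_network(NetworkConfig(depth=2, base_channels=4, in_shape=(32, 32, 32)))
        x = np.zeros((32, 32, 32), dtype=np.float32)
        model.forward(x)  # warm-up
        t0 = time.perf_counter()
        model.forward(x)
        assert time.perf_counter() - t0 < 1.0

    def test_gradients_match_finite_differences(self, rng):
        """Analytic VWCE gradient agrees with central differences on a tiny net."""
        cfg = NetworkConfig(depth=2, base_channels=2, in_shape=(4, 4, 4))
        model = build_network(cfg, seed=1)
        x = rng.random((4, 4, 4)).astype(np.float32)
        target = (rng.random((4, 4, 4)) > 0.5).astype(np.uint8)
        vmap = rng.integers(1, 4, size=(4, 4, 4))
        spec = LossSpec(kind="vwce", class_weights=ClassWeights(), weight_maps=[vmap])

        logits, cache = model.forward(x, want_cache=True)
        loss, dlogits = _loss_and_dlogits(logits, target, spec, vmap)
        grads = model.backward(cache, dlogits)

        for name in ("out_W", "enc0a_W", "dec0b_b"):
            p = model.params[name]
            idx = tuple(0 for _ in p.shape)
            eps = 1e-3
            for sign in (+1, -1):
                p[idx] += sign * eps
                l = _loss_and_dlogits(model.forward(x), target, spec, vmap)[0]
                p[idx] -= sign * eps
                if sign > 0:
                    l_plus = l
                else:
                    l_minus = l
            fd = (l_plus - l_minus) / (2 * eps)
            assert grads[name][idx] == pytest.approx(fd, rel=0.05, abs=1e-2)

    def test_gradient_nonvanishing_for_imperfect_prediction(self, rng):
        """VWCE gradients do not vanish when v >= 1 and the prediction is off."""
        cfg = NetworkConfig(depth=2, base_channels=2, in_shape=(4, 4, 4))
        model = build_network(cfg, seed=2)
        x = rng.random((4, 4, 4)).astype(np.float32)
        target = np.ones((4, 4, 4), dtype=np.uint8)
        vmap = np.full((4, 4, 4), 2, dtype=np.int64)
        spec = LossSpec(kind="vwce", class_weights=ClassWeights(), weight_maps=[vmap])
        logits, cache = model.forward(x, want_cache=True)
        _, dlogits = _loss_and_dlogits(logits, target, spec, vmap)
        assert np.abs(dlogits).max() > 0


class TestLearningRate:
    def test_step_zero_is_lr_init(self):
        cfg = TrainConfig(lr_init=0.01, decay_rate=0.9, decay_steps=10)
        assert lr_at_step(cfg, 0) == 0.01

    def test_no_decay(self):
        cfg = TrainConfig(lr_init=0.01, decay_rate=1.0, decay_steps=5)
        assert lr_at_step(cfg, 1000) == 0.01

    def test_hand_value(self):
        cfg = TrainConfig(lr_init=0.001, decay_rate=0.5, decay_steps=100)
        assert lr_at_step(cfg, 200) == pytest.approx(0.00025, rel=1e-12)


class TestTraining:
    def test_empty_sample_list_rejected(self):
        with pytest.raises(ValueError):
            train_model([], LossSpec(), SMALL, TrainConfig())

    def test_loss_series_deterministic_under_seed(self):
        phantom = generate_phantom(PhantomSpec(shape=(16, 16, 16), tumor_radius_range=(3, 5), seed=2))
        img = clip_and_normalize(phantom.image)
        samples = [(img, phantom.gt_mask)]
        cfg = NetworkConfig(depth=2, base_channels=4, in_shape=(16, 16, 16))
        tcfg = TrainConfig(epochs=3, batch_size=1, seed=9)
        _, h1 = train_model(samples, LossSpec(kind="wce"), cfg, tcfg)
        _, h2 = train_model(samples, LossSpec(kind="wce"), cfg, tcfg)
        assert h1 == h2
        assert np.isfinite(h1).all()

    def test_overfit_single_phantom(self):
        """Training loss halves and the phantom is re-segmented at DSC >= 0.9."""
        phantom = generate_phantom(
            PhantomSpec(shape=(24, 24, 24), tumor_radius_range=(5, 7), seed=8)
        )
        img = clip_and_normalize(phantom.image)
        samples = [(img, phantom.gt_mask)]
        cfg = NetworkConfig(depth=2, base_channels=8, in_shape=(24, 24, 24))
        tcfg = TrainConfig(epochs=200, batch_size=1, seed=3, lr_init=3e-3)
        model, hist = train_model(samples, LossSpec(kind="wce"), cfg, tcfg)
        assert hist[-1] < 0.5 * hist[0]
        pred = predict_mask(model, img)
        assert dsc(pred, phantom.gt_mask) >= 0.90


class TestPrediction:
    def test_threshold_extremes_and_shape(self, rng):
        model = build_network(SMALL, seed=0)
        img = VolumeImage(rng.random((16, 16, 16)))
        assert predict_mask(model, img, threshold=1.0).sum() == 0
        assert predict_mask(model, img, threshold=0.0).sum() == 16**3
        assert predict_mask(model, img).shape == (16, 16, 16)

    def test_incompatible_shape_rejected(self, rng):
        model = build_network(NetworkConfig(depth=3, base_channels=4, in_shape=(16, 16, 16)))
        with pytest.raises(ValueError):
            model.forward(rng.random((10, 10, 10)).astype(np.float32))
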