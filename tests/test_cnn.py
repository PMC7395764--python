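"""Architecture plan, schedule, and training/prediction behavior of the
convolutional trait regressor."""

import dataclasses

import numpy as np
import pytest

from canopytraits.cnn import (CNNConfig, CNNTraitModel, CNNTraitResults,
                              TrainConfig, layer_shape_plan, learning_rate)
from canopytraits.exceptions import (ConfigurationError, DomainError,
                                     PipelineError)
from canopytraits.pipeline import benchmark_cnn_config

EXPECTED_PLAN = [
    ("input", 128, 3),
    ("conv1", 124, 32), ("pool1", 62, 32),
    ("conv2", 60, 64), ("pool2", 30, 64),
    ("conv3", 28, 128), ("pool3", 14, 128),
    ("conv4", 10, 216), ("pool4", 5, 216),
    ("conv5", 1, 512), ("fc", 1, 3),
]


class TestShapePlan:
    def test_default_plan(self):
        """Padding conv2/3 only is the unique plan keeping all pooled sides
        integral: 128-124-62-60-30-28-14-10-5-1."""
        assert layer_shape_plan(CNNConfig()) == EXPECTED_PLAN

    def test_unpadded_config_rejected_at_odd_pool(self):
        with pytest.raises(ConfigurationError, match="pool"):
            layer_shape_plan(CNNConfig(padded_layers=frozenset()))

    def test_small_input_rejected_at_conv(self):
        with pytest.raises(ConfigurationError, match="conv5"):
            layer_shape_plan(CNNConfig(input_side=64))

    def test_plan_matches_forward_pass_shape(self):
        cfg = benchmark_cnn_config()
        plan = layer_shape_plan(cfg)
        assert plan[-1] == ("fc", 1, 3)
        x = np.zeros((2, 128, 128, 3), dtype=np.uint8)
        y = np.zeros((2, 3))
        res = CNNTraitModel(x, y, config=cfg).fit(
            TrainConfig(max_epochs=1, batch_size=2, rng_seed=0))
        assert res.predict(x).shape == (2, 3)

    def test_bad_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            CNNConfig(conv_channels=(8, 16))
        with pytest.raises(ConfigurationError):
            CNNConfig(dropout_rate=1.0)


class TestSchedule:
    def test_printed_schedule_values(self):
        tc = TrainConfig()
        assert learning_rate(0, tc) == pytest.approx(1e-3)
        assert learning_rate(19, tc) == pytest.approx(1e-3)
        assert learning_rate(20, tc) == pytest.approx(1e-4)
        assert learning_rate(45, tc) == pytest.approx(1e-5)

    def test_schedule_law_over_full_run(self):
        tc = TrainConfig()
        for epoch in range(301):
            assert learning_rate(epoch, tc) == pytest.approx(
                1e-3 * 0.1 ** (epoch // 20))


@pytest.fixture(scope="module")
def tiny_fit(cultivars):
    """A 2-epoch fit on a handful of scenes: enough to exercise the whole
    train/predict/save path without real convergence."""
    import dataclasses as dc

    from canopytraits.dataset import center_crop_resize
    from canopytraits.synthdata import SceneSpec, render_plant

    images, targets = [], []
    for i in range(8):
        s = render_plant(cultivars[i % 3], (i % 7) + 1,
                         SceneSpec(rng_seed=100 + i))
        images.append(center_crop_resize(s.rgb, None, 128))
        targets.append(s.traits.as_array())
    x = np.stack(images)
    y = np.stack(targets)
    model = CNNTraitModel(x, y, config=benchmark_cnn_config())
    res = model.fit(TrainConfig(max_epochs=2, batch_size=8, rng_seed=3))
    return x, y, res


class TestTrainPredict:
    def test_history_records_schedule_and_losses(self, tiny_fit):
        _, _, res = tiny_fit
        h = res.history
        assert list(h.columns) == ["epoch", "lr", "train_loss", "val_loss"]
        assert len(h) == 2
        assert np.isfinite(h[["train_loss", "val_loss"]].to_numpy()).all()

    def test_fit_deterministic_per_seed(self, tiny_fit):
        x, y, res = tiny_fit
        res2 = CNNTraitModel(x, y, config=benchmark_cnn_config()).fit(
            TrainConfig(max_epochs=2, batch_size=8, rng_seed=3))
        assert res.weights_hash() == res2.weights_hash()
        assert np.allclose(res.predict(x), res2.predict(x))

    def test_prediction_is_stateless_and_order_equivariant(self, tiny_fit):
        x, _, res = tiny_fit
        p = res.predict(x)
        perm = np.array([3, 1, 0, 2, 7, 6, 5, 4])
        assert np.allclose(res.predict(x[perm]), p[perm])
        # batch vs one-by-one
        singles = np.concatenate([res.predict(x[i:i + 1]) for i in range(4)])
        assert np.allclose(singles, p[:4], rtol=1e-5, atol=1e-4)

    def test_predictions_nonnegative(self, tiny_fit):
        x, _, res = tiny_fit
        assert (res.predict(x) >= 0).all()

    def test_wrong_image_size_rejected(self, tiny_fit):
        _, _, res = tiny_fit
        with pytest.raises(DomainError):
            res.predict(np.zeros((1, 64, 64, 3), dtype=np.uint8))

    def test_save_load_roundtrip(self, tiny_fit, tmp_path):
        x, _, res = tiny_fit
        path = tmp_path / "ckpt.npz"
        res.save(path)
        loaded = CNNTraitResults.load(path)
        assert loaded.weights_hash() == res.weights_hash()
        assert np.allclose(loaded.predict(x), res.predict(x))

    def test_batch_larger_than_dataset_warns(self, tiny_fit):
        x, y, _ = tiny_fit
        with pytest.warns(UserWarning, match="clipping"):
            CNNTraitModel(x[:4], y[:4], config=benchmark_cnn_config()).fit(
                TrainConfig(max_epochs=1, batch_size=99, rng_seed=0))

    def test_diverging_run_aborts_with_diagnostic(self, tiny_fit):
        x, y, _ = tiny_fit
        with pytest.raises(PipelineError, match="loss"):
            CNNTraitModel(x, y * 1e6, config=benchmark_cnn_config()).fit(
                TrainConfig(lr0=1e9, max_epochs=10, batch_size=8, rng_seed=0,
                            target_scaling="none"))


def test_constant_input_prediction_invariant_to_rotation(tiny_fit):
    """With average pooling, a constant image and its 90-degree rotation are
    the same input, so predictions must agree exactly."""
    _, _, res = tiny_fit
    const = np.full((1, 128, 128, 3), 77, dtype=np.uint8)
    rot = np.rot90(const[0]).copy()[None]
    assert np.allclose(res.predict(const), res.predict(rot))
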