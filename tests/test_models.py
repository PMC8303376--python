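"""Architecture construction, training mechanics, and checkpointing."""

import numpy as np
import pytest

from cranioflow import _nn
from cranioflow.models import (
    BackboneAdapter,
    ConfigurationError,
    CranioNetSpec,
    RandomFrozenBackbone,
    TrainConfig,
    build_cranionet,
    build_transfer_model,
    load_model,
    save_model,
    spatial_trace,
    train,
)
from cranioflow.labelspace import LabelVector

TINY_SPEC = CranioNetSpec(input_size=32, filters=(4,), hidden=8)


def _tiny_items(n=4, seed=0, size=32):
    rng = np.random.default_rng(seed)
    img = rng.integers(0, 256, size=(size, size, 3), dtype=np.uint8)
    label = LabelVector.from_labels({"Motor", "Environment"})
    return [(img, label)] * n


class TestCranioNet:
    def test_forward_shape_and_sigmoid_range(self, rng):
        model = build_cranionet(TINY_SPEC, seed=1)
        x = rng.uniform(size=(5, 32, 32, 3)).astype(np.float32)
        out = model.predict(x)
        assert out.shape == (5, 10)
        assert np.all(out > 0) and np.all(out < 1)

    def test_default_spatial_trace_matches_convolution_arithmetic(self):
        # independent closed-form oracle: out = (s + 2p - k)//stride + 1
        def conv(s, p):
            return (s + 2 * p - 3) // 1 + 1

        def pool(s):
            return (s - 3) // 2 + 1

        expected = []
        s = 64
        for block in range(3):
            p = 1 if block == 0 else 0
            s = conv(s, p)
            expected.append(s)
            s = conv(s, p)
            expected.append(s)
            s = pool(s)
            expected.append(s)
        assert expected == [64, 64, 31, 29, 27, 13, 11, 9, 4]
        assert [size for _, size in spatial_trace(CranioNetSpec())] == expected

    def test_spatial_collapse_names_the_stage(self):
        with pytest.raises(ConfigurationError, match="block4"):
            spatial_trace(CranioNetSpec(filters=(8, 16, 32, 64)))

    def test_parameter_count_matches_closed_form(self):
        spec = CranioNetSpec()
        model = build_cranionet(spec, seed=0)
        # layer-by-layer closed forms: conv k*k*cin*cout + cout; BN 2c;
        # dense din*dout + dout; BN1d 2h
        total = 0
        cin = 3
        for cout in spec.filters:
            for _ in range(2):
                total += 9 * cin * cout + cout  # conv
                total += 2 * cout  # batch norm
                cin = cout
        final = spatial_trace(spec)[-1][1]
        total += cin * final * final * spec.hidden + spec.hidden
        total += 2 * spec.hidden
        total += spec.hidden * spec.n_labels + spec.n_labels
        assert model.num_params() == total

    def test_parameter_report_mentions_total(self):
        model = build_cranionet(TINY_SPEC, seed=0)
        assert f"{model.num_params():,d}" in model.parameter_report()


class TestTransferHead:
    class SpatialStub(BackboneAdapter):
        out_channels = 8

        def features(self, x):
            n = x.shape[0]
            return np.full((n, 8, 2, 2), x.mean(), dtype=np.float32)

    class FlatStub(BackboneAdapter):
        out_channels = 8

        def features(self, x):
            return np.zeros((x.shape[0], 8), dtype=np.float32)

    def test_head_adds_exactly_cl_plus_l_parameters(self):
        model = build_transfer_model(self.SpatialStub(), n_labels=10)
        assert model.num_params() == 8 * 10 + 10

    def test_non_spatial_backbone_rejected(self, rng):
        model = build_transfer_model(self.FlatStub(), n_labels=10)
        x = rng.uniform(size=(2, 32, 32, 3)).astype(np.float32)
        with pytest.raises(ConfigurationError, match="spatial"):
            model.predict(x)

    def test_backbone_unchanged_after_training_step(self):
        backbone = RandomFrozenBackbone(channels=(4,), seed=2)
        before = [w.copy() for w in backbone.state()]
        model = build_transfer_model(backbone, seed=2)
        items = _tiny_items(size=16)
        train(model, items, cfg=TrainConfig(epochs=1, batch_size=4, seed=0))
        for b, a in zip(before, backbone.state()):
            np.testing.assert_array_equal(b, a)

    def test_global_average_pool_of_constant_map(self):
        gap = _nn.GlobalAvgPool()
        out = gap.forward(np.full((2, 3, 4, 4), 7.5, dtype=np.float32), train=False)
        np.testing.assert_allclose(out, 7.5)


class TestTraining:
    def test_loss_decreases_on_degenerate_data(self):
        spec = CranioNetSpec(input_size=32, filters=(4,), hidden=8,
                             conv_dropout=0.0, dense_dropout=0.0)
        model = build_cranionet(spec, seed=0)
        cfg = TrainConfig(epochs=5, batch_size=4, l1_weight=0.0,
                          learning_rate=1e-3, seed=0)
        _, history = train(model, _tiny_items(), cfg=cfg)
        losses = history["train_loss"]
        assert all(b < a for a, b in zip(losses, losses[1:]))

    def test_same_seed_reproduces_loss_history(self):
        items = _tiny_items(n=6, seed=1)
        histories = []
        for _ in range(2):
            model = build_cranionet(TINY_SPEC, seed=3)
            _, h = train(model, items, items[:2],
                         cfg=TrainConfig(epochs=2, batch_size=3, seed=3))
            histories.append(h)
        assert histories[0] == histories[1]

    def test_l1_penalty_is_nonnegative_addition(self):
        model = build_cranionet(TINY_SPEC, seed=0)
        pen = _nn.l1_penalty(model.net, 1e-3)
        assert pen > 0
        assert _nn.l1_penalty(model.net, 0.0) == 0.0

    def test_empty_train_set_rejected(self):
        model = build_cranionet(TINY_SPEC, seed=0)
        with pytest.raises(ValueError):
            train(model, [], cfg=TrainConfig(epochs=1))

    def test_validation_loss_recorded_per_epoch(self):
        items = _tiny_items(n=4)
        model = build_cranionet(TINY_SPEC, seed=0)
        _, h = train(model, items, items, cfg=TrainConfig(epochs=3, batch_size=4, seed=0))
        assert len(h["train_loss"]) == len(h["val_loss"]) == 3


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, rng):
        model = build_cranionet(TINY_SPEC, seed=4)
        items = _tiny_items(n=4, seed=2)
        train(model, items, cfg=TrainConfig(epochs=1, batch_size=4, seed=4))
        path = tmp_path / "ckpt"
        save_model(model, path)
        restored = load_model(path)
        x = rng.uniform(size=(3, 32, 32, 3)).astype(np.float32)
        np.testing.assert_allclose(restored.predict(x), model.predict(x), atol=1e-6)
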