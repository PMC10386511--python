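"""Network specs, architecture audit, schedule, prediction contract."""

import numpy as np
import pytest

from groomkit import model, nn


@pytest.fixture(scope="module")
def tiny_fusion():
    spec = model.NetworkSpec(variant="fusion", n_classes=7,
                             width_multiplier=1 / 64)
    return model.build_network(spec, seed=0)


@pytest.fixture(scope="module")
def tiny_baseline():
    spec = model.NetworkSpec(variant="baseline", n_classes=7,
                             width_multiplier=1 / 64)
    return model.build_network(spec, seed=0)


class TestArchitecture:
    def test_baseline_topology(self, tiny_baseline):
        assert tiny_baseline.n_backbone_conv == 8
        assert tiny_baseline.n_max_pools == 5
        assert len(tiny_baseline.fc_layers) == 2
        assert tiny_baseline.branch_conv is None

    def test_baseline_full_width_fc_4096(self):
        spec = model.NetworkSpec(variant="baseline")
        assert spec.fc_units() == 4096
        assert spec.conv_widths() == [64, 128, 256, 256, 512, 512, 512, 512]

    def test_fusion_topology(self, tiny_fusion):
        assert tiny_fusion.n_backbone_conv == 12
        assert tiny_fusion.n_max_pools == 5
        assert tiny_fusion.branch_conv is not None

    def test_fusion_branch_has_exactly_16_kernels(self, tiny_fusion):
        assert tiny_fusion.branch_conv.c_out == 16
        # reduced widths never change the branch width
        spec = model.NetworkSpec(variant="fusion", width_multiplier=0.25)
        assert model.build_network(spec).branch_conv.c_out == 16

    def test_first_pool_spares_time_axis(self, tiny_fusion):
        assert tiny_fusion.pools[0].kernel == (1, 2, 2)
        assert all(p.kernel == (2, 2, 2) for p in tiny_fusion.pools[1:])

    def test_width_reduction_preserves_topology(self):
        full = model.NetworkSpec(variant="fusion")
        small = model.NetworkSpec(variant="fusion", width_multiplier=1 / 32)
        assert len(full.conv_widths()) == len(small.conv_widths()) == 12

    def test_invalid_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            model.NetworkSpec(variant="resnet")


class TestForward:
    def test_probabilities_normalized(self, tiny_fusion, rng):
        stacks = rng.standard_normal((2, 16, 112, 112, 3)).astype(
            np.float32) * 40
        probs = tiny_fusion.predict_proba(stacks)
        assert probs.shape == (2, 7)
        assert probs.sum(axis=1) == pytest.approx(np.ones(2))
        assert np.isfinite(probs).all()

    def test_extreme_inputs_stay_finite(self, tiny_fusion):
        big = np.full((1, 16, 112, 112, 3), 127.0, np.float32)
        probs = tiny_fusion.predict_proba(big)
        assert np.isfinite(probs).all()

    def test_predict_ties_break_to_lowest_index(self, tiny_fusion,
                                                monkeypatch):
        stack = np.zeros((16, 112, 112, 3), np.float32)
        monkeypatch.setattr(
            tiny_fusion, "predict_proba",
            lambda s, batch_size=8: np.full((1, 7), 1 / 7))
        label, probs = model.predict(tiny_fusion, stack)
        assert label == 0
        assert probs.sum() == pytest.approx(1.0)

    def test_predict_rejects_batched_input(self, tiny_fusion):
        with pytest.raises(ValueError):
            model.predict(tiny_fusion,
                          np.zeros((2, 16, 112, 112, 3), np.float32))


class TestSchedule:
    @pytest.mark.parametrize("epoch,expected", [
        (0, 0.003), (3, 0.003), (4, 0.0003), (7, 0.0003), (8, 0.00003)])
    def test_staircase_decay(self, epoch, expected):
        config = model.TrainConfig()
        assert model.lr_at_epoch(config, epoch) == pytest.approx(expected)

    def test_negative_epoch_rejected(self):
        with pytest.raises(ValueError):
            model.lr_at_epoch(model.TrainConfig(), -1)


class _ArrayDataset:
    """Minimal StackDataset-compatible wrapper over fixed arrays."""

    def __init__(self, X, y):
        self.X, self.y = X, y

    def __len__(self):
        return len(self.X)

    def batches(self, batch_size, train_mode=False, rng=None, shuffle=False):
        order = np.arange(len(self.X))
        if shuffle:
            order = rng.permutation(order)
        for i in range(0, len(order), batch_size):
            idx = order[i:i + batch_size]
            yield self.X[idx], self.y[idx]


def _separable_stacks(rng, n_per_class=6):
    """Trivially separable two-class stacks: bright patch top vs
    bottom."""
    X, y = [], []
    for cls in (0, 1):
        for _ in range(n_per_class):
            s = rng.normal(0, 5, (16, 112, 112, 3)).astype(np.float32)
            if cls == 0:
                s[:, 10:40, 40:70] += 120
            else:
                s[:, 70:100, 40:70] += 120
            X.append(s)
            y.append(cls)
    return np.stack(X), np.array(y)


class TestTraining:
    def test_learns_separable_classes_and_loss_descends(self, rng):
        X, y = _separable_stacks(rng)
        ds = _ArrayDataset(X, y)
        spec = model.NetworkSpec(variant="fusion", n_classes=2,
                                 width_multiplier=1 / 64, dropout=0.0)
        net = model.build_network(spec, seed=4)
        config = model.TrainConfig(epochs=5, learning_rate=0.02,
                                   batch_size=4, decay_every=5, seed=4)
        net, history = model.train(net, ds, ds, config)
        assert len(history) == 5
        assert history.train_loss.iloc[-1] < history.train_loss.iloc[0]
        assert history.test_acc.max() > 0.9

    def test_same_seed_reproduces_history(self, rng):
        X, y = _separable_stacks(rng, n_per_class=3)
        ds = _ArrayDataset(X, y)
        spec = model.NetworkSpec(variant="baseline", n_classes=2,
                                 width_multiplier=1 / 64)
        histories = []
        for _ in range(2):
            net = model.build_network(spec, seed=9)
            config = model.TrainConfig(epochs=2, learning_rate=0.01,
                                       batch_size=4, seed=9)
            _, h = model.train(net, ds, ds, config)
            histories.append(h)
        assert histories[0].equals(histories[1])

    def test_empty_dataset_rejected(self):
        empty = _ArrayDataset(np.zeros((0, 16, 112, 112, 3), np.float32),
                              np.zeros(0, int))
        spec = model.NetworkSpec(variant="baseline", n_classes=2,
                                 width_multiplier=1 / 64)
        net = model.build_network(spec)
        with pytest.raises(ValueError):
            model.train(net, empty, empty, model.TrainConfig())


class TestCalibrateInit:
    def test_unit_variance_after_calibration(self, rng):
        spec = model.NetworkSpec(variant="fusion", n_classes=4,
                                 width_multiplier=1 / 32)
        net = model.build_network(spec, seed=3)
        stacks = rng.normal(0, 40, (8, 16, 112, 112, 3)).astype(np.float32)
        net = model.calibrate_init(net, stacks)
        # re-trace the forward pass and audit per-layer output stds
        x = np.ascontiguousarray(stacks.transpose(0, 4, 1, 2, 3))
        x = x * spec.input_scale
        for bi, block in enumerate(net.conv_blocks):
            for conv, relu in zip(block, net._relus[bi]):
                x = relu.forward(conv.forward(x), False)
                assert x.std() == pytest.approx(1.0, rel=0.1)
            x = net.pools[bi].forward(x)
        probs = net.predict_proba(stacks[:2])
        assert np.isfinite(probs).all()

    def test_calibration_deterministic(self, rng):
        stacks = rng.normal(0, 40, (4, 16, 112, 112, 3)).astype(np.float32)
        nets = []
        for _ in range(2):
            spec = model.NetworkSpec(variant="baseline", n_classes=4,
                                     width_multiplier=1 / 64)
            nets.append(model.calibrate_init(
                model.build_network(spec, seed=5), stacks))
        for a, b in zip(nets[0].state(), nets[1].state()):
            assert np.array_equal(a, b)


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, tiny_fusion, rng,
                                             tmp_path):
        stacks = rng.standard_normal((2, 16, 112, 112, 3)).astype(
            np.float32) * 30
        before = tiny_fusion.predict_proba(stacks)
        path = tmp_path / "model.npz"
        model.save_checkpoint(tiny_fusion, path,
                              class_names=["a"] * 7)
        loaded, meta = model.load_checkpoint(path)
        after = loaded.predict_proba(stacks)
        assert np.allclose(before, after)
        assert meta["class_names"] == ["a"] * 7
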