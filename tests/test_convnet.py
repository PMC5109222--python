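import numpy as np
import pytest

from semgimg.convnet import (
    BatchNorm,
    ConvNet,
    ConvNetSpec,
    TrainSpec,
    build,
    lr_for_epoch,
    pretrain_union,
)
from semgimg.convnet.layers import softmax_cross_entropy

SMALL = ConvNetSpec(
    (4, 4, 1), 2, n_filters=8, dense_units=(16,), n_local_layers=1,
    dropout_layers=(),
)


def separable_images(rng, n_per_class=80, shape=(4, 4)):
    """Two classes distinguished by which half of the image is bright."""
    images, labels = [], []
    for label in (0, 1):
        base = np.zeros(shape)
        if label == 0:
            base[:, : shape[1] // 2] = 0.8
        else:
            base[:, shape[1] // 2 :] = 0.8
        x = np.clip(base + 0.05 * rng.standard_normal((n_per_class,) + shape), 0, 1)
        images.append(x)
        labels.append(np.full(n_per_class, label))
    return np.concatenate(images), np.concatenate(labels)


class TestArchitecture:
    def test_probabilities_sum_to_one_for_8_classes(self, rng):
        model = build(ConvNetSpec((4, 4, 1), 8, n_filters=4, dense_units=(8,)), seed=0)
        p = model.predict_proba(rng.random((5, 4, 4)))
        assert p.shape == (5, 8)
        assert np.allclose(p.sum(axis=1), 1.0)

    def test_locally_connected_weight_count_8x16(self):
        from semgimg.convnet.layers import LocallyConnected1x1

        layer = LocallyConnected1x1(64, 64, 8, 16, np.random.default_rng(0))
        assert layer.params["W"].size == 8 * 16 * 64 * 64
        assert layer.params["b"].size == 8 * 16 * 64

    def test_parameter_count_audit_default_arch(self):
        model = build(ConvNetSpec((8, 16, 1), 8), seed=0)
        p = 8 * 16
        expected = (
            2 * 1  # input BN (1 channel)
            + (3 * 3 * 1 * 64 + 64) + 2 * 64      # conv1 + BN
            + (3 * 3 * 64 * 64 + 64) + 2 * 64     # conv2 + BN
            + 2 * (p * 64 * 64 + p * 64 + 2 * 64)  # two locally connected + BN
            + (p * 64 * 512 + 512) + 2 * 512      # fc1 + BN
            + (512 * 512 + 512) + 2 * 512         # fc2 + BN
            + (512 * 128 + 128) + 2 * 128         # fc3 + BN
            + (128 * 8 + 8)                       # output
        )
        assert model.n_parameters == expected

    def test_eight_hidden_layers_by_default(self):
        spec = ConvNetSpec((8, 16, 1), 8)
        assert spec.n_hidden_layers == 7  # + G-way output = 8 layers

    def test_tuning_baseline_variant_removes_local_layers(self):
        full = build(ConvNetSpec((8, 16, 1), 8), seed=0)
        reduced = build(ConvNetSpec((8, 16, 1), 8, n_local_layers=0), seed=0)
        diff = 2 * (8 * 16 * 64 * 64 + 8 * 16 * 64 + 2 * 64)
        assert full.n_parameters - reduced.n_parameters == diff

    def test_1x10_input_supported(self, rng):
        model = build(ConvNetSpec((1, 10, 1), 3, n_filters=4, dense_units=(8,)), seed=0)
        p = model.predict_proba(rng.random((4, 1, 10)))
        assert p.shape == (4, 3)

    def test_deterministic_forward(self, rng):
        model = build(SMALL, seed=3)
        x = rng.random((6, 4, 4))
        assert np.array_equal(model.predict_proba(x), model.predict_proba(x))

    def test_zeroed_final_layer_gives_uniform(self, rng):
        model = build(ConvNetSpec((4, 4, 1), 5, n_filters=4, dense_units=(8,)), seed=0)
        final = model.layers[-1]
        final.params["W"][...] = 0
        final.params["b"][...] = 0
        p = model.predict_proba(rng.random((3, 4, 4)))
        assert np.allclose(p, 0.2)

    def test_bad_n_classes(self):
        with pytest.raises(ValueError):
            ConvNetSpec((4, 4, 1), 1)

    def test_shape_mismatch(self, rng):
        model = build(SMALL, seed=0)
        with pytest.raises(ValueError):
            model.predict_proba(rng.random((2, 5, 5)))

    def test_batch_prediction_equals_per_image(self, rng):
        model = build(SMALL, seed=0)
        x = rng.random((7, 4, 4))
        batched = model.predict_proba(x)
        single = np.concatenate([model.predict_proba(x[i : i + 1]) for i in range(7)])
        assert np.allclose(batched, single, atol=1e-6)


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        spec = ConvNetSpec(
            (3, 3, 1), 2, n_filters=2, dense_units=(4,), n_local_layers=1,
            dropout_layers=(),
        )
        model = build(spec, seed=0)
        for layer in model.layers:  # float64 for a clean numerical oracle
            for k in layer.params:
                layer.params[k] = layer.params[k].astype(np.float64)
        x = rng.random((8, 1, 3, 3))
        y = rng.integers(0, 2, 8)

        def loss_only():
            return softmax_cross_entropy(model.logits(x, train=True), y)[0]

        loss, dlogits = softmax_cross_entropy(model.logits(x, train=True), y)
        model._backward(dlogits)
        eps = 1e-6
        checked = 0
        for layer in model.layers:
            for name, p in layer.params.items():
                if name not in layer.grads:
                    continue
                flat = p.ravel()
                for idx in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                    orig = flat[idx]
                    flat[idx] = orig + eps
                    up = loss_only()
                    flat[idx] = orig - eps
                    down = loss_only()
                    flat[idx] = orig
                    numeric = (up - down) / (2 * eps)
                    analytic = layer.grads[name].ravel()[idx]
                    assert analytic == pytest.approx(numeric, rel=5e-3, abs=1e-6)
                    checked += 1
        assert checked >= 20


class TestTraining:
    def test_lr_schedule(self):
        spec = TrainSpec()
        assert lr_for_epoch(spec, 16) == pytest.approx(0.1)
        assert lr_for_epoch(spec, 17) == pytest.approx(0.01)
        assert lr_for_epoch(spec, 24) == pytest.approx(0.01)
        assert lr_for_epoch(spec, 25) == pytest.approx(0.001)

    def test_separable_problem_reaches_full_training_accuracy(self, rng):
        x, y = separable_images(rng)
        model = build(SMALL, seed=0)
        model.fit(x, y, TrainSpec(batch_size=32, epochs=8, lr=0.05, lr_drop_epochs=(6,), seed=0))
        acc = np.mean(model.predict_proba(x).argmax(axis=1) == y)
        assert acc == 1.0

    def test_zero_lr_zero_decay_leaves_weights_unchanged(self, rng):
        x, y = separable_images(rng, n_per_class=16)
        model = build(SMALL, seed=0)
        before = {k: v.copy() for k, v in model.state_arrays().items()}
        model.fit(x, y, TrainSpec(batch_size=16, epochs=1, lr=0.0, weight_decay=0.0, seed=0))
        after = model.state_arrays()
        for k in before:
            if "running" in k:  # BN statistics still track the data
                continue
            assert np.array_equal(before[k], after[k]), k

    def test_loss_trace_reproducible(self, rng):
        x, y = separable_images(rng, n_per_class=24)
        spec = TrainSpec(batch_size=16, epochs=3, seed=5)
        t1 = build(SMALL, seed=5).fit(x, y, spec)
        t2 = build(SMALL, seed=5).fit(x, y, spec)
        assert t1 == t2

    def test_label_out_of_range(self, rng):
        model = build(SMALL, seed=0)
        with pytest.raises(ValueError, match="labels"):
            model.fit(rng.random((4, 4, 4)), np.array([0, 1, 2, 0]), TrainSpec(epochs=1))

    def test_empty_training_set(self):
        model = build(SMALL, seed=0)
        with pytest.raises(ValueError):
            model.fit(np.empty((0, 4, 4)), np.empty(0, dtype=int), TrainSpec(epochs=1))


class TestBatchNormRecalibration:
    def test_only_bn_statistics_change(self, rng):
        x, y = separable_images(rng, n_per_class=24)
        model = build(SMALL, seed=0)
        model.fit(x, y, TrainSpec(batch_size=16, epochs=2, seed=0))
        before = {k: v.copy() for k, v in model.state_arrays().items()}
        model.recalibrate_bn(rng.random((30, 4, 4)))
        after = model.state_arrays()
        for k in before:
            if "running" in k:
                continue
            assert np.array_equal(before[k], after[k]), k
        changed = [k for k in before if "running" in k and not np.array_equal(before[k], after[k])]
        assert changed

    def test_input_bn_mean_is_sample_mean(self, rng):
        model = build(SMALL, seed=0)
        images = rng.random((40, 4, 4))
        model.recalibrate_bn(images)
        input_bn = model.layers[0]
        assert isinstance(input_bn, BatchNorm)
        assert input_bn.running_mean[0] == pytest.approx(images.mean(), abs=1e-5)
        assert input_bn.running_var[0] == pytest.approx(images.var(), rel=1e-4)

    def test_training_set_recalibration_consistent(self, rng):
        x, y = separable_images(rng, n_per_class=48)
        model = build(SMALL, seed=0)
        model.fit(x, y, TrainSpec(batch_size=32, epochs=4, seed=0))
        mean_before = model.layers[0].running_mean.copy()
        model.recalibrate_bn(x)
        assert model.layers[0].running_mean[0] == pytest.approx(
            mean_before[0], abs=0.05
        )

    def test_too_few_images(self, rng):
        model = build(SMALL, seed=0)
        with pytest.raises(ValueError):
            model.recalibrate_bn(rng.random((1, 4, 4)))


class TestPretrainUnion:
    def test_union_of_one_equals_ordinary_training(self, rng):
        x, y = separable_images(rng, n_per_class=24)
        spec = TrainSpec(batch_size=16, epochs=2, seed=9)
        direct = build(SMALL, seed=9)
        direct.fit(x, y, spec)
        united = pretrain_union(build(SMALL, seed=9), [(x, y)], spec)
        for k, v in direct.state_arrays().items():
            assert np.array_equal(v, united.state_arrays()[k]), k

    def test_same_seed_same_initialization(self):
        a = build(SMALL, seed=4)
        b = build(SMALL, seed=4)
        for k, v in a.state_arrays().items():
            assert np.array_equal(v, b.state_arrays()[k])

    def test_empty_union_rejected(self):
        with pytest.raises(ValueError):
            pretrain_union(build(SMALL, seed=0), [])


@pytest.fixture(scope="module")
def hard_benchmark():
    """Moderate-snr synthetic task where classifier ordering is informative."""
    from semgimg.grid import ElectrodeGrid, IntensityMap, image_stack
    from semgimg.synthetic import SyntheticSpec, synthesize
    from semgimg.voting import SplitSpec, split

    grid = ElectrodeGrid(8, 16)
    imap = IntensityMap()
    spec = SyntheticSpec(
        grid=grid, n_gestures=4, trials_per_gesture=10, fs=1000.0,
        duration=0.25, snr=2.0, seed=1,
    )
    train, test = split(synthesize(spec), SplitSpec("odd_even"))[0]
    images = np.concatenate([image_stack(r, grid, imap) for r in train])
    labels = np.concatenate([np.full(r.n_frames, r.gesture) for r in train])
    model = build(ConvNetSpec((8, 16, 1), 4), seed=1)
    model.fit(images, labels, TrainSpec(epochs=6, lr_drop_epochs=(4, 5), seed=1))
    conv_acc = float(np.mean([
        np.mean(model.predict_proba(image_stack(r, grid, imap)).argmax(1) == r.gesture)
        for r in test
    ]))
    return {"train": train, "test": test, "conv_acc": conv_acc}


class TestSyntheticSeparability:
    """With well-separated gesture maps the ConvNet clears 0.9 per frame and
    outperforms every classical baseline at equal training-data volume."""

    def test_single_frame_accuracy_above_090(self, hard_benchmark):
        assert hard_benchmark["conv_acc"] >= 0.9

    @pytest.mark.parametrize("kind", ["mlp", "knn", "svm", "rf", "lda"])
    def test_convnet_exceeds_baseline(self, hard_benchmark, kind):
        from semgimg.baselines import BaselineSpec, fit_baseline, predict_baseline

        train, test = hard_benchmark["train"], hard_benchmark["test"]
        vectors = np.concatenate([r.signals.T for r in train])
        labels = np.concatenate([np.full(r.n_frames, r.gesture) for r in train])
        mlp_spec = TrainSpec(epochs=28, seed=1) if kind == "mlp" else None
        fitted = fit_baseline(
            BaselineSpec(kind, train_downsample_factor=1, seed=1),
            vectors, labels, mlp_spec,
        )
        acc = float(np.mean([
            np.mean(predict_baseline(fitted, r.signals.T).argmax(1) == r.gesture)
            for r in test
        ]))
        assert hard_benchmark["conv_acc"] > acc


class TestPersistence:
    def test_save_load_roundtrip(self, rng, tmp_path):
        x, y = separable_images(rng, n_per_class=16)
        model = build(SMALL, seed=0)
        model.fit(x, y, TrainSpec(batch_size=16, epochs=1, seed=0))
        path = tmp_path / "model.h5"
        model.save(path)
        loaded = ConvNet.load(path)
        assert np.array_equal(model.predict_proba(x), loaded.predict_proba(x))
        assert loaded.spec == model.spec
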