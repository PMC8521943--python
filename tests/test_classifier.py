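import numpy as np
import pytest

from hearkit import nn
from hearkit.classifier import (
    CnnArchitecture,
    SceneCNN,
    TrainingConfig,
    build_model,
    confusion_and_accuracies,
    evaluate,
    repeated_experiment,
    split_dataset,
    train,
)


def small_feature_set(n_classes=6, n_per_class=6, side=16, seed=0):
    """Linearly separable toy features: one bright block per class + noise."""
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for c in range(n_classes):
        for _ in range(n_per_class):
            f = rng.normal(0, 0.1, (side, side))
            f[c : c + 4, c : c + 4] += 2.0
            xs.append(f)
            ys.append(c)
    return np.array(xs, dtype=np.float32), np.array(ys)


class TestArchitecture:
    def test_default_contract(self):
        arch = CnnArchitecture()
        assert arch.conv_filters == (32, 64, 128, 256)
        assert arch.fc1_width == 280
        assert arch.dropout_rate == 0.5
        assert arch.n_classes == 14

    def test_forward_maps_batch_to_14_scores(self):
        model = build_model(input_shape=(64, 80), seed=0)
        out = model.forward(np.zeros((3, 64, 80)), train=False)
        assert out.shape == (3, 14)
        assert np.all(np.isfinite(out))

    def test_parameter_count_matches_layer_arithmetic(self):
        """Recompute the trainable parameter total independently for 64x400 input."""
        counts = []
        ch, h, w = 1, 64, 400
        for f in (32, 64, 128, 256):
            counts.append(f * ch * 9 + f)  # conv weights + bias
            counts.append(2 * f)  # batchnorm gamma + beta
            ch, h, w = f, h // 2, w // 2
        counts.append(ch * h * w * 280 + 280)  # fc1
        counts.append(280 * 14 + 14)  # output layer
        model = build_model(input_shape=(64, 400), seed=0)
        assert model.parameter_count() == sum(counts) == 7_561_014

    def test_input_too_small_for_four_poolings_rejected(self):
        with pytest.raises(ValueError):
            build_model(input_shape=(8, 80))

    def test_softmax_scores_finite_and_normalised(self):
        model = build_model(input_shape=(16, 16), seed=1)
        x = np.random.default_rng(0).standard_normal((5, 16, 16))
        p = nn.softmax(model.forward(x))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_checkpoint_round_trip(self, tmp_path):
        x, y = small_feature_set()
        model = SceneCNN(
            CnnArchitecture(conv_filters=(4, 8), fc1_width=16, n_classes=6), (16, 16), seed=3
        )
        train(model, x, y, TrainingConfig(max_epochs=2, patience=1, seed=0))
        model.save(tmp_path / "ckpt")
        model2 = SceneCNN.load(tmp_path / "ckpt")
        assert np.array_equal(model.predict(x), model2.predict(x))


class TestSplitDataset:
    def test_default_fraction_yields_700_of_1000(self):
        labels = np.repeat(np.arange(10), 100)
        tr, te = split_dataset(labels, seed=0)
        assert len(tr) == 700 and len(te) == 300

    def test_partitions_are_disjoint_and_cover(self):
        labels = np.repeat(np.arange(5), 9)
        tr, te = split_dataset(labels, seed=1)
        assert set(tr).isdisjoint(te)
        assert len(tr) + len(te) == 45

    def test_stratified_per_class(self):
        labels = np.repeat(np.arange(10), 100)
        tr, _ = split_dataset(labels, seed=2)
        _, counts = np.unique(labels[tr], return_counts=True)
        assert np.all(counts == 70)

    def test_deterministic_given_seed(self):
        labels = np.repeat(np.arange(4), 25)
        a = split_dataset(labels, seed=7)
        b = split_dataset(labels, seed=7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        c = split_dataset(labels, seed=8)
        assert not np.array_equal(a[0], c[0])

    def test_class_with_single_record_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(np.array([0, 0, 1]), seed=0)


class _ConstantModel:
    """Stub whose loss never changes: exercises the early-stop rule alone."""

    def __init__(self, n_classes=3):
        self.net = nn.Sequential([])
        self.n = n_classes

    def forward(self, x, train):
        return np.zeros((len(x), self.n))


class _ImprovingModel(_ConstantModel):
    """Stub whose loss strictly decreases every batch (and so every epoch)."""

    def __init__(self, n_classes=3):
        super().__init__(n_classes)
        self.scale = 0.0

    def forward(self, x, train):
        self.scale += 0.05
        onehot = np.eye(self.n)[x[:, 0].astype(int)]
        return self.scale * onehot


class TestTraining:
    def test_constant_loss_stops_after_patience_plus_one_epochs(self):
        x = np.zeros((30, 1))
        y = np.zeros(30, dtype=int)
        history = train(
            _ConstantModel(), x, y, TrainingConfig(max_epochs=250, patience=10, seed=0)
        )
        assert len(history) == 11

    def test_strictly_decreasing_loss_runs_all_epochs(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 3, 30)
        x = y[:, None].astype(float)
        cfg = TrainingConfig(max_epochs=15, patience=5, seed=0)
        history = train(_ImprovingModel(), x, y, cfg)
        assert len(history) == 15
        assert all(b < a for a, b in zip(history, history[1:]))

    def test_identical_seeds_give_identical_histories(self):
        x, y = small_feature_set()
        arch = CnnArchitecture(conv_filters=(4, 8), fc1_width=16, n_classes=6)
        cfg = TrainingConfig(max_epochs=3, patience=2, seed=5)
        h1 = train(SceneCNN(arch, (16, 16), seed=9), x, y, cfg)
        h2 = train(SceneCNN(arch, (16, 16), seed=9), x, y, cfg)
        assert h1 == h2

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train(_ConstantModel(), np.zeros((0, 1)), np.zeros(0), TrainingConfig())


class TestEvaluate:
    def test_perfect_predictions_give_identity_confusion(self):
        y = np.repeat(np.arange(4), 5)
        conf, per_class, overall = confusion_and_accuracies(y, y, 4)
        assert overall == 1.0
        assert np.array_equal(conf, np.diag([5, 5, 5, 5]))
        assert np.all(per_class == 1.0)

    def test_constant_predictor_on_balanced_data_scores_chance(self):
        y = np.repeat(np.arange(7), 3)
        pred = np.zeros_like(y)
        _, _, overall = confusion_and_accuracies(y, pred, 7)
        assert overall == pytest.approx(1 / 7)

    def test_tally_matches_independent_counting(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 5, 200)
        pred = rng.integers(0, 5, 200)
        conf, per_class, overall = confusion_and_accuracies(y, pred, 5)
        # independent oracle: plain dict counting
        tally = {}
        for a, b in zip(y, pred):
            tally[(a, b)] = tally.get((a, b), 0) + 1
        for (a, b), c in tally.items():
            assert conf[a, b] == c
        assert conf.sum() == 200
        assert overall == pytest.approx(sum(tally.get((c, c), 0) for c in range(5)) / 200)

    def test_unknown_label_rejected(self):
        model = SceneCNN(
            CnnArchitecture(conv_filters=(4,), fc1_width=8, n_classes=3), (16, 16), seed=0
        )
        with pytest.raises(ValueError):
            evaluate(model, np.zeros((2, 16, 16)), np.array([0, 7]))
        with pytest.raises(ValueError):
            evaluate(model, np.zeros((0, 16, 16)), np.array([], dtype=int))


@pytest.fixture(scope="module")
def toy_report():
    x, y = small_feature_set()
    arch = CnnArchitecture(conv_filters=(4, 8), fc1_width=16, n_classes=6)
    cfg = TrainingConfig(max_epochs=4, patience=3, n_repetitions=3, seed=1)
    return repeated_experiment(x, y, arch=arch, config=cfg)


class TestRepeatedExperiment:
    def test_single_repetition_has_zero_std(self):
        x, y = small_feature_set()
        arch = CnnArchitecture(conv_filters=(4, 8), fc1_width=16, n_classes=6)
        cfg = TrainingConfig(max_epochs=2, patience=1, n_repetitions=1, seed=2)
        report = repeated_experiment(x, y, arch=arch, config=cfg)
        assert np.all(report.confusion_std == 0.0)

    def test_confusion_mean_rows_sum_to_one(self, toy_report):
        assert np.allclose(toy_report.confusion_mean.sum(axis=1), 1.0, atol=1e-6)

    def test_mean_and_std_match_per_run_matrices(self, toy_report):
        runs = toy_report.confusion_runs
        assert runs.shape[0] == 3
        assert np.allclose(toy_report.confusion_mean, runs.mean(axis=0))
        assert np.allclose(toy_report.confusion_std, runs.std(axis=0))

    def test_overall_accuracy_in_unit_interval(self, toy_report):
        assert 0.0 <= toy_report.overall_accuracy <= 1.0
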