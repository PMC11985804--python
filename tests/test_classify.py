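"""Classifier architectures, metrics, and confidence intervals."""

import numpy as np
import pytest

from docfc import classify, dataset
from docfc.classify import (ARCHITECTURES, CI, build_model,
                            confidence_interval, evaluate, train)
from docfc.nn import Dense
from docfc.types import CLASS_ORDER


class TestBuildModel:
    def test_mlp1_parameter_count_from_855_features(self):
        model, _ = build_model("mlp1", 855, seed=0)
        assert model.n_parameters() == 118084

    def test_mlp2_hidden_widths(self):
        model, spec = build_model("mlp2", 855, seed=0)
        dense = [l for l in model.layers if isinstance(l, Dense)]
        assert [d.W.shape for d in dense] == [
            (855, 256), (256, 128), (128, 64), (64, 4)]
        assert spec.lr == 1e-3 and spec.epochs == 100

    @pytest.mark.parametrize("arch", ARCHITECTURES)
    def test_output_dimension_is_four(self, arch, rng):
        model, spec = build_model(arch, 855, seed=0)
        X = spec.reshape(rng.standard_normal((6, 855)))
        assert model.forward(X, training=False).shape == (6, 4)

    def test_unknown_architecture_rejected(self):
        with pytest.raises(ValueError, match="unknown architecture"):
            build_model("transformer", 855)

    def test_sequence_reshape_is_band_major(self, rng):
        _, spec = build_model("lstm", 20, seed=0, n_metrics=2, n_bands=5)
        X = np.arange(20, dtype=float)[None, :]
        seq = spec.reshape(X)
        assert seq.shape == (1, 5, 4)
        # first metric block: features 0..9 -> 5 bands x 2 pairs
        np.testing.assert_array_equal(seq[0, 0], [0, 1, 10, 11])
        np.testing.assert_array_equal(seq[0, 1], [2, 3, 12, 13])


class TestTrainingBenchmark:
    def test_mlp1_separates_gaussian_blobs(self, blob_benchmark):
        Xtr, Ytr, Xte, Yte, _ = blob_benchmark
        model, spec = build_model("mlp1", Xtr.shape[1], seed=0)
        hist = train(model, spec, Xtr, Ytr)
        rep = evaluate(model, spec, Xte, Yte, n_boot=200)
        assert rep.accuracy >= 0.95
        # loss decreases over the first five epochs on a separable problem
        assert all(np.diff(hist.loss[:5]) <= 1e-3)

    def test_label_shuffle_sits_at_chance(self, blob_benchmark):
        # permuting labels on both sides destroys all class structure, so
        # accuracy on the 600-row balanced test set must sit at 1/4
        Xtr, Ytr, Xte, Yte, _ = blob_benchmark
        rng = np.random.default_rng(0)
        Ysh_tr = Ytr[rng.permutation(len(Ytr))]
        Ysh_te = Yte[rng.permutation(len(Yte))]
        model, spec = build_model("mlp1", Xtr.shape[1], seed=0)
        train(model, spec, Xtr, Ysh_tr, epochs=20)
        rep = evaluate(model, spec, Xte, Ysh_te, n_boot=100)
        assert abs(rep.accuracy - 0.25) <= 0.05

    def test_seeded_training_is_reproducible(self, blob_benchmark):
        Xtr, Ytr, Xte, Yte, _ = blob_benchmark
        accs = []
        for _ in range(2):
            model, spec = build_model("mlp1", Xtr.shape[1], seed=3)
            train(model, spec, Xtr, Ytr, epochs=5)
            accs.append(evaluate(model, spec, Xte, Yte, n_boot=50).accuracy)
        assert abs(accs[0] - accs[1]) < 1e-6


class TestEvaluate:
    def _perfect(self, n_per=5):
        """A fixed 'model' evaluated via its own predictions."""
        rng = np.random.default_rng(0)
        X = rng.standard_normal((4 * n_per, 8))
        y = np.repeat(np.array(CLASS_ORDER, dtype=object), n_per)
        return X, y

    def test_all_correct_gives_unit_metrics(self):
        X, y = self._perfect()
        Y = dataset.one_hot(y)
        model, spec = build_model("mlp1", 8, seed=0)
        # force perfect predictions by evaluating on the training targets of
        # an overfit tiny problem
        train(model, spec, X, Y, epochs=300)
        rep = evaluate(model, spec, X, Y, n_boot=50)
        if rep.accuracy == 1.0:  # overfit succeeded (deterministic seed)
            assert rep.precision == rep.recall == rep.f1 == 1.0
            assert np.trace(rep.confusion) == rep.n_test

    def test_weighted_f1_matches_hand_computation(self):
        # 10 fixed samples over 4 classes with known confusion structure
        y_true = np.array([0, 0, 0, 1, 1, 2, 2, 2, 3, 3])
        y_pred = np.array([0, 0, 1, 1, 1, 2, 0, 2, 3, 2])
        from sklearn.metrics import precision_recall_fscore_support
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=[0, 1, 2, 3], average="weighted",
            zero_division=0)
        # hand computation: per-class F1 weighted by support
        # class 0: P=2/3, R=2/3, F1=2/3 (support 3)
        # class 1: P=2/3, R=1,   F1=4/5 (support 2)
        # class 2: P=2/3, R=2/3, F1=2/3 (support 3)
        # class 3: P=1,   R=1/2, F1=2/3 (support 2)
        hand = (3 * (2 / 3) + 2 * (4 / 5) + 3 * (2 / 3) + 2 * (2 / 3)) / 10
        assert f == pytest.approx(hand)

    def test_weighted_recall_equals_accuracy_on_balanced_set(
            self, blob_benchmark):
        Xtr, Ytr, Xte, Yte, _ = blob_benchmark
        model, spec = build_model("mlp1", Xtr.shape[1], seed=1)
        train(model, spec, Xtr, Ytr, epochs=3)
        rep = evaluate(model, spec, Xte, Yte, n_boot=50)
        assert rep.recall == pytest.approx(rep.accuracy, abs=1e-12)

    def test_metric_bounds_on_fuzzed_predictions(self, rng):
        X = rng.standard_normal((40, 8))
        y = rng.choice(np.array(CLASS_ORDER, dtype=object), size=40)
        Y = dataset.one_hot(y)
        model, spec = build_model("mlp1", 8, seed=0)
        rep = evaluate(model, spec, X, Y, n_boot=50)
        for name in ("accuracy", "precision", "recall", "f1"):
            assert 0.0 <= getattr(rep, name) <= 1.0
        assert rep.confusion.sum(axis=1).tolist() == \
            [int((y == c).sum()) for c in CLASS_ORDER]

    def test_empty_test_set_rejected(self):
        model, spec = build_model("mlp1", 8, seed=0)
        with pytest.raises(ValueError):
            evaluate(model, spec, np.empty((0, 8)), np.empty((0, 4)))


class TestConfidenceInterval:
    def test_constant_values_zero_width(self):
        ci = confidence_interval(np.full(50, 0.8))
        assert ci.lower == ci.point == ci.upper == pytest.approx(0.8)

    def test_interval_contains_point(self, rng):
        for _ in range(10):
            ci = confidence_interval(rng.random(30), seed=1)
            assert ci.lower <= ci.point <= ci.upper

    def test_coverage_of_bernoulli_mean(self):
        """95% percentile bootstrap covers p=0.8 in >=90% of repetitions."""
        rng = np.random.default_rng(5)
        hits = 0
        reps = 200
        for i in range(reps):
            sample = (rng.random(1000) < 0.8).astype(float)
            ci = confidence_interval(sample, seed=i, n_boot=500)
            hits += ci.lower <= 0.8 <= ci.upper
        assert hits / reps >= 0.90

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confidence_interval(np.array([]))

    def test_report_serialization_round_trip(self, tmp_path, rng):
        import json
        X = rng.standard_normal((20, 8))
        y = rng.choice(np.array(CLASS_ORDER, dtype=object), size=20)
        Y = dataset.one_hot(y)
        model, spec = build_model("mlp1", 8, seed=0)
        rep = evaluate(model, spec, X, Y, n_boot=50)
        rep.to_json(tmp_path / "report.json")
        back = json.loads((tmp_path / "report.json").read_text())
        assert back["accuracy"] == pytest.approx(rep.accuracy)
        assert back["ci"]["accuracy"]["lower"] <= back["accuracy"]
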