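"""Multilayer perceptron: activation, normalization, backprop and search."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from keratoscreen.mlp import (
    DivergenceError,
    MLPModel,
    TrainConfig,
    bipolar_sigmoid,
    classify,
    forward,
    hyperparameter_search,
    loss_and_gradients,
    normalize_features,
    percentile_cutoffs,
    train,
)
from keratoscreen.scan import CLASS_ORDER


class TestBipolarSigmoid:
    def test_odd_at_zero(self):
        for sigma in (0.5, 1.0, 2.0):
            assert bipolar_sigmoid(0.0, sigma) == 0.0

    def test_saturation(self):
        assert bipolar_sigmoid(50.0, 1.0) == pytest.approx(1.0, abs=1e-9)
        assert bipolar_sigmoid(-50.0, 1.0) == pytest.approx(-1.0, abs=1e-9)

    def test_hand_value(self):
        # 2/(1+e^-2) - 1 = tanh(1)
        assert bipolar_sigmoid(1.0, 2.0) == pytest.approx(math.tanh(1.0), abs=1e-12)

    @given(st.floats(-20, 20), st.floats(-20, 20))
    def test_strictly_increasing(self, a, b):
        if a == b:
            return
        lo, hi = sorted((a, b))
        assert bipolar_sigmoid(lo, 1.3) < bipolar_sigmoid(hi, 1.3)


class TestNormalization:
    def test_endpoints_and_midpoint(self):
        cutoffs = (np.array([0.0]), np.array([10.0]))
        assert normalize_features(np.array([0.0]), cutoffs)[0] == -1.0
        assert normalize_features(np.array([10.0]), cutoffs)[0] == 1.0
        assert normalize_features(np.array([5.0]), cutoffs)[0] == 0.0

    def test_clipping(self):
        cutoffs = (np.array([0.0]), np.array([1.0]))
        assert normalize_features(np.array([7.0]), cutoffs)[0] == 1.0
        assert normalize_features(np.array([-7.0]), cutoffs)[0] == -1.0

    def test_degenerate_cutoff_raises(self):
        with pytest.raises(ValueError):
            normalize_features(np.array([1.0]), (np.array([2.0]), np.array([2.0])))

    def test_percentile_cutoffs_leave_most_unclipped(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(2000, 4))
        cut = percentile_cutoffs(X)
        Z = normalize_features(X, cut)
        frac_unclipped = np.mean(np.abs(Z) < 1.0)
        assert frac_unclipped >= 0.96


class TestForward:
    def test_zero_network_outputs_zero(self):
        model = MLPModel(
            layer_sizes=(2, 3, 5),
            weights=[np.zeros((2, 3)), np.zeros((3, 5))],
            biases=[np.zeros(3), np.zeros(5)],
            sigma=1.0,
            cutoffs=(np.full(2, -1.0), np.full(2, 1.0)),
        )
        assert np.all(forward(model, np.array([0.3, -0.7])) == 0.0)

    def test_hand_computed_2_2_1(self):
        W1 = np.array([[0.3, -0.2], [0.5, 0.4]])
        b1 = np.array([0.1, -0.1])
        W2 = np.array([[0.7], [-0.6]])
        b2 = np.array([0.2])
        sigma = 1.5
        model = MLPModel(
            layer_sizes=(2, 2, 1),
            weights=[W1, W2],
            biases=[b1, b2],
            sigma=sigma,
            cutoffs=(np.full(2, -1.0), np.full(2, 1.0)),
            class_order=("A",),
        )
        x = np.array([0.4, -0.9])
        h = np.tanh(0.5 * sigma * (x @ W1 + b1))
        want = np.tanh(0.5 * sigma * (h @ W2 + b2))
        assert forward(model, x)[0] == pytest.approx(want[0], abs=1e-12)

    def test_outputs_bounded(self):
        rng = np.random.default_rng(1)
        model = MLPModel(
            layer_sizes=(4, 6, 5),
            weights=[rng.normal(size=(4, 6)) * 3, rng.normal(size=(6, 5)) * 3],
            biases=[rng.normal(size=6), rng.normal(size=5)],
            sigma=2.0,
            cutoffs=(np.full(4, -1.0), np.full(4, 1.0)),
        )
        out = forward(model, rng.uniform(-1, 1, size=(50, 4)))
        assert np.all(np.abs(out) < 1.0)


class TestGradients:
    def test_numerical_gradient_agreement(self):
        rng = np.random.default_rng(42)
        sizes = (3, 4, 2)
        weights = [rng.normal(size=(3, 4)) * 0.5, rng.normal(size=(4, 2)) * 0.5]
        biases = [rng.normal(size=4) * 0.1, rng.normal(size=2) * 0.1]
        X = rng.uniform(-1, 1, size=(7, 3))
        T = np.eye(2)[rng.integers(0, 2, size=7)]
        sigma = 1.3
        loss, gW, gb = loss_and_gradients(weights, biases, sigma, X, T)
        eps = 1e-6
        for l in range(2):
            for idx in np.ndindex(weights[l].shape):
                w0 = weights[l][idx]
                weights[l][idx] = w0 + eps
                lp, *_ = loss_and_gradients(weights, biases, sigma, X, T)
                weights[l][idx] = w0 - eps
                lm, *_ = loss_and_gradients(weights, biases, sigma, X, T)
                weights[l][idx] = w0
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(gW[l][idx], rel=1e-6, abs=1e-10)
            for j in range(biases[l].size):
                b0 = biases[l][j]
                biases[l][j] = b0 + eps
                lp, *_ = loss_and_gradients(weights, biases, sigma, X, T)
                biases[l][j] = b0 - eps
                lm, *_ = loss_and_gradients(weights, biases, sigma, X, T)
                biases[l][j] = b0
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(gb[l][j], rel=1e-6, abs=1e-10)


class TestTraining:
    def test_xor(self):
        X = np.array([[-1, -1], [-1, 1], [1, -1], [1, 1]], dtype=float)
        labels = np.array(["off", "on", "on", "off"])
        cfg = TrainConfig(
            learning_rate=0.5, momentum=0.9, sigma=1.0, hidden_layers=(4,),
            max_epochs=5000, patience=5000, seed=1,
        )
        model = train(X, labels, cfg, class_order=("off", "on"))
        assert model.training_log[-1] < 0.05

    def test_separable_two_class_is_perfect(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(-0.5, 0.1, (30, 3)), rng.normal(0.5, 0.1, (30, 3))])
        labels = np.array(["Normal"] * 30 + ["Kcn"] * 30)
        cfg = TrainConfig(max_epochs=2000, seed=2)
        model = train(X, labels, cfg)
        preds = [classify(model, x)[0] for x in X]
        assert preds == list(labels)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(-1, 1, (40, 4))
        labels = np.array(["Normal", "Kcn"] * 20)
        cfg = TrainConfig(max_epochs=300, seed=11)
        log1 = train(X, labels, cfg).training_log
        log2 = train(X, labels, cfg).training_log
        assert log1 == log2

    def test_mostly_nonincreasing_error(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(-0.4, 0.2, (40, 5)), rng.normal(0.4, 0.2, (40, 5))])
        labels = np.array(["Normal"] * 40 + ["Kcn"] * 40)
        model = train(X, labels, TrainConfig(max_epochs=1000, seed=3))
        log = np.array(model.training_log)
        frac_down = np.mean(np.diff(log) <= 1e-12)
        assert frac_down >= 0.90

    def test_nan_loss_aborts_with_divergence_error(self):
        # bounded tanh outputs keep the MSE finite for any finite input, so
        # the NaN path is exercised with a corrupted feature vector
        rng = np.random.default_rng(9)
        X = rng.uniform(-1, 1, (30, 3))
        X[4, 1] = np.nan
        labels = np.array(["Normal", "Kcn", "Abn"] * 10)
        with pytest.raises(DivergenceError, match="learning_rate"):
            train(X, labels, TrainConfig(max_epochs=100, seed=1))

    def test_single_class_rejected(self):
        X = np.zeros((10, 3))
        with pytest.raises(ValueError):
            train(X, np.array(["Normal"] * 10), TrainConfig())


class TestClassify:
    def _fixed_output_model(self, outputs):
        # linear-ish model forced by biases only (weights zero, input ignored)
        out = np.asarray(outputs, dtype=float)
        pre = np.arctanh(out) / 0.5  # sigma = 1 -> y = tanh(0.5 x)
        return MLPModel(
            layer_sizes=(19, len(out)),
            weights=[np.zeros((19, len(out)))],
            biases=[pre],
            sigma=1.0,
            cutoffs=(np.full(19, -1.0), np.full(19, 1.0)),
        )

    def test_argmax_in_class_order(self):
        model = self._fixed_output_model([0.1, 0.9, -0.2, 0.0, 0.3])
        cls, out = classify(model, np.zeros(19))
        assert cls == "Kcn"
        assert out[1] == pytest.approx(0.9, abs=1e-9)

    def test_tie_break_first_class(self):
        model = self._fixed_output_model([0.5, 0.5, 0.0, 0.0, 0.0])
        cls, _ = classify(model, np.zeros(19))
        assert cls == CLASS_ORDER[0]


class TestHyperparameterSearch:
    def _data(self):
        rng = np.random.default_rng(21)
        X = np.vstack([rng.normal(-0.5, 0.15, (40, 4)), rng.normal(0.5, 0.15, (40, 4))])
        y = np.array(["Normal"] * 40 + ["Kcn"] * 40)
        sel = rng.permutation(80)
        return (X[sel[:56]], y[sel[:56]]), (X[sel[56:]], y[sel[56:]])

    def test_single_config_returned(self):
        tr, te = self._data()
        cfg = TrainConfig(max_epochs=500, seed=4)
        model, report = hyperparameter_search(tr, te, [cfg])
        assert len(report) == 1
        assert model.sigma == cfg.sigma

    def test_runaway_learning_rate_loses_to_good_config(self):
        tr, te = self._data()
        good = TrainConfig(max_epochs=500, seed=4)
        bad = TrainConfig(learning_rate=1e4, max_epochs=500, seed=4)
        model, report = hyperparameter_search(tr, te, [bad, good])
        assert len(report) == 2
        f1 = report.set_index("config")["macro_f1"]
        assert f1[1] > f1[0]  # the sane config wins on test macro-F1
        assert model.training_log[-1] < 0.5

    def test_report_covers_grid(self):
        tr, te = self._data()
        grid = [TrainConfig(max_epochs=200, seed=s) for s in range(3)]
        _, report = hyperparameter_search(tr, te, grid)
        assert len(report) == 3
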