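"""Architecture fidelity, network mechanics and the estimator contract."""

import numpy as np
import pytest

import pockethar as ph
from pockethar.model import (
    ArchitectureError,
    ArchitectureSpec,
    ConvSpec,
    DenseSpec,
    DropoutSpec,
    LSTMSpec,
    PoolSpec,
    TrainConfig,
    build_model,
)
from pockethar.nn import softmax


class TestDefaultArchitecture:
    def test_layer_type_counts(self):
        spec = ph.default_architecture()
        assert spec.n_conv == 6
        assert spec.n_pool == 3
        assert spec.n_dropout == 4
        assert spec.n_lstm == 1
        assert spec.n_dense == 4

    def test_conv_filters_and_kernels(self):
        convs = [l for l in ph.default_architecture().layers if isinstance(l, ConvSpec)]
        assert [(c.filters, c.kernel) for c in convs] == [
            (512, 5), (256, 3), (64, 3), (128, 3), (256, 5), (512, 7),
        ]
        assert all(c.activation == "relu" and c.padding == "same" for c in convs)

    def test_lstm_dense_and_dropout_settings(self):
        spec = ph.default_architecture()
        lstm = [l for l in spec.layers if isinstance(l, LSTMSpec)][0]
        assert (lstm.units, lstm.activation) == (512, "tanh")
        denses = [l for l in spec.layers if isinstance(l, DenseSpec)]
        assert [d.units for d in denses] == [100, 28, 64, 6]
        assert denses[-1].activation == "softmax"
        assert all(d.rate == 0.3 for d in spec.layers if isinstance(d, DropoutSpec))
        pools = [l for l in spec.layers if isinstance(l, PoolSpec)]
        assert all(p.kind == "average" and p.size == 3 for p in pools)

    def test_parameter_count_is_stable(self):
        """Regression: total trainable parameters with 4 input features."""
        net = build_model(ph.default_architecture(), 55, 4, seed=0)
        assert net.n_params == 3_715_830
        net2 = build_model(ph.default_architecture(), 195, 4, seed=1)
        assert net2.n_params == 3_715_830  # independent of window length and seed

    def test_desk_spec_scales_conv_and_lstm_only(self):
        desk = ph.desk_architecture()
        convs = [l for l in desk.layers if isinstance(l, ConvSpec)]
        assert [c.filters for c in convs] == [64, 32, 8, 16, 32, 64]
        assert [l.units for l in desk.layers if isinstance(l, LSTMSpec)] == [64]
        assert [d.units for d in desk.layers if isinstance(d, DenseSpec)] == [100, 28, 64, 6]


class TestBuildModel:
    def test_output_is_probability_simplex(self):
        net = build_model(ph.desk_architecture(), 35, 4, seed=0)
        x = np.random.default_rng(0).normal(size=(8, 35, 4)).astype(np.float32)
        probs = softmax(net.forward(x))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs > 0)

    def test_short_windows_still_build(self):
        # ceil-mode pooling keeps any W >= 1 representable (the sweep starts at 5)
        net = build_model(ph.desk_architecture(), 5, 4, seed=0)
        probs = net.predict_proba(np.zeros((2, 5, 4), dtype=np.float32))
        assert probs.shape == (2, 6)

    def test_invalid_input_shapes_rejected(self):
        with pytest.raises(ArchitectureError):
            build_model(ph.desk_architecture(), 0, 4)
        with pytest.raises(ArchitectureError):
            build_model(ph.desk_architecture(), 35, 0)

    def test_non_softmax_final_layer_rejected(self):
        bad = ArchitectureSpec((LSTMSpec(4), DenseSpec(6, "relu")))
        with pytest.raises(ArchitectureError):
            build_model(bad, 10, 3)


def _toy_windows(n=120, W=9, seed=0):
    """Two linearly separable classes: distinct constant offsets."""
    rng = np.random.default_rng(seed)
    y = np.array(["a", "b"])[rng.integers(0, 2, n)]
    X = rng.normal(scale=0.1, size=(n, W, 3)).astype(np.float32)
    X[y == "b"] += 2.0
    return X, y


_TOY_SPEC = ArchitectureSpec(
    (ConvSpec(8, 3), PoolSpec("average", 3), LSTMSpec(8),
     DenseSpec(16, "relu"), DenseSpec(6, "softmax"))
)


class TestEstimator:
    def test_separable_toy_problem_is_learned(self):
        X, y = _toy_windows()
        clf = ph.CNNLSTMClassifier(
            architecture=_TOY_SPEC, epochs=20, batch_size=32,
            learning_rate=0.01, random_state=0,
        ).fit(X, y)
        assert clf.score(X, y) >= 0.95

    def test_history_length_matches_epochs(self):
        X, y = _toy_windows(n=60)
        clf = ph.CNNLSTMClassifier(
            architecture=_TOY_SPEC, epochs=2, batch_size=32, random_state=0
        ).fit(X, y)
        assert list(clf.history_["epoch"]) == [1, 2]
        assert set(clf.history_.columns) == {"epoch", "loss", "holdout_accuracy"}

    def test_training_is_deterministic_under_seed(self):
        X, y = _toy_windows(n=80)
        losses = []
        for _ in range(2):
            clf = ph.CNNLSTMClassifier(
                architecture=_TOY_SPEC, epochs=1, batch_size=32, random_state=3
            ).fit(X, y)
            losses.append(clf.history_["loss"].iloc[0])
        assert abs(losses[0] - losses[1]) < 1e-6

    def test_predict_proba_rows_sum_to_one(self):
        X, y = _toy_windows(n=60)
        clf = ph.CNNLSTMClassifier(
            architecture=_TOY_SPEC, epochs=1, batch_size=32, random_state=0
        ).fit(X, y)
        probs = clf.predict_proba(X[:10])
        assert probs.shape == (10, 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_best_on_holdout_restores_best_weights(self):
        X, y = _toy_windows(n=100)
        clf = ph.CNNLSTMClassifier(
            architecture=_TOY_SPEC, epochs=5, batch_size=32,
            checkpoint_policy="best_on_holdout", random_state=0,
        ).fit(X, y, holdout=(X[:30], y[:30]))
        best = clf.history_["holdout_accuracy"].max()
        assert clf.score(X[:30], y[:30]) == pytest.approx(best, abs=1e-9)

    def test_sklearn_params_roundtrip(self):
        clf = ph.CNNLSTMClassifier(epochs=3)
        params = clf.get_params()
        assert params["epochs"] == 3
        clf.set_params(epochs=7)
        assert clf.get_params()["epochs"] == 7


class TestTrainWrapper:
    def test_missing_class_rejected(self, micro_features):
        ws = ph.segment(micro_features[0], 10)
        mask = ws.labels != "sitting"
        with pytest.raises(ValueError, match="sitting"):
            ph.train(ph.desk_architecture(), ws.subset(mask),
                     TrainConfig(epochs=1, batch_size=64, checkpoint_policy="last"))

    def test_smoke_run_produces_history(self, micro_features):
        ws = ph.segment(micro_features[0], 10)
        cfg = TrainConfig(epochs=2, batch_size=128, checkpoint_policy="last", seed=0)
        clf = ph.train(_TOY_SPEC, ws, cfg)
        assert len(clf.history_) == 2

    def test_train_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(checkpoint_policy="bogus")
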