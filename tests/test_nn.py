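"""Forward pass, gradients, training behaviour and selection protocols."""

import numpy as np
import pytest

from metaloc.core import MetalocError
from metaloc.evaluation import roc
from metaloc.nn import (
    MLPModel,
    TrainConfig,
    bce_loss,
    gradients,
    init_mlp,
    logsig,
    stepwise_select,
    topology_search,
    train,
)


class TestForward:
    def test_zero_weights_give_half(self):
        model = init_mlp(3, (4,), 10, seed=0)
        model.weights = [np.zeros_like(w) for w in model.weights]
        model.biases = [np.zeros_like(b) for b in model.biases]
        out = model.forward(np.zeros((2, 3)))
        assert np.allclose(out, 0.5)

    def test_single_neuron_closed_form(self):
        model = MLPModel(weights=[np.array([[1.0]])] * 1, biases=[np.array([0.0])])
        # single layer, one unit: logsig(2) = 1/(1+e^-2)
        out = model.forward(np.array([[2.0]]))
        assert out[0, 0] == pytest.approx(1 / (1 + np.exp(-2)))

    def test_saturation_no_overflow(self):
        assert logsig(np.array([-1e4]))[0] == 0.0
        assert logsig(np.array([1e4]))[0] == 1.0
        model = init_mlp(1, (), 10, seed=0)
        model.weights[0][:] = -1e3
        out = model.forward(np.array([[1e3]]))
        assert np.all(np.isfinite(out)) and np.all(out >= 0)

    def test_outputs_strictly_inside_unit_interval(self, rng):
        model = init_mlp(5, (7,), 10, seed=3)
        out = model.forward(rng.normal(size=(20, 5)))
        assert np.all((out > 0) & (out < 1))

    def test_dimension_mismatch_errors(self):
        model = init_mlp(4, (5,), 10, seed=0)
        with pytest.raises(MetalocError):
            model.forward(np.zeros((2, 3)))


class TestGradients:
    @pytest.mark.parametrize("hidden", [(), (4,), (5, 3)])
    def test_match_finite_differences(self, hidden, rng):
        """Analytic backprop vs central differences, 1e-6 relative."""
        model = init_mlp(4, hidden, 10, seed=11)
        X = rng.normal(size=(6, 4))
        Y = (rng.random((6, 10)) < 0.3).astype(float)
        gw, gb = gradients(model, X, Y)
        eps = 1e-6
        for layer in range(len(model.weights)):
            w = model.weights[layer]
            for idx in [(0, 0), (w.shape[0] - 1, w.shape[1] - 1)]:
                orig = w[idx]
                w[idx] = orig + eps
                up = bce_loss(model.forward(X), Y)
                w[idx] = orig - eps
                down = bce_loss(model.forward(X), Y)
                w[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert gw[layer][idx] == pytest.approx(numeric, rel=1e-4, abs=1e-8)
            b = model.biases[layer]
            orig = b[0]
            b[0] = orig + eps
            up = bce_loss(model.forward(X), Y)
            b[0] = orig - eps
            down = bce_loss(model.forward(X), Y)
            b[0] = orig
            numeric = (up - down) / (2 * eps)
            assert gb[layer][0] == pytest.approx(numeric, rel=1e-4, abs=1e-8)


class TestTrain:
    def test_zero_epochs_identity(self, rng):
        model = init_mlp(3, (4,), 10, seed=5)
        X, Y = rng.normal(size=(8, 3)), np.zeros((8, 10))
        result = train(model, X, Y, TrainConfig(epochs=0))
        for w0, w1 in zip(model.weights, result.model.weights):
            assert np.array_equal(w0, w1)

    def test_same_seed_same_trajectory(self, rng):
        X = rng.normal(size=(30, 4))
        Y = (rng.random((30, 10)) < 0.2).astype(float)
        r1 = train(init_mlp(4, (5,), 10, seed=9), X, Y, TrainConfig(epochs=50))
        r2 = train(init_mlp(4, (5,), 10, seed=9), X, Y, TrainConfig(epochs=50))
        assert r1.loss_history == r2.loss_history
        for w1, w2 in zip(r1.model.weights, r2.model.weights):
            assert np.array_equal(w1, w2)

    def test_loss_history_non_increasing(self, rng):
        X = rng.normal(size=(40, 3))
        Y = (rng.random((40, 10)) < 0.3).astype(float)
        result = train(init_mlp(3, (5,), 10, seed=2), X, Y, TrainConfig(epochs=100))
        assert all(b <= a + 1e-12 for a, b in zip(result.loss_history, result.loss_history[1:]))

    def test_linearly_separable_toy_learns(self, rng):
        """Margin-separated classes reach near-perfect training AUROC."""
        n = 60
        labels = np.repeat([1.0, 0.0], n // 2)
        X = np.column_stack([labels * 2 - 1, labels * 2 - 1]) + rng.normal(0, 0.1, (n, 2))
        Y = np.tile(labels[:, None], (1, 10))
        result = train(init_mlp(2, (5,), 10, seed=1), X, Y, TrainConfig(epochs=200))
        auc = roc(result.model.forward(X)[:, 0], labels.astype(int)).auroc
        assert auc > 0.99

    def test_label_shuffled_training_chance_level(self, rng):
        """Labels independent of features -> held-out AUROC ~ 0.5."""
        X_train, X_test = rng.normal(size=(300, 6)), rng.normal(size=(300, 6))
        Y_train = (rng.random((300, 10)) < 0.2).astype(float)
        Y_test = (rng.random((300, 10)) < 0.2).astype(float)
        result = train(init_mlp(6, (10,), 10, seed=4), X_train, Y_train,
                       TrainConfig(epochs=150))
        out = result.model.forward(X_test).ravel()
        y = Y_test.ravel().astype(int)
        auc = roc(out, y).auroc
        n_pos = y.sum()
        n_neg = len(y) - n_pos
        se = np.sqrt((n_pos + n_neg + 1) / (12 * n_pos * n_neg))
        assert abs(auc - 0.5) < 3 * se

    def test_serialization_round_trip(self, tmp_path, rng):
        model = init_mlp(4, (5, 3), 10, seed=8)
        path = tmp_path / "model.json"
        model.save(path)
        back = MLPModel.load(path)
        assert back.layer_sizes == model.layer_sizes
        for w0, w1 in zip(model.weights, back.weights):
            assert np.array_equal(w0, w1)
        X = rng.normal(size=(3, 4))
        assert np.array_equal(model.forward(X), back.forward(X))


def _toy_multilabel(rng, n=120, d_signal=2.0):
    """10-location toy set with informative first two feature blocks."""
    Y = np.zeros((n, 10))
    Y[np.arange(n), rng.integers(0, 10, n)] = 1.0
    X = Y + rng.normal(0, 1 / d_signal, size=(n, 10))
    return X, Y


class TestTopologySearch:
    def test_grid_bookkeeping(self, rng):
        X, Y = _toy_multilabel(rng)
        Xt, Yt = _toy_multilabel(rng)
        res = topology_search(
            X, Y, Xt, Yt, structures=((3,), (5,)), repeats=3, seed=0,
            config=TrainConfig(epochs=30),
        )
        assert set(res.grid) == {(3,), (5,)}
        assert all(len(v) == 3 for v in res.grid.values())
        assert all(len(v) == 3 for v in res.best3.values())
        assert res.chosen in res.grid

    def test_best3_are_top_repeats(self, rng):
        X, Y = _toy_multilabel(rng)
        Xt, Yt = _toy_multilabel(rng)
        res = topology_search(
            X, Y, Xt, Yt, structures=((4,),), repeats=5, seed=1,
            config=TrainConfig(epochs=30),
        )
        assert res.best3[(4,)] == sorted(res.grid[(4,)], reverse=True)[:3]

    def test_single_structure_chosen(self, rng):
        X, Y = _toy_multilabel(rng)
        res = topology_search(
            X, Y, X, Y, structures=((6,),), repeats=3, seed=2,
            config=TrainConfig(epochs=20),
        )
        assert res.chosen == (6,)

    def test_too_few_repeats_errors(self, rng):
        X, Y = _toy_multilabel(rng)
        with pytest.raises(MetalocError):
            topology_search(X, Y, X, Y, repeats=2)

    def test_oversized_net_on_tiny_data_overfits(self, rng):
        """Learning power keeps rising with size but held-out prediction
        power peaks: a 15x15 net on 100 rows memorises its training set."""
        X, Y = _toy_multilabel(rng, n=100, d_signal=1.0)
        Xt, Yt = _toy_multilabel(rng, n=300, d_signal=1.0)
        result = train(init_mlp(10, (15, 15), 10, seed=0), X, Y,
                       TrainConfig(epochs=400))
        train_auc = roc(result.model.forward(X).ravel(),
                        Y.ravel().astype(int)).auroc
        test_auc = roc(result.model.forward(Xt).ravel(),
                       Yt.ravel().astype(int)).auroc
        assert train_auc > test_auc


class TestStepwise:
    def test_redundant_duplicate_rejected(self, rng):
        """A predictor identical to one already kept adds nothing."""
        X, Y = _toy_multilabel(rng, n=200)
        Xt, Yt = _toy_multilabel(rng, n=200)

        def builder(names):
            blocks_tr = [X for _ in names]
            blocks_te = [Xt for _ in names]
            return np.concatenate(blocks_tr, axis=1), np.concatenate(blocks_te, axis=1)

        sel = stepwise_select(
            {"orig": 0.9, "clone": 0.8}, builder, Y, Yt,
            hidden=(8,), config=TrainConfig(epochs=60, l2=1e-3), repeats=3, seed=0,
        )
        assert sel.kept == ["orig"]
        assert sel.kept_flags == [True, False]

    def test_single_informative_candidate_kept(self, rng):
        X, Y = _toy_multilabel(rng, n=200)
        Xt, Yt = _toy_multilabel(rng, n=200)
        sel = stepwise_select(
            {"only": 0.8}, lambda names: (X, Xt), Y, Yt,
            hidden=(8,), config=TrainConfig(epochs=60), repeats=3, seed=0,
        )
        assert sel.kept == ["only"]
        assert sel.trajectory[0] > 0.5

    def test_trajectory_records_every_candidate(self, rng):
        X, Y = _toy_multilabel(rng, n=100)
        sel = stepwise_select(
            {"a": 0.9, "b": 0.7}, lambda names: (X, X), Y, Y,
            hidden=(4,), config=TrainConfig(epochs=20), repeats=3, seed=0,
        )
        assert len(sel.trajectory) == 2
        assert sel.candidate_order == ["a", "b"]
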