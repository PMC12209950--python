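"""Training loop, early stopping, scheduler, metrics, grid search, class rules."""

import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support

from moimech.gnn import GNNModel
from moimech.synthdata import PlantedNetworkSpec, make_planted_network
from moimech.trainer import (
    Adam,
    EarlyStopper,
    GraphTaskData,
    NodeTaskData,
    PlateauScheduler,
    PredictionSet,
    TrainConfig,
    assign_moi_class,
    evaluate,
    grid_search,
    train_model,
)


def planted_node_data(seed=1, n=60, **kw):
    pn = make_planted_network(PlantedNetworkSpec(n_nodes=n, seed=seed, **kw))
    g = pn.graph
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    a, b = int(0.8 * n), int(0.9 * n)
    return g, NodeTaskData(g, g.y, idx[:a], idx[a:b], idx[b:])


class TestEarlyStopping:
    def test_handcrafted_loss_sequence_stops_after_patience(self):
        # losses per epoch: improvement at epoch 2 (1-based), then three
        # non-improving epochs exhaust patience 3 at epoch 5
        stopper = EarlyStopper(patience=3)
        losses = [1.0, 0.9, 0.95, 0.96, 0.97]
        stops = [stopper.update(e, l) for e, l in enumerate(losses)]
        assert stops == [False, False, False, False, True]
        assert stopper.best_epoch == 1  # 0-based epoch 2

    def test_training_restores_best_epoch_parameters(self):
        g, data = planted_node_data(seed=2)
        model = GNNModel("gcn", g.X.shape[1], 8, 2, "node", seed=2)
        config = TrainConfig(hidden_size=8, learning_rate=1e-2, max_epochs=40,
                             patience=5, seed=2)
        history = train_model(model, data, config)
        best = history["best_epoch"]
        assert best <= len(history["valid_loss"]) - 1
        assert history["valid_loss"][best] == min(history["valid_loss"])

    def test_empty_validation_set_is_error(self):
        g, data = planted_node_data(seed=2)
        data.valid_idx = np.array([], dtype=int)
        model = GNNModel("gcn", g.X.shape[1], 8, 2, "node", seed=2)
        with pytest.raises(ValueError):
            train_model(model, data, TrainConfig(seed=2))


class TestScheduler:
    def test_lr_multiplied_by_factor_after_plateau(self):
        opt = Adam([], lr=0.01)
        sched = PlateauScheduler(opt, factor=0.5, patience=3)
        sched.step(1.0)  # establishes best
        for _ in range(2):
            sched.step(1.0)
        assert opt.lr == 0.01  # plateau shorter than patience
        sched.step(1.0)
        assert opt.lr == pytest.approx(0.005)

    def test_improvement_resets_plateau_counter(self):
        opt = Adam([], lr=0.01)
        sched = PlateauScheduler(opt, factor=0.5, patience=2)
        sched.step(1.0)
        sched.step(1.1)
        sched.step(0.9)  # improvement
        sched.step(1.0)
        assert opt.lr == 0.01


class TestTraining:
    def test_overfits_tiny_separable_network(self):
        # 20 nodes, strong clean signal: training loss collapses
        g, data = planted_node_data(seed=3, n=20, effect_size=50.0)
        model = GNNModel("gcn", g.X.shape[1], 16, 2, "node", dropout=0.0, seed=3)
        config = TrainConfig(hidden_size=16, learning_rate=5e-2, max_epochs=50,
                             patience=49, seed=3)
        history = train_model(model, data, config)
        assert history["train_loss"][-1] < 0.1 * history["train_loss"][0]

    def test_deterministic_history_under_fixed_seed(self):
        g, data = planted_node_data(seed=4)
        config = TrainConfig(hidden_size=8, learning_rate=1e-2, max_epochs=15,
                             patience=14, seed=4)
        h1 = train_model(GNNModel("gcn", g.X.shape[1], 8, 2, "node", seed=4), data, config)
        h2 = train_model(GNNModel("gcn", g.X.shape[1], 8, 2, "node", seed=4), data, config)
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["valid_loss"] == h2["valid_loss"]

    def test_graph_task_trains(self):
        rng = np.random.default_rng(0)
        from conftest import random_graph
        graphs = []
        for k in range(12):
            g = random_graph(rng, n_max=8, n_feat=3)
            g.y = np.array([k % 2, 1 - k % 2, k % 2])
            graphs.append(g)
        data = GraphTaskData(graphs[:8], graphs[8:])
        model = GNNModel("gcn", 3, 8, 3, "graph", seed=0)
        history = train_model(model, data, TrainConfig(hidden_size=8, learning_rate=1e-2,
                                                       max_epochs=5, patience=4, seed=0))
        assert len(history["train_loss"]) == 5


class TestGridSearch:
    def test_full_grid_yields_25_rows(self):
        g, data = planted_node_data(seed=5, n=30)
        config = TrainConfig(max_epochs=2, patience=1, seed=5)
        _, best, table = grid_search("gcn", data, config, 2)
        assert len(table) == 25
        assert set(zip(table.hidden_size, table.learning_rate)) == {
            (h, lr) for h in config.hidden_sizes for lr in config.learning_rates
        }

    def test_singleton_grid_returns_that_cell(self):
        g, data = planted_node_data(seed=5, n=30)
        config = TrainConfig(hidden_sizes=(8,), learning_rates=(1e-2,),
                             max_epochs=3, patience=2, seed=5)
        _, best, table = grid_search("gcn", data, config, 2)
        assert len(table) == 1
        assert best["hidden_size"] == 8 and best["learning_rate"] == 1e-2

    def test_planted_best_cell_wins(self):
        # one cell gets a workable learning rate, the rest get a vanishing
        # one: the workable cell must win on validation F1
        g, data = planted_node_data(seed=6, n=80)
        config = TrainConfig(hidden_sizes=(16,), learning_rates=(1e-12, 1e-2, 1e-13),
                             max_epochs=30, patience=29, seed=6)
        _, best, table = grid_search("gcn", data, config, 2)
        assert best["learning_rate"] == 1e-2
        assert best["valid_f1"] == table.valid_f1.max()


class TestEvaluate:
    def _pred(self, probs, y):
        probs = np.asarray(probs, dtype=float)
        return PredictionSet([f"s{i}" for i in range(len(probs))], probs,
                             [f"l{k}" for k in range(probs.shape[1])], np.asarray(y))

    def test_perfect_predictions(self):
        p = self._pred([[0.9, 0.1], [0.2, 0.8]], [[1, 0], [0, 1]])
        assert evaluate(p) == {"precision": 1.0, "recall": 1.0, "F1": 1.0}

    def test_everything_wrong(self):
        p = self._pred([[0.9, 0.1], [0.1, 0.9]], [[0, 1], [1, 0]])
        assert evaluate(p) == {"precision": 0.0, "recall": 0.0, "F1": 0.0}

    def test_macro_metrics_match_sklearn_confusion_oracle(self):
        probs = np.array([[0.9, 0.2], [0.4, 0.7], [0.6, 0.6], [0.1, 0.3]])
        y = np.array([[1, 0], [0, 1], [1, 1], [0, 0]])
        p = self._pred(probs, y)
        got = evaluate(p)
        pr, rc, f1, _ = precision_recall_fscore_support(
            y, (probs >= 0.5).astype(int), average="macro", zero_division=1)
        assert got["precision"] == pytest.approx(pr)
        assert got["recall"] == pytest.approx(rc)
        assert got["F1"] == pytest.approx(f1)

    def test_empty_label_scores_one(self):
        p = self._pred([[0.9, 0.1], [0.8, 0.2]], [[1, 0], [1, 0]])
        assert evaluate(p)["F1"] == 1.0  # label 2 has no truth and no calls

    def test_invariant_to_sample_order(self, rng):
        probs = rng.random((20, 3))
        y = (rng.random((20, 3)) < 0.5).astype(int)
        perm = rng.permutation(20)
        assert evaluate(self._pred(probs, y)) == evaluate(self._pred(probs[perm], y[perm]))

    def test_out_of_range_probabilities_rejected(self):
        with pytest.raises(ValueError):
            self._pred([[1.2, 0.0]], [[1, 0]])


class TestMoiClassRule:
    @pytest.mark.parametrize("p_ad,expected", [(0.7, "AD"), (0.5, "ADAR"), (0.3, "AR"),
                                               (0.61, "AD"), (0.4, "ADAR")])
    def test_benchmark_thresholds(self, p_ad, expected):
        assert assign_moi_class(p_ad, rule="benchmark") == expected

    @pytest.mark.parametrize("p_ad,p_ar,expected", [
        (0.9, 0.8, "ADAR"), (0.9, 0.2, "AD"), (0.1, 0.7, "AR"), (0.4, 0.3, "AD"),
        (0.2, 0.45, "AR"),
    ])
    def test_inference_rule(self, p_ad, p_ar, expected):
        assert assign_moi_class(p_ad, p_ar, rule="inference") == expected

    def test_out_of_range_probability_is_error(self):
        with pytest.raises(ValueError):
            assign_moi_class(1.5)
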