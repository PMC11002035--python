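import numpy as np
import pytest

from molgcn import (
    AtomVocabulary,
    TrainConfig,
    encode_graph,
    forward,
    gcn_layer,
    init_params,
    learning_rate_at,
    mse_loss,
    parse_smiles,
    predict_batch,
    train,
)
from molgcn.chem_io import LabeledRecord
from molgcn.gcn_model import batch_loss_and_grads, relu


def brute_force_gcn_layer(H, A_hat, W):
    """Triple-loop evaluation of relu(A_hat @ H @ W)."""
    n, d = H.shape
    AH = np.zeros((n, d))
    for i in range(n):
        for k in range(d):
            AH[i, k] = sum(A_hat[i, j] * H[j, k] for j in range(n))
    out = np.zeros((n, W.shape[1]))
    for i in range(n):
        for k in range(W.shape[1]):
            out[i, k] = max(0.0, sum(AH[i, j] * W[j, k] for j in range(d)))
    return out


class TestConfig:
    def test_defaults_are_published_schedule(self):
        cfg = TrainConfig()
        assert (cfg.radius, cfg.graph_layers, cfg.fc_layers) == (1, 6, 10)
        assert (cfg.batch_size, cfg.iterations, cfg.decay_interval) == (4, 1000, 10)
        assert cfg.learning_rate == pytest.approx(1e-4)
        assert cfg.lr_decay == pytest.approx(0.99)
        assert cfg.train_fraction == pytest.approx(0.7)

    @pytest.mark.parametrize("kwargs", [
        {"batch_size": 0}, {"train_fraction": 1.0}, {"learning_rate": 0.0},
        {"iterations": 0}, {"radius": -1},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TrainConfig(**kwargs)


class TestInitParams:
    def test_seeded_determinism(self):
        cfg = TrainConfig(seed=5)
        a = init_params(7, cfg)
        b = init_params(7, cfg)
        for x, y in zip(a.arrays(), b.arrays()):
            assert np.array_equal(x, y)

    def test_different_seeds_differ(self):
        a = init_params(7, TrainConfig(seed=1))
        b = init_params(7, TrainConfig(seed=2))
        assert not np.array_equal(a.embedding, b.embedding)

    def test_shapes(self):
        cfg = TrainConfig(hidden_dim=50, graph_layers=6, fc_layers=10)
        p = init_params(9, cfg)
        assert p.embedding.shape == (9, 50)
        assert len(p.graph_W) == 6 and all(w.shape == (50, 50) for w in p.graph_W)
        assert len(p.fc_W) == 10 and all(w.shape == (50, 50) for w in p.fc_W)
        assert p.out_W.shape == (50, 2) and p.out_b.shape == (2,)


class TestGcnLayer:
    def test_single_node_identity(self):
        H = np.array([[1.5, -2.0]])
        out = gcn_layer(H, np.array([[1.0]]), np.eye(2), activation=lambda x: x)
        assert out == pytest.approx(H)

    def test_hand_worked_two_node_case(self):
        A_hat = np.full((2, 2), 0.5)
        H = np.diag([2.0, 2.0])
        out = gcn_layer(H, A_hat, np.eye(2), activation=relu)
        assert out == pytest.approx(np.ones((2, 2)))

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(200):
            n, d = int(rng.integers(1, 6)), int(rng.integers(1, 5))
            H = rng.normal(size=(n, d))
            A_hat = rng.normal(size=(n, n))
            W = rng.normal(size=(d, d))
            assert gcn_layer(H, A_hat, W) == pytest.approx(
                brute_force_gcn_layer(H, A_hat, W), abs=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gcn_layer(np.ones((3, 2)), np.ones((2, 2)), np.eye(2))


class TestMseLoss:
    def test_perfect_one_hot_is_zero(self):
        assert mse_loss([[1.0, 0.0], [0.0, 1.0]], [0, 1]) == 0.0

    def test_hand_worked_single_sample(self):
        # label 0: ((0.6-1)^2 + (0.4-0)^2) / 2 = 0.16
        assert mse_loss([[0.6, 0.4]], [0]) == pytest.approx(0.16)

    def test_duplicating_samples_preserves_loss(self):
        probs = [[0.7, 0.3], [0.2, 0.8]]
        labels = [1, 1]
        assert mse_loss(probs + probs, labels + labels) == pytest.approx(
            mse_loss(probs, labels))

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            mse_loss(np.empty((0, 2)), [])


class TestForward:
    def _encoded(self, smiles, vocab=None, radius=1):
        vocab = vocab or AtomVocabulary()
        return encode_graph(parse_smiles(smiles), vocab, radius), vocab

    def test_probs_normalized(self):
        graph, vocab = self._encoded("CC(=O)Oc1ccccc1")
        params = init_params(len(vocab), TrainConfig(seed=0))
        pred = forward(graph, params)
        assert pred.probs[0] + pred.probs[1] == pytest.approx(1.0, abs=1e-9)
        assert pred.score == pred.probs[1]
        assert pred.label == int(np.argmax(pred.probs))

    def test_deterministic(self):
        graph, vocab = self._encoded("CCO")
        params = init_params(len(vocab), TrainConfig(seed=3))
        assert forward(graph, params) == forward(graph, params)

    def test_duplicated_component_preserves_mean_readout(self):
        """Two identical disconnected copies give the same prediction as one."""
        vocab = AtomVocabulary()
        single = encode_graph(parse_smiles("CCO"), vocab, 1)
        doubled = encode_graph(parse_smiles("CCO.CCO"), vocab, 1)
        params = init_params(len(vocab), TrainConfig(seed=1))
        one = forward(single, params)
        two = forward(doubled, params)
        assert one.probs == pytest.approx(two.probs, abs=1e-12)

    def test_out_of_vocabulary_id_rejected(self):
        graph, vocab = self._encoded("CCO")
        params = init_params(1, TrainConfig(seed=0))  # vocabulary too small
        with pytest.raises(ValueError):
            forward(graph, params)


class TestGradients:
    def test_finite_difference_check(self, rng):
        """Backprop matches central differences on sampled parameters."""
        cfg = TrainConfig(hidden_dim=6, graph_layers=3, fc_layers=3, seed=9)
        vocab = AtomVocabulary()
        graphs = [encode_graph(parse_smiles(s), vocab, 1) for s in ("CCO", "CC(=O)C")]
        params = init_params(len(vocab), cfg)
        labels = np.array([0, 1])
        _, grads = batch_loss_and_grads(graphs, labels, params)
        arrays, grad_arrays = params.arrays(), grads.arrays()
        checked = 0
        while checked < 5:
            k = int(rng.integers(len(arrays)))
            a, g = arrays[k], grad_arrays[k]
            idx = tuple(int(rng.integers(s)) for s in a.shape)
            eps = 1e-6
            orig = a[idx]
            a[idx] = orig + eps
            up, _ = batch_loss_and_grads(graphs, labels, params)
            a[idx] = orig - eps
            down, _ = batch_loss_and_grads(graphs, labels, params)
            a[idx] = orig
            numeric = (up - down) / (2 * eps)
            if abs(numeric) < 1e-10:  # dead relu path: nothing to compare
                continue
            assert g[idx] == pytest.approx(numeric, rel=1e-4)
            checked += 1


class TestTraining:
    def test_learning_rate_schedule(self):
        cfg = TrainConfig()
        # iteration 25 (1-based) runs at 1e-4 * 0.99^2
        assert learning_rate_at(cfg, 24) == pytest.approx(1e-4 * 0.99 ** 2)
        for k in range(0, 50, 7):
            assert learning_rate_at(cfg, k) == pytest.approx(
                cfg.learning_rate * cfg.lr_decay ** (k // cfg.decay_interval))

    def test_identical_seed_identical_trace(self, toy_motif_dataset, tiny_config):
        vocab1, vocab2 = AtomVocabulary(), AtomVocabulary()
        _, trace1 = train(toy_motif_dataset, vocab1, tiny_config)
        _, trace2 = train(toy_motif_dataset, vocab2, tiny_config)
        assert trace1 == trace2

    def test_loss_decreases_on_separable_toy_set(self, toy_motif_dataset, tiny_config):
        vocab = AtomVocabulary()
        _, trace = train(toy_motif_dataset, vocab, tiny_config)
        assert trace[-1] < trace[0]

    def test_empty_training_set_rejected(self, tiny_config):
        with pytest.raises(ValueError):
            train([], AtomVocabulary(), tiny_config)


class TestPredictBatch:
    def test_scores_and_labels(self, toy_motif_dataset, tiny_config):
        vocab = AtomVocabulary()
        params, _ = train(toy_motif_dataset, vocab, tiny_config)
        vocab.freeze()
        preds, failures = predict_batch(toy_motif_dataset, vocab, params, tiny_config)
        assert not failures
        for p in preds:
            assert 0.0 <= p.score <= 1.0
            assert p.label == (1 if p.score > 0.5 else 0)

    def test_parse_failures_reported_per_record(self, toy_motif_dataset, tiny_config):
        vocab = AtomVocabulary()
        params, _ = train(toy_motif_dataset[:8], vocab, tiny_config)
        vocab.freeze()
        records = [toy_motif_dataset[0],
                   LabeledRecord("xyzzy", 0),
                   toy_motif_dataset[1]]
        preds, failures = predict_batch(records, vocab, params, tiny_config)
        assert failures == [1]
        assert preds[1] is None and preds[0] is not None and preds[2] is not None
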