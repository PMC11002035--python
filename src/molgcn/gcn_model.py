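"""The graph-convolutional classifier and its training loop.

Architecture: a learned embedding row per atom-environment id forms H^(0);
``graph_layers`` propagation steps H^(l+1) = sigma(A_hat H^(l) W^(l)) mix each
node with its neighbors under the symmetric normalization; the node matrix is
pooled by an arithmetic mean into one graph vector; ``fc_layers`` rectified
fully connected layers and a linear 2-unit map produce class scores, which a
normalized-exponential transform turns into probabilities.  Training minimises
the mean squared error between those probabilities and one-hot targets with
plain stochastic gradient descent, the learning rate decaying by a fixed
factor every ``decay_interval`` epochs.

The forward and backward passes are written directly in NumPy.  Inside one
mini-batch the member graphs are stacked block-diagonally so the whole batch
propagates through each layer in a single matrix product; the mean readout
becomes one segment-mean matrix multiply, which also makes the backward pass
a short chain of matrix products.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem_io import LabeledRecord, parse_smiles, SmilesParseError
from .graph_build import AtomVocabulary, MolGraph, encode_graph


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters; the defaults are the published schedule."""

    radius: int = 1
    graph_layers: int = 6
    fc_layers: int = 10
    batch_size: int = 4
    learning_rate: float = 1e-4
    lr_decay: float = 0.99
    decay_interval: int = 10
    iterations: int = 1000
    hidden_dim: int = 50
    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self):
        for name in ("radius",):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("graph_layers", "fc_layers", "batch_size",
                     "decay_interval", "iterations", "hidden_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.learning_rate <= 0 or not 0 < self.lr_decay <= 1:
            raise ValueError("bad learning-rate schedule")


@dataclass
class ModelParams:
    """All learnable tensors; shapes follow the config and vocabulary size."""

    embedding: np.ndarray            # |vocab| x d
    graph_W: list[np.ndarray]        # graph_layers matrices, d x d
    fc_W: list[np.ndarray]           # fc_layers matrices, d x d
    fc_b: list[np.ndarray]           # fc_layers vectors, d
    out_W: np.ndarray                # d x 2
    out_b: np.ndarray                # 2

    def arrays(self) -> list[np.ndarray]:
        """All parameter tensors, in a fixed order (views, not copies)."""
        return ([self.embedding] + self.graph_W + self.fc_W + self.fc_b
                + [self.out_W, self.out_b])

    def copy(self) -> "ModelParams":
        return ModelParams(
            embedding=self.embedding.copy(),
            graph_W=[w.copy() for w in self.graph_W],
            fc_W=[w.copy() for w in self.fc_W],
            fc_b=[b.copy() for b in self.fc_b],
            out_W=self.out_W.copy(),
            out_b=self.out_b.copy(),
        )


@dataclass(frozen=True)
class Prediction:
    probs: tuple[float, float]  # (p_neg, p_pos), sums to 1
    score: float                # p_pos
    label: int                  # argmax


def init_params(vocab_size: int, config: TrainConfig) -> ModelParams:
    """Seeded fan-scaled uniform initialization of every tensor.

    Weight matrices use rectifier-preserving (He) scaling, uniform on
    +/- sqrt(6 / fan_in): with this gain the signal variance survives the
    sixteen rectified layers of the default architecture, which plain
    variance-averaged scaling attenuates too strongly for the small fixed
    learning rate to recover.  Embedding rows are unit-variance uniform.
    """
    if vocab_size < 1:
        raise ValueError("vocab_size must be >= 1")
    rng = np.random.default_rng(config.seed)
    d = config.hidden_dim

    def he_uniform(fan_in: int, fan_out: int) -> np.ndarray:
        limit = np.sqrt(6.0 / fan_in)
        return rng.uniform(-limit, limit, size=(fan_in, fan_out))

    return ModelParams(
        embedding=rng.uniform(-np.sqrt(3.0), np.sqrt(3.0), size=(vocab_size, d)),
        graph_W=[he_uniform(d, d) for _ in range(config.graph_layers)],
        fc_W=[he_uniform(d, d) for _ in range(config.fc_layers)],
        fc_b=[np.zeros(d) for _ in range(config.fc_layers)],
        out_W=he_uniform(d, 2),
        out_b=np.zeros(2),
    )


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def gcn_layer(H: np.ndarray, A_hat: np.ndarray, W: np.ndarray, activation=relu) -> np.ndarray:
    """One propagation step: activation(A_hat @ H @ W)."""
    H = np.asarray(H, dtype=float)
    A_hat = np.asarray(A_hat, dtype=float)
    W = np.asarray(W, dtype=float)
    if H.ndim != 2 or A_hat.shape != (H.shape[0], H.shape[0]) or W.shape[0] != H.shape[1]:
        raise ValueError(
            f"shape mismatch: H {H.shape}, A_hat {A_hat.shape}, W {W.shape}")
    return activation(A_hat @ H @ W)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def mse_loss(probs_batch: np.ndarray, labels_batch: np.ndarray) -> float:
    """Mean squared error against one-hot targets.

    The mean runs over all 2m probability components of the m samples.
    """
    probs = np.asarray(probs_batch, dtype=float)
    labels = np.asarray(labels_batch, dtype=int)
    if probs.ndim != 2 or probs.shape[1] != 2 or probs.shape[0] != labels.shape[0]:
        raise ValueError("probs_batch must be m x 2 aligned with labels_batch")
    if probs.shape[0] == 0:
        raise ValueError("empty batch")
    targets = np.zeros_like(probs)
    targets[np.arange(len(labels)), labels] = 1.0
    return float(np.mean((probs - targets) ** 2))


# ---------------------------------------------------------------------------
# batched forward / backward


class _Batch:
    """Block-diagonal stacking of several MolGraphs."""

    def __init__(self, graphs: list[MolGraph]):
        sizes = [g.n for g in graphs]
        N = sum(sizes)
        B = len(graphs)
        self.ids = np.concatenate([g.node_ids for g in graphs])
        self.A_hat = np.zeros((N, N))
        self.S = np.zeros((B, N))  # segment-mean readout matrix
        offset = 0
        for k, g in enumerate(graphs):
            self.A_hat[offset:offset + g.n, offset:offset + g.n] = g.A_hat
            self.S[k, offset:offset + g.n] = 1.0 / g.n
            offset += g.n


def _forward_batch(batch: _Batch, params: ModelParams):
    """Forward pass over a stacked batch; returns probs and the tape."""
    if batch.ids.max() >= params.embedding.shape[0]:
        raise ValueError("node id out of vocabulary range")
    H = params.embedding[batch.ids]
    Hs, Zs = [H], []
    for W in params.graph_W:
        Z = batch.A_hat @ H @ W
        H = relu(Z)
        Zs.append(Z)
        Hs.append(H)
    R = batch.S @ H
    Xs, Us = [R], []
    X = R
    for W, b in zip(params.fc_W, params.fc_b):
        U = X @ W + b
        X = relu(U)
        Us.append(U)
        Xs.append(X)
    logits = X @ params.out_W + params.out_b
    probs = softmax(logits)
    return probs, (Hs, Zs, Xs, Us)


def _backward_batch(batch: _Batch, params: ModelParams, probs: np.ndarray,
                    labels: np.ndarray, tape) -> ModelParams:
    """Gradients of the batch MSE loss with respect to every parameter."""
    Hs, Zs, Xs, Us = tape
    B = probs.shape[0]
    targets = np.zeros_like(probs)
    targets[np.arange(B), labels] = 1.0
    # loss = sum((p - t)^2) / (2B)  =>  dL/dp = (p - t) / B
    dprobs = (probs - targets) / B
    # normalized-exponential backward
    dlogits = probs * (dprobs - (dprobs * probs).sum(axis=1, keepdims=True))

    grads = ModelParams(
        embedding=np.zeros_like(params.embedding),
        graph_W=[np.zeros_like(w) for w in params.graph_W],
        fc_W=[np.zeros_like(w) for w in params.fc_W],
        fc_b=[np.zeros_like(b) for b in params.fc_b],
        out_W=np.zeros_like(params.out_W),
        out_b=np.zeros_like(params.out_b),
    )
    grads.out_W[:] = Xs[-1].T @ dlogits
    grads.out_b[:] = dlogits.sum(axis=0)
    dX = dlogits @ params.out_W.T
    for k in range(len(params.fc_W) - 1, -1, -1):
        dU = dX * (Us[k] > 0)
        grads.fc_W[k][:] = Xs[k].T @ dU
        grads.fc_b[k][:] = dU.sum(axis=0)
        dX = dU @ params.fc_W[k].T
    dH = batch.S.T @ dX
    for l in range(len(params.graph_W) - 1, -1, -1):
        dZ = dH * (Zs[l] > 0)
        AH = batch.A_hat @ Hs[l]
        grads.graph_W[l][:] = AH.T @ dZ
        dH = batch.A_hat.T @ (dZ @ params.graph_W[l].T)
    np.add.at(grads.embedding, batch.ids, dH)
    return grads


def batch_loss_and_grads(graphs: list[MolGraph], labels: np.ndarray,
                         params: ModelParams) -> tuple[float, ModelParams]:
    """Loss and full gradients for one mini-batch (used by training and by
    the finite-difference gradient check)."""
    batch = _Batch(graphs)
    labels = np.asarray(labels, dtype=int)
    probs, tape = _forward_batch(batch, params)
    loss = mse_loss(probs, labels)
    grads = _backward_batch(batch, params, probs, labels, tape)
    return loss, grads


def forward(graph: MolGraph, params: ModelParams, config: TrainConfig | None = None) -> Prediction:
    """Classify one encoded molecule."""
    probs, _ = _forward_batch(_Batch([graph]), params)
    p_neg, p_pos = float(probs[0, 0]), float(probs[0, 1])
    return Prediction(probs=(p_neg, p_pos), score=p_pos, label=int(np.argmax(probs[0])))


def learning_rate_at(config: TrainConfig, iteration: int) -> float:
    """Learning rate in effect during a 0-based iteration (epoch) index."""
    return config.learning_rate * config.lr_decay ** (iteration // config.decay_interval)


def train(records: list[LabeledRecord], vocab: AtomVocabulary,
          config: TrainConfig) -> tuple[ModelParams, list[float]]:
    """Fit the classifier; returns parameters and the per-epoch loss trace.

    One iteration is one full sweep over the training set in mini-batches of
    ``batch_size`` (the last, possibly short, batch is kept).  The epoch order
    is reshuffled from the config seed, so identical inputs give identical
    traces.  Records must all be parseable; filter failures out beforehand.
    """
    if not records:
        raise ValueError("empty training set")
    graphs = [encode_graph(parse_smiles(r.smiles), vocab, config.radius) for r in records]
    labels = np.array([r.label for r in records], dtype=int)
    params = init_params(len(vocab), config)
    rng = np.random.default_rng(config.seed + 1)  # ordering stream, separate from init
    n = len(graphs)
    loss_trace: list[float] = []
    for it in range(config.iterations):
        lr = learning_rate_at(config, it)
        order = rng.permutation(n)
        total, seen = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            loss, grads = batch_loss_and_grads([graphs[i] for i in idx], labels[idx], params)
            for p, g in zip(params.arrays(), grads.arrays()):
                p -= lr * g
            total += loss * len(idx)
            seen += len(idx)
        loss_trace.append(total / seen)
    return params, loss_trace


def predict_batch(records: list[LabeledRecord], vocab: AtomVocabulary,
                  params: ModelParams, config: TrainConfig
                  ) -> tuple[list[Prediction | None], list[int]]:
    """Score records with a trained model and a frozen vocabulary.

    Returns per-record predictions (None where the SMILES failed to parse)
    and the indices of the failures.
    """
    predictions: list[Prediction | None] = []
    failures: list[int] = []
    for i, rec in enumerate(records):
        try:
            mol = parse_smiles(rec.smiles)
        except SmilesParseError:
            predictions.append(None)
            failures.append(i)
            continue
        graph = encode_graph(mol, vocab, config.radius)
        predictions.append(forward(graph, params, config))
    return predictions, failures
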