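from pathlib import Path

import numpy as np
import pytest

from molgcn import (
    AtomVocabulary,
    GeneratorConfig,
    TrainConfig,
    encode_graph,
    generate_dataset,
    parse_smiles,
)

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def reference_runs_path() -> Path:
    """Published per-run hold-out metrics used to validate aggregation."""
    return DATA_DIR / "reference_runs.csv"


@pytest.fixture(scope="session")
def citronellal():
    return parse_smiles("C[C@H](CCC=C(C)C)CC=O")


@pytest.fixture(scope="session")
def tiny_config():
    """A desk-scale config for fast training smoke tests."""
    return TrainConfig(hidden_dim=12, graph_layers=2, fc_layers=2,
                       iterations=60, learning_rate=5e-3, seed=7)


@pytest.fixture(scope="session")
def toy_motif_dataset():
    """40 linearly separable molecules labeled by the planted motif."""
    return generate_dataset(GeneratorConfig(n_pos=20, n_neg=20, seed=11))


def encode_all(smiles_list, radius=1, vocab=None):
    vocab = vocab or AtomVocabulary()
    graphs = [encode_graph(parse_smiles(s), vocab, radius) for s in smiles_list]
    return graphs, vocab


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
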