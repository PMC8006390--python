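import numpy as np
import pytest

from hetfactor import HeteroGraph, SynthConfig, generate, make_split
from hetfactor.model import ModelConfig
from hetfactor.training import TrainConfig, train


def toy_hetgraph() -> HeteroGraph:
    """Hand-built 4-type graph: two diseases bridging three genes, one GO
    term shared by two genes, one symptom on each disease."""
    return HeteroGraph(
        node_ids={
            "G": ["g0", "g1", "g2"],
            "D": ["d0", "d1"],
            "O": ["o0"],
            "S": ["s0", "s1"],
        },
        edges={
            "G-G": np.array([[0, 1]]),
            "G-D": np.array([[0, 0], [1, 0], [1, 1], [2, 1]]),
            "G-O": np.array([[0, 0], [2, 0]]),
            "D-S": np.array([[0, 0], [1, 1]]),
        },
    )


@pytest.fixture
def toy_graph() -> HeteroGraph:
    return toy_hetgraph()


@pytest.fixture(scope="session")
def small_synth():
    """A small planted network (non-default sizes, kept fast for unit tests)."""
    cfg = SynthConfig(n_G=60, n_D=40, n_O=30, n_S=15, seed=7)
    g, labels = generate(cfg)
    return g, labels, cfg


@pytest.fixture(scope="session")
def small_split(small_synth):
    g, _, _ = small_synth
    return make_split(g, test_fraction=0.2, neg_ratio=1.0, seed=7)


def tiny_model_cfg(**kw) -> ModelConfig:
    defaults = dict(hidden_dim=16, num_heads=2, num_factor_graphs=2, sem_dim=16)
    defaults.update(kw)
    return ModelConfig(**defaults)


@pytest.fixture(scope="session")
def small_model(small_synth, small_split):
    """A briefly trained model on the small planted network."""
    g, _, _ = small_synth
    tcfg = TrainConfig(epochs=15, seed=7, patience=0, val_fraction=0.1)
    return train(g, small_split, tcfg, tiny_model_cfg())
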