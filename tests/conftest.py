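import numpy as np
import pytest

from mtsc.io_preprocess import AnnotatedDataset
from mtsc.metric_net import EmbeddingNetwork
from mtsc.multitask_train import TrainConfig, train
from mtsc.synthetic_data import SimConfig, simulate
from mtsc.workflow import preprocess_references


def make_dataset(counts, name="toy", labels=None, cell_ids=None, gene_ids=None,
                 normalized=False):
    counts = np.asarray(counts, dtype=float)
    n, g = counts.shape
    return AnnotatedDataset(
        name=name,
        matrix=counts,
        cell_ids=cell_ids or [f"c{i}" for i in range(n)],
        gene_ids=gene_ids or [f"g{j}" for j in range(g)],
        labels=labels,
        normalized=normalized,
    )


def passthrough_net(dim: int) -> EmbeddingNetwork:
    """Identity network: embed(x) = x for non-negative inputs."""
    eye = np.eye(dim)
    return EmbeddingNetwork(W1=eye.copy(), b1=np.zeros(dim),
                            W2=eye.copy(), b2=np.zeros(dim))


@pytest.fixture(scope="session")
def small_sim_config():
    """Desk-scale simulation: 2 batches, 3 types, 200 genes."""
    return SimConfig(
        n_genes=200,
        cell_types={"alpha": 30, "beta": 30, "gamma": 30},
        n_batches=2,
        marker_genes_per_type=12,
        mean_depth=1500.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_batches(small_sim_config):
    return simulate(small_sim_config)


@pytest.fixture(scope="session")
def small_model(small_batches):
    """A quickly trained model on the small synthetic batches."""
    refs = preprocess_references(small_batches, qc=None)
    cfg = TrainConfig(epochs=15, seed=5, hidden_dim=64, embed_dim=10)
    return train(refs, cfg)
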